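# Protein-name words that can stand as an independent member inside a
# hyphenated complex name (e.g. the "cyclin" in CDK1-cyclin-B).
cyclin
calmodulin
ubiquitin
actin
tubulin
histone
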