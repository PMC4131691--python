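# Headwords marking a protein part / region mention.
domain
domains
terminus
termini
subunit
subunits
residue
residues
region
regions
motif
motifs
loop
loops
tail
tails
peptide
peptides
fragment
fragments
segment
segments
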