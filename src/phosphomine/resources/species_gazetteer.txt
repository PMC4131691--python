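# Model-organism gazetteer (scientific + common names), case-insensitive,
# longest match wins. Editable.
Homo sapiens
human
humans
Mus musculus
mouse
mice
murine
Rattus norvegicus
rat
rats
Saccharomyces cerevisiae
Saccharomyces
yeast
Schizosaccharomyces pombe
Gallus gallus
chick
chicken
Danio rerio
zebrafish
Drosophila melanogaster
Drosophila
Xenopus laevis
Xenopus
Caenorhabditis elegans
C. elegans
Arabidopsis thaliana
Arabidopsis
Escherichia coli
E. coli
bovine
cow
porcine
pig
rabbit
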