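# Species synonym table for PubMed query construction.
# key <TAB> MeSH term <TAB> synonym|synonym|...
# Only the Human row is fixed by the service's documented query template;
# the other rows are editable artifact data in the same shape.
human	Humans	Homo sapiens|human|Modern Man
mouse	Mice	Mus musculus|mouse|mice
rat	Rats	Rattus norvegicus|rat|rats
yeast	Saccharomyces cerevisiae	Saccharomyces cerevisiae|yeast|budding yeast
chicken	Chickens	Gallus gallus|chicken|chick
zebrafish	Zebrafish	Danio rerio|zebrafish
fruit fly	Drosophila melanogaster	Drosophila melanogaster|Drosophila|fruit fly
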