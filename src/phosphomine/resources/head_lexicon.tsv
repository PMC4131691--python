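# Headword -> semantic category hints, applied before morphology rules.
# word <TAB> value
# KINASE_HEAD is resolved to PROTEIN_FAMILY (plural/generic use) or PROTEIN
# (singular with a specific name) by the classifier.
kinase	KINASE_HEAD
kinases	KINASE_HEAD
phosphatase	PROTEIN
phosphatases	PROTEIN_FAMILY
complex	PROTEIN_COMPLEX
complexes	PROTEIN_COMPLEX
holoenzyme	PROTEIN_COMPLEX
heterodimer	PROTEIN_COMPLEX
protein	PROTEIN
proteins	PROTEIN
enzyme	PROTEIN
enzymes	PROTEIN_FAMILY
ATP	CHEMICAL
GTP	CHEMICAL
ADP	CHEMICAL
DNA	CHEMICAL
RNA	CHEMICAL
mRNA	CHEMICAL
phosphate	CHEMICAL
phosphates	CHEMICAL
inhibitor	CHEMICAL
inhibitors	CHEMICAL
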