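# Phosphorylation trigger lexicon.
# word-or-phrase <TAB> form (nominal | verbal)
# The adjectival form ("<SITE>-phosphorylated") is recognized structurally
# by the pattern engine, not listed here.
# This list is a declared superset of the published partial list and is
# editable; phrases may contain spaces (matched tolerant of hyphen/space).
phosphorylation	nominal
phosphorylations	nominal
autophosphorylation	nominal
hyperphosphorylation	nominal
transphosphorylation	nominal
phosphoprotein	nominal
phosphoproteins	nominal
phospho amino acid	nominal
phospho amino acids	nominal
phosphorylate	verbal
phosphorylates	verbal
phosphorylated	verbal
phosphorylating	verbal
autophosphorylate	verbal
autophosphorylates	verbal
autophosphorylated	verbal
hyperphosphorylate	verbal
hyperphosphorylates	verbal
hyperphosphorylated	verbal
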