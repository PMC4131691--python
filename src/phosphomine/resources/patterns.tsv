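# Pattern inventory for the phosphorylation IE engine.
# pattern_id <TAB> trigger form <TAB> slot template (slot=ROLE, space-separated)
# Slots: subject (NP left of trigger), object (NP right of a verbal trigger),
# of_pp / by_pp / at_pp (prepositional adjuncts), premod (nouns preceding a
# nominal trigger inside its NP), prefix (hyphenated prefix of an adjectival
# trigger), next_np (NP following an adjectival trigger).
# at_pp covers the site prepositions at/on/in; adjuncts match in any order.
# A trailing '*' marks a slot that must resolve to its stated role for the
# rule to fire; '+' marks a slot that must resolve to some role (the content
# may override, e.g. an of-phrase that is itself a site).
V1	verbal_active	subject=KINASE object=SUBSTRATE* at_pp=SITE
V2	verbal_passive	subject=SUBSTRATE by_pp=KINASE at_pp=SITE
V3	verbal_active	subject=KINASE object=SITE* of_pp=SUBSTRATE at_pp=SITE
N1	nominal	of_pp=SUBSTRATE+ at_pp=SITE by_pp=KINASE
N2	nominal	premod=SUBSTRATE* at_pp=SITE by_pp=KINASE
A1	adjectival	prefix=SITE* next_np=SUBSTRATE*
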