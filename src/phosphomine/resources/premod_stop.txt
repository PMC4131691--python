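# Premodifiers excluded from kinase/substrate mention strings
# (species words and quality adjectives); the full NP span is still kept
# as provenance.
human
murine
mouse
rat
yeast
bovine
porcine
chick
chicken
recombinant
endogenous
exogenous
purified
biotinylated
tagged
wild-type
wt
mutant
native
full-length
the
a
an
this
that
these
those
its
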