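# Closed-class and domain lexicon for the default tagger.
# word <TAB> tag (NOUN VERB AUX ADJ ADV DET PREP CONJ PUNCT NUM)
the	DET
a	DET
an	DET
this	DET
that	DET
these	DET
those	DET
its	DET
their	DET
his	DET
her	DET
our	DET
each	DET
any	DET
some	DET
both	DET
all	DET
no	DET
several	DET
of	PREP
in	PREP
on	PREP
at	PREP
by	PREP
for	PREP
with	PREP
without	PREP
from	PREP
to	PREP
into	PREP
onto	PREP
within	PREP
through	PREP
between	PREP
during	PREP
via	PREP
upon	PREP
after	PREP
before	PREP
under	PREP
over	PREP
against	PREP
including	PREP
as	PREP
and	CONJ
or	CONJ
but	CONJ
nor	CONJ
whereas	CONJ
while	CONJ
whether	CONJ
because	CONJ
although	CONJ
if	CONJ
when	CONJ
is	AUX
are	AUX
was	AUX
were	AUX
be	AUX
been	AUX
being	AUX
am	AUX
has	AUX
have	AUX
had	AUX
having	AUX
can	AUX
could	AUX
may	AUX
might	AUX
will	AUX
would	AUX
shall	AUX
should	AUX
must	AUX
do	AUX
does	AUX
did	AUX
not	ADV
also	ADV
here	ADV
directly	ADV
specifically	ADV
subsequently	ADV
previously	ADV
further	ADV
thus	ADV
moreover	ADV
however	ADV
therefore	ADV
then	ADV
we	NOUN
it	NOUN
they	NOUN
i	NOUN
he	NOUN
she	NOUN
you	NOUN
# domain verbs commonly reporting phosphorylation findings
phosphorylate	VERB
phosphorylates	VERB
phosphorylated	VERB
phosphorylating	VERB
autophosphorylate	VERB
autophosphorylates	VERB
autophosphorylated	VERB
hyperphosphorylate	VERB
hyperphosphorylates	VERB
hyperphosphorylated	VERB
dephosphorylate	VERB
dephosphorylates	VERB
dephosphorylated	VERB
report	VERB
reports	VERB
reported	VERB
show	VERB
shows	VERB
showed	VERB
shown	VERB
demonstrate	VERB
demonstrates	VERB
demonstrated	VERB
found	VERB
find	VERB
finds	VERB
reveal	VERB
reveals	VERB
revealed	VERB
require	VERB
requires	VERB
required	VERB
bind	VERB
binds	VERB
bound	VERB
occur	VERB
occurs	VERB
occurred	VERB
# ambiguous -ate/-ed nouns that the suffix rules would mistag
substrate	NOUN
substrates	NOUN
phosphate	NOUN
phosphates	NOUN
state	NOUN
states	NOUN
rate	NOUN
rates	NOUN
fate	NOUN
date	NOUN
seed	NOUN
need	NOUN
bed	NOUN
# common adjectives in these texts
mutant	ADJ
recombinant	ADJ
wild-type	ADJ
endogenous	ADJ
essential	ADJ
present	ADJ
absent	ADJ
novel	ADJ
other	ADJ
same	ADJ
such	ADJ
specific	ADJ
# species words kept nominal so "human Crm1" chunks with head "Crm1"
human	NOUN
murine	NOUN
bovine	NOUN
porcine	NOUN
in-vitro	ADJ
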