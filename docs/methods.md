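# Methods

This note documents the models, rules and design choices behind
phosphomine, in the spirit of a statistical package's methods appendix:
what the procedure assumes, which knobs matter, and what the tests do and
do not establish.

## Linguistic preprocessing

**Sentence segmentation** cuts at `[.!?]` + whitespace + capital/digit,
protected by an abbreviation list (`e.g.`, `i.e.`, `Fig.`, `et al.`, …),
single-letter initials (`S. cerevisiae`) and decimal numbers. The
splitter is purely rule-based and deterministic.

**Tokenization** keeps hyphen/slash compounds whole when any part carries
a digit or is non-lowercase (`CDK1-cyclin-B`, `Ser-391`, `FLT3/ITD`),
splitting slashes only between plain lowercase words (`and/or`).
Rationale: surface variants of kinase names must survive verbatim so that
downstream collapsing can keep them distinct, and compounds like
`phosphorylation-dependent` must *not* decompose into a bare trigger
word. Possessive `'s` is split off; parentheses are separate tokens.

**Tagging** uses a coarse 10-tag set (NOUN, VERB, AUX, ADJ, ADV, DET,
PREP, CONJ, PUNCT, NUM). The default tagger is a closed-class lexicon of
~170 entries plus domain verbs, suffix rules (-tion → noun, -ylated →
verb, -ly → adverb, …) and a default-noun fallback for unknown
capitalized or digit-bearing tokens — the right default for gene/protein
symbols. A contextual pass retags attributive participles ("the
**phosphorylated** forms") as adjectives so they neither chunk as verb
groups nor fire verbal patterns. The hand-written chunk rules only need
coarse distinctions, so no statistical tagger is used; any callable
satisfying the tokens-in/equal-length-tags-out contract can be plugged
in instead.

**Chunking** builds maximal flat NPs (optional determiner + premodifiers
+ head noun, optionally a trailing number bound to the head, as in
"serine 391") and VGs (auxiliaries/adverbs + main verb). NP heads are
always the rightmost noun; chunks never overlap.

## Term classification

Categories are assigned by the first matching rule in a fixed priority
order — site grammar, headword lexicon, hyphenated-complex test, protein
morphology (digit-bearing symbol, -ase/-in suffix, Greek-letter modifier,
short all-caps symbol), part-words, species gazetteer, OTHER — and the
rule id is recorded on every mention for auditability. The
hyphenated-complex test requires at least two *independent* protein names
inside one token, where a numbered suffix does not count: `CDK1-cyclin-B`
is a complex but `GSK-3B` is a single protein.

The site grammar accepts residue+position in all common spellings
(one-letter codes only when uppercase and digit-adjacent — a bare "S" is
never a site), bare residue types, regions/domains, and coordination with
elliptical right conjuncts ("Ser-63 and -73" inherits Ser from the left
conjunct — standard biomedical convention). When forms nest ("serine
residue Ser-391") the most specific reading wins; an embedded-position
fallback accepts such strings only when every surrounding word is site
vocabulary, which keeps NPs like "Ser-64-phosphorylated Sox9" from being
swallowed as sites.

Species detection is gazetteer-only (shipped model-organism list,
longest match wins) and is surfaced for highlighting, never used to
resolve the substrate's taxon.

## Event extraction

Sentences are simplified before matching:

* discourse frames ending in a "that"-complementizer are stripped
  ("Here, we report that X" → "X");
* parentheticals with no protein or site content are removed;
* clause coordination (", and", ", but", ";") is split;
* coordinated same-category protein NPs adjacent to a trigger verb are
  distributed into clause copies.

Each clause keeps a piecewise map back to section offsets, so every
extracted mention addresses its exact substring in the original text.

The pattern inventory (data file, one line per rule) covers the verbal
active/passive forms, the site-of-substrate construction, the two
nominalizations and the adjectival compound. Slot filling is
*content-driven*: an NP assigned to a substrate slot that actually parses
as a site fills the site slot instead, which is what deterministically
forces the V3 reading of "phosphorylated Y654 of beta-catenin". Rules are
tried in inventory order and the first rule whose required slots fill
wins; shuffling the order changes at most the pattern id of ties. Events
with neither kinase nor substrate (nor an unresolved anaphor) are
discarded.

The `kinase_mode` switch (default `precision`) controls a recall-biased
variant in which subject NPs of category OTHER are accepted as kinases
when the clause carries a kinase cue word. Negation and speculation are
not modeled: hedged statements extract normally, which matches the
curation-support use case where a curator reviews every row.

## Document assembly

Anaphora resolution is deliberately narrow: a window of 2 sentences
within the same section, and only for bare anaphoric NPs ("this
residue", "the enzyme"). A site anaphor folds its event into the
antecedent event (contributing any new slots and appending evidence); a
substrate-less event inherits the substrate of the nearest preceding
event in the window. The small window bounds error propagation.

Collapsing groups events by the exact surface tuple (kinase string,
substrate string, normalized site list) after whitespace normalization —
case-sensitive, no synonym merging, so textual variants like FLT3 vs
FLT3/ITD remain separate rows for the curator to merge. Sites are keyed
as `Xaa-NNN` and ordered by position; rows with all three slots filled
sort first, ties keep first-evidence order. Collapsing is idempotent and
loses no evidence sentences.

## Triage and queries

*Potential* = case-insensitive whole-word trigger match over title and
abstract only (multi-word triggers tolerate hyphen/space variation);
*positive* = potential **and** at least one extracted substrate. Defining
positive as a refinement of potential keeps the subset invariant total
even for full-text documents whose only events lie outside the
title/abstract. PubMed query construction is pure string building from a
shipped species-synonym table; only the Human row is fixed by the
documented service template, the rest are editable data. Executing
queries against NCBI is out of scope.

## Evaluation

Scoring is document-level: a predicted value is correct if the same
document's gold set contains a match. Policies: EXACT (case-insensitive
surface) for kinase/substrate, SITE_NORMALIZED (site-grammar equality, so
"Ser-391" ≡ "serine 391") for sites; both can be selected per slot since
curator practice varies. Zero denominators yield 0 by convention so batch
evaluation is total. Inter-annotator agreement scores annotator B against
A; swapping the arguments swaps precision and recall and preserves F
exactly.

A note on reproducing printed score tables: an F recomputed from
*printed, rounded* precision/recall can differ from the printed F by one
unit in the last digit (harmonic-mean rounding), so the acceptance tests
assert agreement within 0.01 rather than exact re-rounding where the
printed inputs make exact agreement impossible.

## Synthetic corpus

The generator emits one template instantiation per document from fixed
name pools (10 kinases, 10 substrates, Ser/Thr/Tyr sites in three surface
styles), with a default mix weighted toward the simple verbal and nominal
constructions (14% V1, 14% V2, 10% V3, 12% N1, 10% N2, 10% A1, 10%
cross-sentence, 15% distractors, 5% trigger-free). Distractors probe the
known precision hazards: trigger words inside hyphen compounds,
phosphatase/phosphate vocabulary, and site mentions without any trigger.
Gold annotations (slots, normalized sites, triage labels) are computed by
the generator from the template metadata, independently of the extraction
code. Output is fully determined by the seed.

What the generated corpus does **not** emulate: real MEDLINE discourse
(multi-event abstracts, long-range coreference, novel protein
nomenclature, OCR noise). Perfect slot recall on the generated corpus
therefore demonstrates that the engine covers the documented
constructions, not that it attains any particular recall on live
literature. The default test sizes (150 documents for unit suites, 500
for the recall/precision property, 1000 for the triage subset property)
were chosen to exercise every template many times while keeping the suite
fast.

## Known limitations

* No gene/protein normalization to database accessions; family and
  complex mentions carry an entity-type label precisely because they
  cannot be normalized.
* No negation/speculation handling and no experimental-evidence
  detection; review filtering by publication type is the only
  evidence-oriented filter.
* The pattern inventory is intentionally minimal and extensible; clause
  constructions outside it (e.g. relative clauses, by-agent fronting)
  are not covered.
* Anaphora resolution is heuristic; antecedents beyond 2 sentences or
  across sections are never linked.
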