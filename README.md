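# phosphomine

Rule-based mining of **protein phosphorylation events** from biomedical
abstracts and full-text sections. Given free text, the pipeline extracts
(kinase, substrate, phosphorylation site) tuples with sentence-level
evidence, triages documents by phosphorylation relevance, and scores
extractions against curator-style gold annotations. It is aimed at
database curators (phosphorylation and PTM resources) and at anyone who
needs structured kinase–substrate–site assertions from literature without
running a machine-learned model.

## The method

Phosphorylation findings are reported in a small number of recurring
constructions. The pipeline makes those constructions explicit:

1. **Shallow parsing** — sentences are segmented, tokenized (hyphenated
   biochemical names such as `CDK1-cyclin-B`, `Ser-391` and `FLT3/ITD`
   stay single tokens), tagged with a coarse 10-tag set by a
   self-contained lexicon + suffix-rule tagger, and chunked into flat noun
   phrases and verb groups.
2. **Term classification** — each NP receives one semantic category
   (protein, protein complex, protein family, protein part, chemical,
   site, species, other) by prioritized rules over the headword, affixes
   and morphology. A site grammar normalizes mentions into residue +
   position (`Ser-391`, `S391`, `serine 391`, `pS473`, `Tyr(654)`), bare
   residue type, or region/domain (`C-terminal domain`), including
   coordination (`S64 and S181`, `Ser-63 and -73`).
3. **Pattern matching** — sentences are simplified (discourse-frame
   stripping, clause splitting, parenthetical removal, coordination
   distribution) and a declarative pattern inventory is matched over each
   clause: active/passive verbal forms, nominalizations
   ("phosphorylation of X at Y by Z"), the site-of-substrate construction
   ("phosphorylated Y654 of beta-catenin") and adjectival compounds
   ("Ser-391-phosphorylated X"). Patterns are data
   (`resources/patterns.tsv`), not code.
4. **Document assembly** — anaphoric slots ("this residue", "the
   enzyme") are resolved across sentences, identical outputs are
   collapsed into summary rows (surface variants such as FLT3 vs FLT3/ITD
   deliberately stay distinct), and full-text documents are restricted to
   the experimentally relevant sections (Abstract, Results, Figure
   legend, Discussion).
5. **Triage & evaluation** — documents are *potential* when a trigger
   word (phosphorylation, phosphorylate(s), phosphorylated,
   phosphoprotein(s), phospho amino acid(s), …) occurs in title/abstract
   and *positive* when at least one substrate is extracted. Extraction
   quality is scored at the document level with
   Precision = TP/(TP+FP), Recall = TP/(TP+FN),
   F = 2·P·R/(P+R); inter-annotator agreement uses the same F, which is
   symmetric in the two annotators.

I/O covers plain text, MEDLINE/nbib records, BioC XML (round-trip safe)
and RFC-4180 CSV summaries. A synthetic-corpus generator produces seeded,
fully-annotated test corpora for every supported construction.

## Worked example

```bash
$ printf '%s' "Here, we report that human Crm1 is phosphorylated at serine 391 in mitosis by CDK1-cyclin-B." > crm1.txt
$ phosphomine extract --in crm1.txt
pmid,kinase,substrate,site,evidence_sentences
crm1,CDK1-cyclin-B,Crm1,Ser-391,"Here, we report that human Crm1 is phosphorylated at serine 391 in mitosis by CDK1-cyclin-B."
```

The passive pattern fires: the subject NP `human Crm1` fills the
substrate slot (the species premodifier is excluded from the mention, so
the substrate string is `Crm1`), the by-agent `CDK1-cyclin-B` is
classified as a protein complex and fills the kinase slot, and
`serine 391` normalizes to the site `Ser-391`.

Query construction for a species-restricted, review-free search prints
the exact PubMed template:

```bash
$ phosphomine query-build --query "beta catenin" --species human --exclude-reviews
beta catenin[TIAB] AND (Homo sapiens [TIAB] OR human [TIAB] OR Modern Man [TIAB] OR Humans [MeSH Terms]) AND NOT Review [PT]
```

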