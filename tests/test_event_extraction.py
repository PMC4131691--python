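"""Sentence simplification and pattern matching over clauses."""

import random

import pytest

from phosphomine.event_extraction import (
    DEFAULT_CONFIG,
    ExtractionConfig,
    extract_sentence_events,
    match_patterns,
    simplify_sentence,
)
from phosphomine.linguistic_preprocess import split_sentences
from phosphomine.model import Residue, SectionName, SiteKind


def _sentence(text):
    (s,) = split_sentences(text, "doc", SectionName.ABSTRACT)
    return s


def _events(text, config=DEFAULT_CONFIG):
    return extract_sentence_events(_sentence(text), config)


class TestSimplify:
    def test_discourse_prefix_stripped(self):
        (clause,) = simplify_sentence(_sentence(
            "Here, we report that human Crm1 is phosphorylated at serine 391 "
            "in mitosis by CDK1-cyclin-B."
        ))
        assert clause.text.startswith("human Crm1 is phosphorylated")

    def test_plain_clause_unchanged(self):
        text = "CK2 phosphorylates p53 at Ser-20."
        (clause,) = simplify_sentence(_sentence(text))
        assert clause.text == text

    def test_clause_coordination_splits(self):
        clauses = simplify_sentence(_sentence(
            "In COS-7 cells, FLT3/ITD phosphorylated Y654, and this residue "
            "was essential for nuclear localization."
        ))
        assert len(clauses) == 2
        assert clauses[0].text.endswith("Y654")
        assert clauses[1].text.startswith("this residue")

    def test_uninformative_parenthetical_removed_entity_kept(self):
        (c1,) = simplify_sentence(_sentence(
            "CK2 (previously described) phosphorylates p53."
        ))
        assert "(previously described)" not in c1.text
        (c2,) = simplify_sentence(_sentence(
            "Glycogen synthase kinase-3beta (GSK-3B) phosphorylates tau protein."
        ))
        assert "GSK-3B" in c2.text

    def test_segments_map_back_to_section(self):
        sentence = _sentence(
            "Here, we report that CK2 phosphorylates p53 at Ser-20."
        )
        (clause,) = simplify_sentence(sentence)
        mapped = clause.map_span(0, len(clause.text))
        assert mapped is not None
        assert sentence.text[mapped[0]:mapped[1]] == clause.text


def _shape(ev):
    return (
        ev.kinase.text if ev.kinase else None,
        ev.substrate.text if ev.substrate else None,
        tuple((s.residue, s.position) for s in ev.sites
              if s.kind is SiteKind.RESIDUE_POSITION),
        ev.pattern_id,
    )


class TestMatchPatterns:
    def test_passive_with_by_agent_and_site(self):
        (ev,) = _events(
            "Here, we report that human Crm1 is phosphorylated at serine 391 "
            "in mitosis by CDK1-cyclin-B."
        )
        assert _shape(ev) == (
            "CDK1-cyclin-B", "Crm1", ((Residue.SER, 391),), "V2"
        )

    def test_site_of_substrate_forces_v3(self):
        (ev,) = _events("FLT3 directly phosphorylated Y654 of beta-catenin.")
        assert _shape(ev) == ("FLT3", "beta-catenin", ((Residue.TYR, 654),), "V3")

    def test_nominal_with_coordinated_sites_no_kinase(self):
        (ev,) = _events(
            "Here we show, in the developing chick neural tube, that "
            "phosphorylation of Sox9 on S64 and S181 facilitates its "
            "SUMOylation, and the phosphorylated forms of Sox9 are essential "
            "for trunk neural crest delamination."
        )
        assert _shape(ev) == (
            None, "Sox9", ((Residue.SER, 64), (Residue.SER, 181)), "N1"
        )

    def test_simple_active(self):
        (ev,) = _events("GSK-3B phosphorylates tau protein.")
        assert _shape(ev) == ("GSK-3B", "tau protein", (), "V1")

    def test_trigger_without_protein_nps_yields_nothing(self):
        assert _events("Phosphorylation was increased overall.") == []

    def test_no_trigger_no_event(self):
        assert _events("CK2 binds p53 at the promoter.") == []

    def test_adjectival_site_compound(self):
        (ev,) = _events("Ser-64-phosphorylated Sox9 accumulates in the nucleus.")
        assert _shape(ev) == (None, "Sox9", ((Residue.SER, 64),), "A1")

    def test_premodifier_nominal(self):
        (ev,) = _events("Crm1 phosphorylation at Ser-12 increased twofold.")
        assert _shape(ev) == (None, "Crm1", ((Residue.SER, 12),), "N2")

    def test_events_carry_trigger_from_lexicon(self):
        for ev in _events("CK2 phosphorylates p53 at Ser-20."):
            assert ev.trigger_text.lower() in DEFAULT_CONFIG.trigger_map

    def test_rule_order_shuffle_changes_nothing_but_tiebreak(self):
        text = "Here, we report that Crm1 is phosphorylated at Ser-391 by CDK1."
        base = _events(text)
        rng = random.Random(0)
        for _ in range(5):
            rules = list(DEFAULT_CONFIG.rules)
            rng.shuffle(rules)
            config = ExtractionConfig(rules=tuple(rules))
            got = _events(text, config)
            assert [
                (e.kinase.text if e.kinase else None,
                 e.substrate.text if e.substrate else None,
                 e.sites) for e in got
            ] == [
                (e.kinase.text if e.kinase else None,
                 e.substrate.text if e.substrate else None,
                 e.sites) for e in base
            ]

    def test_kinase_recall_mode_accepts_cued_other_subject(self):
        text = "The Wee1-like kinase activity of Myt1 phosphorylates Cdc2 at Thr-14."
        precision = _events(text)
        recall = _events(text, ExtractionConfig(kinase_mode="recall"))
        rec_kinases = [e.kinase for e in recall if e.kinase]
        pre_kinases = [e.kinase for e in precision if e.kinase]
        assert len(rec_kinases) >= len(pre_kinases)

    def test_mention_spans_address_section_text(self):
        text = (
            "Here, we report that human Crm1 is phosphorylated at serine 391 "
            "in mitosis by CDK1-cyclin-B."
        )
        (ev,) = _events(text)
        for mention in (ev.kinase, ev.substrate):
            s, e = mention.span
            assert text[s:e] == mention.text


class TestFixtureCorpus:
    def test_covered_templates_fully_recovered(self, small_corpus):
        from phosphomine.pipeline import annotate_document

        docs, gold = small_corpus
        for doc, gd in zip(docs, gold):
            rows = {
                (r.kinase_text, r.substrate_text, r.site_texts)
                for r in annotate_document(doc).summary
            }
            want = {(e.kinase, e.substrate, e.sites) for e in gd.events}
            assert want <= rows, (gd.kind, doc.sections[1].text, want, rows)

    def test_distractors_produce_no_events(self, small_corpus):
        from phosphomine.pipeline import annotate_document

        docs, gold = small_corpus
        for doc, gd in zip(docs, gold):
            if gd.kind in ("distractor", "trigger_free"):
                assert annotate_document(doc).events == []
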