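"""NP categorization, the site grammar, and species detection."""

import pytest
from hypothesis import given, settings, strategies as st

from phosphomine.linguistic_preprocess import chunk, pos_tag, tokenize
from phosphomine.model import Category, Document, Residue, Section, SectionName, SiteKind
from phosphomine.term_classifier import (
    classify_np,
    detect_species,
    parse_site_mention,
)


def _classify(text):
    toks = pos_tag(tokenize(text))
    chunks = chunk(toks)
    assert chunks, f"no NP chunk for {text!r}"
    return classify_np(toks, chunks[0])


class TestClassifyNP:
    @pytest.mark.parametrize(
        "text,category",
        [
            ("CDK1-cyclin-B", Category.PROTEIN_COMPLEX),
            ("Src kinases", Category.PROTEIN_FAMILY),
            ("human", Category.SPECIES),
            ("the cell", Category.OTHER),
            ("Crm1", Category.PROTEIN),
            ("GSK-3B", Category.PROTEIN),
            ("p53", Category.PROTEIN),
            ("tau protein", Category.PROTEIN),
            ("the C-terminal domain", Category.SITE),
            ("serine 391", Category.SITE),
            ("the catalytic subunit", Category.PROTEIN_PART),
            ("ATP", Category.CHEMICAL),
        ],
    )
    def test_category(self, text, category):
        got, rule = _classify(text)
        assert got is category

    def test_rule_trace_is_recorded(self):
        _, rule = _classify("CDK1-cyclin-B")
        assert rule == "hyphen-complex"
        _, rule = _classify("the cell")
        assert rule == "default"

    def test_exactly_one_category_per_np(self):
        # priority order means site grammar beats protein morphology
        got, rule = _classify("S64")
        assert got is Category.SITE and rule == "site-grammar"


class TestParseSiteMention:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("serine 391", [(SiteKind.RESIDUE_POSITION, Residue.SER, 391)]),
            ("Ser-391", [(SiteKind.RESIDUE_POSITION, Residue.SER, 391)]),
            ("S391", [(SiteKind.RESIDUE_POSITION, Residue.SER, 391)]),
            ("Ser391", [(SiteKind.RESIDUE_POSITION, Residue.SER, 391)]),
            ("Y654", [(SiteKind.RESIDUE_POSITION, Residue.TYR, 654)]),
            ("pS473", [(SiteKind.RESIDUE_POSITION, Residue.SER, 473)]),
            ("Tyr(654)", [(SiteKind.RESIDUE_POSITION, Residue.TYR, 654)]),
            (
                "S64 and S181",
                [
                    (SiteKind.RESIDUE_POSITION, Residue.SER, 64),
                    (SiteKind.RESIDUE_POSITION, Residue.SER, 181),
                ],
            ),
            (
                "S64/S181",
                [
                    (SiteKind.RESIDUE_POSITION, Residue.SER, 64),
                    (SiteKind.RESIDUE_POSITION, Residue.SER, 181),
                ],
            ),
            (
                "Ser-63 and -73",
                [
                    (SiteKind.RESIDUE_POSITION, Residue.SER, 63),
                    (SiteKind.RESIDUE_POSITION, Residue.SER, 73),
                ],
            ),
            ("serine", [(SiteKind.RESIDUE_TYPE, Residue.SER, None)]),
            ("threonine", [(SiteKind.RESIDUE_TYPE, Residue.THR, None)]),
            ("banana", []),
            ("S", []),  # bare one-letter code is never a site
        ],
    )
    def test_forms(self, text, expected):
        got = [
            (s.kind, s.residue if s.kind is not SiteKind.REGION else None,
             s.position)
            for s in parse_site_mention(text)
        ]
        want = [
            (k, r if k is not SiteKind.REGION else None, p)
            for k, r, p in expected
        ]
        assert got == want

    def test_region_forms(self):
        (spec,) = parse_site_mention("C-terminal domain")
        assert spec.kind is SiteKind.REGION
        assert spec.region_text == "C-terminal domain"
        (spec,) = parse_site_mention("the SH2 domain")
        assert spec.kind is SiteKind.REGION

    def test_most_specific_wins(self):
        specs = parse_site_mention("serine residue Ser-391")
        assert [(s.kind, s.position) for s in specs] == [
            (SiteKind.RESIDUE_POSITION, 391)
        ]

    @given(
        st.sampled_from(["S", "T", "Y"]),
        st.integers(min_value=1, max_value=2000),
        st.sampled_from(["S", "T", "Y"]),
        st.integers(min_value=1, max_value=2000),
    )
    @settings(derandomize=True)
    def test_coordination_distributes(self, r1, p1, r2, p2):
        a, b = f"{r1}{p1}", f"{r2}{p2}"
        joined = parse_site_mention(f"{a} and {b}")
        assert len(joined) == len(parse_site_mention(a)) + len(
            parse_site_mention(b)
        )

    def test_total_and_deterministic(self):
        for junk in ("", "   ", "!!", "site of action", "10 mg"):
            assert parse_site_mention(junk) == parse_site_mention(junk)


class TestDetectSpecies:
    def test_chick_in_sox9_sentence(self):
        doc = Document(
            "x",
            (Section(SectionName.ABSTRACT,
                     "Here we show, in the developing chick neural tube, that "
                     "Sox9 is phosphorylated."),),
        )
        names = [m.text for m in detect_species(doc)]
        assert names == ["chick"]

    def test_no_gazetteer_word(self):
        doc = Document("x", (Section(SectionName.ABSTRACT, "CK2 binds p53."),))
        assert detect_species(doc) == []

    def test_longest_match_wins_and_counts(self):
        doc = Document(
            "x",
            (Section(SectionName.ABSTRACT,
                     "Homo sapiens and human samples were used."),),
        )
        names = [m.text for m in detect_species(doc)]
        assert names == ["Homo sapiens", "human"]

    def test_spans_address_text(self):
        text = "Studies in Saccharomyces cerevisiae and mouse confirmed this."
        doc = Document("x", (Section(SectionName.ABSTRACT, text),))
        for m in detect_species(doc):
            assert text[m.span[0]:m.span[1]] == m.text
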