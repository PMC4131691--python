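"""Format readers and writers: plain text, MEDLINE, BioC, CSV."""

import io
import logging

import pytest

from phosphomine import corpus_io
from phosphomine.model import Document, Section, SectionName, SummaryRow, Sentence
from phosphomine.pipeline import annotate_document


CRM1 = (
    "Here, we report that human Crm1 is phosphorylated at serine 391 in "
    "mitosis by CDK1-cyclin-B."
)


class TestPlainText:
    def test_single_abstract_section(self):
        doc = corpus_io.read_plain_text(io.StringIO(CRM1), "23729730")
        assert len(doc.sections) == 1
        assert doc.sections[0].name is SectionName.ABSTRACT
        assert doc.sections[0].text == CRM1

    def test_empty_input_is_valid(self):
        doc = corpus_io.read_plain_text(io.StringIO(""), "x")
        assert doc.sections[0].text == ""
        assert annotate_document(doc).events == []

    def test_first_line_title_round_trip(self, tmp_path):
        raw = "A title line\nThe abstract body."
        p = tmp_path / "doc.txt"
        p.write_text(raw, encoding="utf-8")
        doc = corpus_io.read_plain_text(p, "d1", first_line_title=True)
        names = [s.name for s in doc.sections]
        assert names == [SectionName.TITLE, SectionName.ABSTRACT]
        assert doc.sections[0].text + "\n" + doc.sections[1].text == raw

    def test_undecodable_bytes_raise_format_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_bytes(b"\xff\xfe\x00 garbage \x80")
        with pytest.raises(corpus_io.FormatError):
            corpus_io.read_plain_text(p, "d1")


MEDLINE_SAMPLE = """\
PMID- 1001
TI  - Phosphorylation of p53 by CK2.
AB  - CK2 phosphorylates p53 at Ser-20.
PT  - Journal Article
PT  - Review

PMID- 1002
TI  - A kinase study.
AB  - PKA is inactive here.
PT  - Journal Article

TI  - Record without an id.
AB  - This one is skipped.

PMID- 1003
TI  - Third record.
AB  - Nothing to see.
"""


class TestMedline:
    def test_pub_types_loaded(self):
        docs = corpus_io.read_medline_records(io.StringIO(MEDLINE_SAMPLE))
        assert "Review" in docs[0].pub_types

    def test_empty_collection(self):
        assert corpus_io.read_medline_records(io.StringIO("")) == []

    def test_missing_id_skipped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="phosphomine.corpus_io"):
            docs = corpus_io.read_medline_records(io.StringIO(MEDLINE_SAMPLE))
        assert [d.doc_id for d in docs] == ["1001", "1002", "1003"]
        assert sum("PMID" in r.message for r in caplog.records) == 1


class TestBioC:
    def test_round_trip_identity_on_golden(self, golden_annotated):
        annotated, _ = golden_annotated
        payload = corpus_io.write_bioc(annotated)
        back = corpus_io.read_bioc(payload)
        for a, b in zip(annotated, back):
            assert a.document == b.document
            assert a.events == b.events
            assert a.mentions == b.mentions

    def test_one_event_three_annotations_one_relation(self, golden_annotated):
        from lxml import etree

        annotated, _ = golden_annotated
        crm1 = [a for a in annotated if a.document.doc_id == "23729730"]
        root = etree.fromstring(corpus_io.write_bioc(crm1))
        anns = root.findall(".//annotation")
        event_anns = [
            a for a in anns
            if a.find("infon[@key='type']").text in ("kinase", "substrate", "site")
        ]
        assert len(event_anns) == 3
        assert len(root.findall(".//relation")) == 1

    def test_golden_annotation_texts(self, golden_annotated):
        annotated, _ = golden_annotated
        payload = corpus_io.write_bioc(annotated).decode()
        for text in ("CDK1-cyclin-B", "Crm1", "serine 391"):
            assert f"<text>{text}</text>" in payload

    def test_zero_events_valid_passage(self):
        doc = Document("99", (Section(SectionName.ABSTRACT, "Nothing here."),))
        adoc = annotate_document(doc)
        back = corpus_io.read_bioc(corpus_io.write_bioc([adoc]))
        assert back[0].document == doc
        assert back[0].events == []

    def test_annotation_offsets_address_text(self, golden_annotated):
        from lxml import etree

        annotated, _ = golden_annotated
        root = etree.fromstring(corpus_io.write_bioc(annotated))
        for xdoc in root.findall("document"):
            full = {}
            for xpass in xdoc.findall("passage"):
                offset = int(xpass.findtext("offset"))
                full[offset] = xpass.findtext("text") or ""
            for ann in xdoc.findall(".//annotation"):
                loc = ann.find("location")
                start = int(loc.get("offset"))
                length = int(loc.get("length"))
                base = max(o for o in full if o <= start)
                text = full[base][start - base:start - base + length]
                assert text == ann.findtext("text")

    def test_invalid_xml_raises_format_error(self):
        with pytest.raises(corpus_io.FormatError):
            corpus_io.read_bioc(b"<collection><document>")


def _row(doc_id="23729730", kinase="CDK1-cyclin-B", substrate="Crm1",
         sites=("Ser-391",), sentences=(CRM1,)):
    evidence = tuple(
        Sentence(doc_id, SectionName.ABSTRACT, i, (0, len(t)), t)
        for i, t in enumerate(sentences)
    )
    return SummaryRow(doc_id, kinase, substrate, tuple(sites), len(evidence),
                      evidence, frozenset({SectionName.ABSTRACT}))


class TestCsv:
    def test_crm1_row(self):
        import csv

        text = corpus_io.write_csv([_row()])
        rows = list(csv.reader(io.StringIO(text)))
        assert rows[0] == corpus_io.CSV_HEADER
        assert rows[1] == ["23729730", "CDK1-cyclin-B", "Crm1", "Ser-391", CRM1]

    def test_empty_rows_header_only(self):
        assert corpus_io.write_csv([]).strip() == ",".join(corpus_io.CSV_HEADER)

    def test_two_sites_joined_in_input_order(self):
        import csv

        text = corpus_io.write_csv([_row(sites=("Ser-64", "Ser-181"))])
        rows = list(csv.reader(io.StringIO(text)))
        assert rows[1][3] == "Ser-64; Ser-181"

    def test_row_and_column_counts(self, small_corpus):
        import csv

        docs, _ = small_corpus
        all_rows = [
            r for d in docs[:30] for r in annotate_document(d).summary
        ]
        parsed = list(csv.reader(io.StringIO(corpus_io.write_csv(all_rows))))
        assert len(parsed) == len(all_rows) + 1
        assert all(len(r) == len(corpus_io.CSV_HEADER) for r in parsed)

    def test_annotations_from_csv_round_trip(self):
        text = corpus_io.write_csv(
            [_row(), _row(kinase="FLT3", substrate="beta-catenin",
                          sites=("Tyr-654",), doc_id="22126602")]
        )
        ann = corpus_io.annotations_from_csv(io.StringIO(text))
        assert ann["kinase"]["23729730"] == {"CDK1-cyclin-B"}
        assert ann["site"]["22126602"] == {"Tyr-654"}

    def test_rejected_status_rows_excluded(self):
        csv_text = (
            "pmid,kinase,substrate,site,status\n"
            "1,CK2,p53,Ser-20,validated\n"
            "1,PKA,p53,,rejected\n"
        )
        ann = corpus_io.annotations_from_csv(io.StringIO(csv_text))
        assert ann["kinase"]["1"] == {"CK2"}
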