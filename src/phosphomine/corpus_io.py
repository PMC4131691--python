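"""Readers and writers for every format the tool touches.

Formats: plain-text abstracts (UTF-8), MEDLINE/nbib records (via
Bio.Medline), BioC XML collections (via lxml) and RFC-4180 CSV summaries.
Offsets in BioC output follow the passage-offset convention: each
annotation's location is absolute within the document (cumulative passage
offset + section-relative span), and every written annotation satisfies
``text[offset:offset+length] == annotation.text``.
"""

from __future__ import annotations

import csv
import io
import logging
from pathlib import Path
from typing import Dict, IO, Iterable, List, Optional, Sequence, Set, Union

from Bio import Medline
from lxml import etree

from .model import (
    AnnotatedDocument,
    Category,
    Document,
    EntityMention,
    PhosphoEvent,
    Residue,
    Section,
    SectionName,
    Sentence,
    SiteKind,
    SiteSpec,
    SummaryRow,
)

logger = logging.getLogger(__name__)

#: Delimiter for multi-valued CSV cells (inside standard CSV quoting).
CSV_DELIMITER = "; "

CSV_HEADER = ["pmid", "kinase", "substrate", "site", "evidence_sentences"]


class FormatError(ValueError):
    """Raised when an input stream cannot be parsed as the expected format."""


# ---------------------------------------------------------------------------
# plain text

def read_plain_text(
    source: Union[str, Path, IO[str]],
    doc_id: str,
    first_line_title: bool = False,
) -> Document:
    """Read a plain-text abstract as a single Document.

    With ``first_line_title`` the first line becomes the TITLE section and
    the remainder the ABSTRACT; otherwise the whole input is one ABSTRACT
    section.
    """
    if isinstance(source, (str, Path)):
        try:
            text = Path(source).read_text(encoding="utf-8")
        except UnicodeDecodeError as exc:
            raise FormatError(f"{source}: not valid UTF-8") from exc
    else:
        text = source.read()
    if first_line_title and "\n" in text:
        title, rest = text.split("\n", 1)
        sections = (
            Section(SectionName.TITLE, title),
            Section(SectionName.ABSTRACT, rest),
        )
    else:
        sections = (Section(SectionName.ABSTRACT, text),)
    return Document(doc_id, sections)


# ---------------------------------------------------------------------------
# MEDLINE records

#: Case-insensitive heading -> section mapping for full-text inputs.
_SECTION_HEADINGS = {
    "title": SectionName.TITLE,
    "abstract": SectionName.ABSTRACT,
    "results": SectionName.RESULTS,
    "figure legend": SectionName.FIGURE_LEGEND,
    "figure legends": SectionName.FIGURE_LEGEND,
    "fig. legend": SectionName.FIGURE_LEGEND,
    "discussion": SectionName.DISCUSSION,
}


def section_name_for(heading: str) -> SectionName:
    return _SECTION_HEADINGS.get(heading.strip().lower(), SectionName.OTHER)


def read_medline_records(stream: IO[str]) -> List[Document]:
    """Parse MEDLINE/nbib-format records into Documents.

    One Document per record with TITLE and ABSTRACT sections; publication
    types (PT lines) are kept so review filtering is possible. Records
    missing a PMID are skipped with a logged warning.
    """
    documents: List[Document] = []
    try:
        records = list(Medline.parse(stream))
    except Exception as exc:  # malformed container
        raise FormatError(f"cannot parse MEDLINE input: {exc}") from exc
    for record in records:
        pmid = record.get("PMID")
        if not pmid:
            logger.warning("skipping MEDLINE record without PMID: %r",
                           record.get("TI", "<no title>"))
            continue
        sections = []
        if record.get("TI"):
            sections.append(Section(SectionName.TITLE, record["TI"]))
        sections.append(Section(SectionName.ABSTRACT, record.get("AB", "")))
        documents.append(
            Document(pmid, tuple(sections), tuple(record.get("PT", [])))
        )
    return documents


# ---------------------------------------------------------------------------
# BioC XML

def _sentence_infons(sentence: Sentence) -> str:
    return "|".join(
        [sentence.section_name.value, str(sentence.index),
         str(sentence.span[0]), str(sentence.span[1])]
    )


def _sentence_from_infon(value: str, document: Document) -> Sentence:
    section_name, index, start, end = value.split("|")
    name = SectionName[section_name]
    section = document.get_section(name)
    text = section.text[int(start):int(end)] if section else ""
    return Sentence(document.doc_id, name, int(index), (int(start), int(end)), text)


def _site_infons(spec: SiteSpec) -> Dict[str, str]:
    return {
        "site_kind": spec.kind.value,
        "residue": spec.residue.name,
        "position": "" if spec.position is None else str(spec.position),
        "region_text": spec.region_text or "",
    }


def _site_from_infons(infons: Dict[str, str], surface: str) -> SiteSpec:
    return SiteSpec(
        kind=SiteKind[infons["site_kind"]],
        residue=Residue[infons["residue"]],
        position=int(infons["position"]) if infons.get("position") else None,
        region_text=infons.get("region_text") or None,
        surface=surface,
    )


def write_bioc(
    annotated_docs: Sequence[AnnotatedDocument], stream: Optional[IO[bytes]] = None
) -> bytes:
    """Serialize annotated documents as one BioC collection.

    Each event becomes one <relation> whose nodes reference the slot
    annotations (kinase, substrate, site); the trigger and sentence
    provenance travel as relation infons. ``write_bioc`` then
    ``read_bioc`` is the identity on documents, mentions and events.
    """
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = "phosphomine"
    etree.SubElement(root, "date").text = ""
    etree.SubElement(root, "key").text = "phosphomine.key"
    for adoc in annotated_docs:
        doc = adoc.document
        xdoc = etree.SubElement(root, "document")
        etree.SubElement(xdoc, "id").text = doc.doc_id
        if doc.pub_types:
            _infon(xdoc, "pub_types", "|".join(doc.pub_types))
        offsets: Dict[SectionName, int] = {}
        cumulative = 0
        for section in doc.sections:
            xpass = etree.SubElement(xdoc, "passage")
            _infon(xpass, "section", section.name.value)
            etree.SubElement(xpass, "offset").text = str(cumulative)
            offsets.setdefault(section.name, cumulative)
            etree.SubElement(xpass, "text").text = section.text
            cumulative += len(section.text) + 1  # +1: virtual newline joiner
        passages = xdoc.findall("passage")
        by_section = {
            p.find("infon[@key='section']").text: p for p in passages
        }

        counter = [0]

        def add_annotation(section_name: SectionName, span, text, infons):
            xpass = by_section[section_name.value]
            ann = etree.SubElement(xpass, "annotation",
                                   id=f"A{counter[0]}")
            counter[0] += 1
            for k, v in infons.items():
                _infon(ann, k, v)
            etree.SubElement(
                ann, "location",
                offset=str(offsets[section_name] + span[0]),
                length=str(span[1] - span[0]),
            )
            etree.SubElement(ann, "text").text = text
            return ann.get("id")

        for mention in adoc.mentions:
            add_annotation(
                mention.sentence.section_name, mention.span, mention.text,
                {
                    "type": "mention",
                    "category": mention.category.value,
                    "rule": mention.rule,
                    "sentence": _sentence_infons(mention.sentence),
                },
            )
        for ei, event in enumerate(adoc.events):
            nodes = []
            for role, mention in (("kinase", event.kinase),
                                  ("substrate", event.substrate)):
                if mention is None:
                    continue
                aid = add_annotation(
                    mention.sentence.section_name, mention.span, mention.text,
                    {
                        "type": role,
                        "category": mention.category.value,
                        "rule": mention.rule,
                        "sentence": _sentence_infons(mention.sentence),
                    },
                )
                nodes.append((role, aid))
            sent0 = event.sentence_refs[0]
            for si, spec in enumerate(event.sites):
                surface = spec.surface or spec.normalized()
                pos = sent0.text.find(surface)
                span = (
                    (sent0.span[0] + pos, sent0.span[0] + pos + len(surface))
                    if pos >= 0
                    else event.trigger
                )
                text = surface if pos >= 0 else event.trigger_text
                infons = {"type": "site", "sentence": _sentence_infons(sent0),
                          "surface": spec.surface}
                infons.update(_site_infons(spec))
                aid = add_annotation(sent0.section_name, span, text, infons)
                nodes.append(("site", aid))
            xpass = by_section[sent0.section_name.value]
            rel = etree.SubElement(xpass, "relation", id=f"R{ei}")
            _infon(rel, "type", "phosphorylation")
            _infon(rel, "pattern_id", event.pattern_id)
            _infon(rel, "trigger_start", str(event.trigger[0]))
            _infon(rel, "trigger_end", str(event.trigger[1]))
            _infon(rel, "trigger_text", event.trigger_text)
            if event.anaphors:
                _infon(rel, "anaphors", "|".join(event.anaphors))
            for si, sent in enumerate(event.sentence_refs):
                _infon(rel, f"sentence:{si}", _sentence_infons(sent))
            for role, aid in nodes:
                etree.SubElement(rel, "node", refid=aid, role=role)
    payload = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    if stream is not None:
        stream.write(payload)
    return payload


def _infon(parent, key: str, value: str) -> None:
    el = etree.SubElement(parent, "infon", key=key)
    el.text = value


def _infon_map(element) -> Dict[str, str]:
    return {
        i.get("key"): (i.text or "") for i in element.findall("infon")
    }


def read_bioc(source: Union[bytes, IO[bytes]]) -> List[AnnotatedDocument]:
    """Parse a BioC collection written by :func:`write_bioc`."""
    if isinstance(source, bytes):
        data = source
    else:
        data = source.read()
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"invalid BioC XML: {exc}") from exc
    out: List[AnnotatedDocument] = []
    for idx, xdoc in enumerate(root.findall("document")):
        try:
            out.append(_read_bioc_document(xdoc))
        except Exception as exc:
            raise FormatError(f"document {idx}: {exc}") from exc
    return out


def _read_bioc_document(xdoc) -> AnnotatedDocument:
    doc_id = xdoc.findtext("id")
    doc_infons = _infon_map(xdoc)
    pub_types = tuple(
        p for p in doc_infons.get("pub_types", "").split("|") if p
    )
    sections = []
    passage_offsets: Dict[str, int] = {}
    for xpass in xdoc.findall("passage"):
        infons = _infon_map(xpass)
        name = infons["section"]
        offset = int(xpass.findtext("offset"))
        text = xpass.findtext("text") or ""
        sections.append(Section(SectionName[name], text))
        passage_offsets.setdefault(name, offset)
    document = Document(doc_id, tuple(sections), pub_types)

    annotations: Dict[str, Dict] = {}
    mentions: List[EntityMention] = []
    for xpass in xdoc.findall("passage"):
        name = _infon_map(xpass)["section"]
        base = passage_offsets[name]
        for ann in xpass.findall("annotation"):
            infons = _infon_map(ann)
            loc = ann.find("location")
            start = int(loc.get("offset")) - base
            end = start + int(loc.get("length"))
            record = {
                "infons": infons,
                "span": (start, end),
                "text": ann.findtext("text") or "",
            }
            annotations[ann.get("id")] = record
            if infons.get("type") == "mention":
                mentions.append(_mention_from_record(record, document))

    events: List[PhosphoEvent] = []
    for xpass in xdoc.findall("passage"):
        for rel in xpass.findall("relation"):
            infons = _infon_map(rel)
            kinase = substrate = None
            sites: List[SiteSpec] = []
            for node in rel.findall("node"):
                record = annotations[node.get("refid")]
                role = node.get("role")
                if role == "kinase":
                    kinase = _mention_from_record(record, document)
                elif role == "substrate":
                    substrate = _mention_from_record(record, document)
                elif role == "site":
                    sites.append(
                        _site_from_infons(record["infons"],
                                          record["infons"].get("surface", ""))
                    )
            refs = []
            si = 0
            while f"sentence:{si}" in infons:
                refs.append(
                    _sentence_from_infon(infons[f"sentence:{si}"], document)
                )
                si += 1
            events.append(
                PhosphoEvent(
                    kinase=kinase,
                    substrate=substrate,
                    sites=tuple(sites),
                    trigger=(int(infons["trigger_start"]),
                             int(infons["trigger_end"])),
                    trigger_text=infons["trigger_text"],
                    sentence_refs=tuple(refs),
                    pattern_id=infons["pattern_id"],
                    anaphors=tuple(
                        a for a in infons.get("anaphors", "").split("|") if a
                    ),
                )
            )
    return AnnotatedDocument(document, events, mentions, [])


def _mention_from_record(record: Dict, document: Document) -> EntityMention:
    infons = record["infons"]
    return EntityMention(
        category=Category[infons["category"]],
        span=record["span"],
        text=record["text"],
        sentence=_sentence_from_infon(infons["sentence"], document),
        rule=infons.get("rule", ""),
    )


# ---------------------------------------------------------------------------
# CSV

def write_csv(
    summary_rows: Sequence[SummaryRow], stream: Optional[IO[str]] = None
) -> str:
    """Write summary rows as RFC-4180 CSV.

    Multi-valued cells (sites, evidence sentences) are joined with
    ``"; "`` inside one quoted cell, in input order.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for row in summary_rows:
        writer.writerow([
            row.doc_id,
            row.kinase_text,
            row.substrate_text,
            CSV_DELIMITER.join(row.site_texts),
            CSV_DELIMITER.join(s.text for s in row.evidence),
        ])
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def annotations_from_csv(stream: IO[str]) -> Dict[str, Dict[str, Set[str]]]:
    """Read a summary/gold CSV into per-slot document-level annotation sets.

    Accepts the :func:`write_csv` schema plus an optional ``status``
    column (validated / rejected / added); rejected rows are excluded.
    Multi-valued cells are split on the documented delimiter.
    """
    reader = csv.DictReader(stream)
    if reader.fieldnames is None or "pmid" not in reader.fieldnames:
        raise FormatError("CSV must have a 'pmid' column")
    out: Dict[str, Dict[str, Set[str]]] = {s: {} for s in ("kinase", "substrate", "site")}
    for row in reader:
        status = (row.get("status") or "").strip().lower()
        if status == "rejected":
            continue
        pmid = row["pmid"]
        for slot in ("kinase", "substrate", "site"):
            bucket = out[slot].setdefault(pmid, set())
            cell = row.get(slot) or ""
            for value in cell.split(CSV_DELIMITER):
                value = value.strip()
                if value:
                    bucket.add(value)
    return out
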