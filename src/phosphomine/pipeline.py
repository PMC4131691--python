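"""End-to-end composition: document in, annotated document out."""

from __future__ import annotations

from typing import List, Sequence

from .document_assembly import (
    collapse_annotations,
    link_cross_sentence,
    select_sections,
)
from .event_extraction import (
    DEFAULT_CONFIG,
    ExtractionConfig,
    extract_document_events,
)
from .linguistic_preprocess import preprocess_sentence, split_sentences
from .model import AnnotatedDocument, Document, TriageResult
from .term_classifier import classify_chunks, detect_species
from .triage import classify_document


def annotate_document(
    document: Document, config: ExtractionConfig = DEFAULT_CONFIG
) -> AnnotatedDocument:
    """Run extraction, cross-sentence linking and collapsing on one
    document; also annotates NP mentions and species for the evidence
    view."""
    doc = select_sections(document, abstracts_only=config.abstracts_only)
    events = link_cross_sentence(extract_document_events(doc, config), doc)
    summary = collapse_annotations(events)
    mentions = []
    for section in doc.sections:
        for sentence in split_sentences(section.text, doc.doc_id, section.name):
            tokens, chunks = preprocess_sentence(
                sentence.text, offset=sentence.span[0]
            )
            mentions.extend(classify_chunks(tokens, chunks, sentence))
    mentions.extend(detect_species(doc))
    return AnnotatedDocument(doc, list(events), mentions, list(summary))


def triage_documents(
    documents: Sequence[Document], config: ExtractionConfig = DEFAULT_CONFIG
) -> List[TriageResult]:
    out = []
    for doc in documents:
        events = link_cross_sentence(extract_document_events(doc, config), doc)
        out.append(classify_document(doc, events))
    return out
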