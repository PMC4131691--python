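"""Document-level assembly: cross-sentence linking, redundancy collapsing,
section filtering.

Collapsing is deliberately surface-based: textual variants of the same
protein (FLT3 vs FLT3/ITD) stay distinct rows, mirroring how a curator is
expected to merge them manually. Rows with kinase, substrate and site all
filled sort first.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    Category,
    Document,
    EntityMention,
    PhosphoEvent,
    PROTEIN_LIKE,
    RELEVANT_SECTIONS,
    SectionName,
    Sentence,
    SummaryRow,
)

#: Anaphora resolution window, in sentences, same section only.
ANAPHORA_WINDOW = 2


def _sentence_pos(sentence: Sentence) -> Tuple[str, int]:
    return (sentence.section_name.value, sentence.index)


def _within_window(a: Sentence, b: Sentence, window: int = ANAPHORA_WINDOW) -> bool:
    return (
        a.section_name is b.section_name
        and abs(a.index - b.index) <= window
    )


def link_cross_sentence(
    events: Sequence[PhosphoEvent], document: Document
) -> List[PhosphoEvent]:
    """Resolve anaphoric slots and inherit missing substrates across
    sentences.

    Heuristics, applied in document order:
      (a) an event whose only handle on a slot is an anaphor ("this
          residue", "the enzyme") is merged into / resolved against the
          nearest preceding event (site anaphor) or protein-compatible
          slot (kinase/substrate anaphor) within the window;
      (b) an event lacking a substrate inherits the substrate of the
          nearest preceding event in the same section within the window;
      (c) merged events append their evidence sentences.
    """
    ordered = sorted(events, key=lambda e: _sentence_pos(e.sentence_refs[0]))
    resolved: List[PhosphoEvent] = []
    for ev in ordered:
        ev = _resolve_anaphors(ev, resolved)
        if ev is None:
            continue
        resolved.append(ev)
    # (b) substrate inheritance
    out: List[PhosphoEvent] = []
    for i, ev in enumerate(resolved):
        if ev.substrate is None:
            donor = None
            for prev in reversed(out):
                if prev.substrate is None:
                    continue
                if _within_window(prev.sentence_refs[-1], ev.sentence_refs[0]):
                    donor = prev
                    break
            if donor is not None:
                ev = ev.with_(substrate=donor.substrate)
        out.append(ev)
    return out


def _resolve_anaphors(
    ev: PhosphoEvent, resolved: List[PhosphoEvent]
) -> Optional[PhosphoEvent]:
    if not ev.anaphors:
        return ev
    remaining = list(ev.anaphors)
    for kind in list(remaining):
        antecedent = None
        for j in range(len(resolved) - 1, -1, -1):
            prev = resolved[j]
            if not _within_window(prev.sentence_refs[-1], ev.sentence_refs[0]):
                continue
            if kind == "site" and prev.sites:
                antecedent = j
                break
            if kind == "substrate" and prev.substrate is not None:
                antecedent = j
                break
            if kind == "kinase" and prev.kinase is not None:
                antecedent = j
                break
        if antecedent is None:
            continue
        prev = resolved[antecedent]
        remaining.remove(kind)
        if kind == "site":
            # the event talks about an already-introduced site: merge into
            # the antecedent event, contributing any new slots
            merged = prev.with_(
                kinase=prev.kinase or ev.kinase,
                substrate=prev.substrate or ev.substrate,
                sites=tuple(
                    list(prev.sites)
                    + [s for s in ev.sites if s not in prev.sites]
                ),
                sentence_refs=_merge_refs(prev.sentence_refs, ev.sentence_refs),
            )
            # the current event has been folded into its antecedent
            resolved[antecedent] = merged
            return None
        if kind == "substrate":
            ev = ev.with_(substrate=prev.substrate, anaphors=tuple(remaining))
        elif kind == "kinase":
            ev = ev.with_(kinase=prev.kinase, anaphors=tuple(remaining))
    ev = ev.with_(anaphors=tuple(remaining))
    if ev.kinase is None and ev.substrate is None:
        return None
    return ev


def _merge_refs(
    a: Tuple[Sentence, ...], b: Tuple[Sentence, ...]
) -> Tuple[Sentence, ...]:
    merged = list(a)
    for s in b:
        if s not in merged:
            merged.append(s)
    merged.sort(key=_sentence_pos)
    return tuple(merged)


# ---------------------------------------------------------------------------
# collapsing

def _normalize_ws(text: str) -> str:
    return " ".join(text.split())


def _site_key(event: PhosphoEvent) -> Tuple[str, ...]:
    # dedupe by normalized form so "S64" and "Ser-64" collapse together
    by_key = {s.key(): s for s in event.sites}
    return tuple(s.normalized() for _, s in sorted(by_key.items()))


def collapse_annotations(events: Sequence[PhosphoEvent]) -> List[SummaryRow]:
    """Collapse identical (kinase, substrate, site set) tuples into one row.

    Grouping is by exact surface strings after whitespace normalization
    (case-sensitive, no synonym merging) and by the normalized site list.
    Complete rows (all three slots filled) sort first; ties keep
    first-evidence document order.
    """
    groups: Dict[Tuple, List[PhosphoEvent]] = {}
    order: List[Tuple] = []
    for ev in events:
        key = (
            _normalize_ws(ev.kinase.text) if ev.kinase else "",
            _normalize_ws(ev.substrate.text) if ev.substrate else "",
            _site_key(ev),
        )
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(ev)

    rows: List[SummaryRow] = []
    for key in order:
        evs = groups[key]
        evidence: List[Sentence] = []
        for ev in evs:
            for s in ev.sentence_refs:
                if s not in evidence:
                    evidence.append(s)
        evidence.sort(key=_sentence_pos)
        doc_id = evs[0].sentence_refs[0].doc_id
        rows.append(
            SummaryRow(
                doc_id=doc_id,
                kinase_text=key[0],
                substrate_text=key[1],
                site_texts=key[2],
                sentence_count=len(evidence),
                evidence=tuple(evidence),
                sections=frozenset(s.section_name for s in evidence),
            )
        )
    rows.sort(
        key=lambda r: (
            0 if r.complete else 1,
            _sentence_pos(r.evidence[0]) if r.evidence else ("", 0),
        )
    )
    return rows


def collapse_rows(rows: Sequence[SummaryRow]) -> List[SummaryRow]:
    """Idempotent re-collapse of already-built rows (merges equal keys)."""
    merged: Dict[Tuple, SummaryRow] = {}
    order = []
    for row in rows:
        key = (row.kinase_text, row.substrate_text, row.site_texts)
        if key in merged:
            old = merged[key]
            evidence = list(old.evidence)
            for s in row.evidence:
                if s not in evidence:
                    evidence.append(s)
            evidence.sort(key=_sentence_pos)
            merged[key] = SummaryRow(
                old.doc_id, old.kinase_text, old.substrate_text, old.site_texts,
                len(evidence), tuple(evidence),
                old.sections | row.sections,
            )
        else:
            merged[key] = row
            order.append(key)
    out = [merged[k] for k in order]
    out.sort(
        key=lambda r: (
            0 if r.complete else 1,
            _sentence_pos(r.evidence[0]) if r.evidence else ("", 0),
        )
    )
    return out


# ---------------------------------------------------------------------------
# section filtering

def select_sections(document: Document, abstracts_only: bool = False) -> Document:
    """Keep title/abstract plus the experimentally relevant full-text
    sections (Results, Figure legend, Discussion); drop the rest."""
    keep = (
        {SectionName.TITLE, SectionName.ABSTRACT}
        if abstracts_only
        else RELEVANT_SECTIONS
    )
    sections = tuple(s for s in document.sections if s.name in keep)
    if sections == document.sections:
        return document
    return Document(document.doc_id, sections, document.pub_types)
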