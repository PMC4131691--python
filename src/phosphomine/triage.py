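"""Document-level relevance filtering and PubMed query construction.

A document is *potential* when a phosphorylation trigger word occurs in
its title or abstract (the same pre-filter used to build the back-end
database), and *positive* when extraction additionally finds at least one
substrate. Query construction is pure string building; executing queries
against NCBI is out of scope, which keeps the package fully offline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import Document, PhosphoEvent, SectionName, TriageResult
from .resources import resource_lines
from .event_extraction import load_triggers


def _trigger_patterns(directory=None) -> List[Tuple[str, re.Pattern]]:
    pats = []
    for word in load_triggers(directory):
        # phrases tolerate an intervening hyphen or space between words
        escaped = r"[-\s]".join(re.escape(w) for w in word.split())
        pats.append(
            (word, re.compile(rf"\b{escaped}\b", re.IGNORECASE))
        )
    return pats


_cached_patterns: Optional[List[Tuple[str, re.Pattern]]] = None


def _patterns() -> List[Tuple[str, re.Pattern]]:
    global _cached_patterns
    if _cached_patterns is None:
        _cached_patterns = _trigger_patterns()
    return _cached_patterns


def has_trigger(document: Document) -> TriageResult:
    """Case-insensitive whole-word trigger match over TITLE and ABSTRACT
    only; other sections are not consulted."""
    text = " ".join(
        s.text for s in document.sections
        if s.name in (SectionName.TITLE, SectionName.ABSTRACT)
    )
    matched = tuple(
        word for word, pat in _patterns() if pat.search(text)
    )
    return TriageResult(
        doc_id=document.doc_id,
        potential=bool(matched),
        positive=False,
        matched_triggers=matched,
    )


def classify_document(
    document: Document, events: Sequence[PhosphoEvent]
) -> TriageResult:
    """Positive iff the document is potential and at least one extracted
    event has its substrate slot filled."""
    base = has_trigger(document)
    positive = base.potential and any(ev.substrate is not None for ev in events)
    return TriageResult(
        doc_id=base.doc_id,
        potential=base.potential,
        positive=positive,
        matched_triggers=base.matched_triggers,
    )


def filter_reviews(documents: Sequence[Document]) -> List[Document]:
    """Drop documents whose publication types include "Review"."""
    return [
        d for d in documents
        if not any(pt.lower() == "review" for pt in d.pub_types)
    ]


# ---------------------------------------------------------------------------
# PubMed query construction

@dataclass(frozen=True)
class SpeciesEntry:
    key: str
    mesh: str
    synonyms: Tuple[str, ...]


def load_species_table(directory=None) -> Dict[str, SpeciesEntry]:
    table = {}
    for line in resource_lines("species_query.tsv", directory):
        key, mesh, syns = line.split("\t")
        table[key] = SpeciesEntry(key, mesh, tuple(syns.split("|")))
    return table


@dataclass(frozen=True)
class QuerySpec:
    user_query: str
    species: Tuple[str, ...] = ()
    exclude_reviews: bool = False
    abstracts_only: bool = False

    def __post_init__(self) -> None:
        if not self.user_query:
            raise ValueError("user_query must be non-empty")


def build_pubmed_query(spec: QuerySpec, directory=None) -> str:
    """Render the exact PubMed query template used by the online service.

    Human example: ``user_query[TIAB] AND (Homo sapiens [TIAB] OR human
    [TIAB] OR Modern Man [TIAB] OR Humans [MeSH Terms])``; review
    exclusion appends `` AND NOT Review [PT]``.
    """
    table = load_species_table(directory)
    query = f"{spec.user_query}[TIAB]"
    if spec.species:
        terms: List[str] = []
        for key in spec.species:
            entry = table.get(key.lower())
            if entry is None:
                raise KeyError(f"unknown species key: {key!r}")
            terms.extend(f"{syn} [TIAB]" for syn in entry.synonyms)
            terms.append(f"{entry.mesh} [MeSH Terms]")
        query += " AND (" + " OR ".join(terms) + ")"
    if spec.exclude_reviews:
        query += " AND NOT Review [PT]"
    return query
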