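"""Core domain types shared across the pipeline.

All character offsets are 0-based, half-open, counted in Unicode code
points, and relative to the text of the *section* they address. A span
``(start, end)`` recorded on a token, mention or trigger always satisfies
``section_text[start:end] == recorded_text``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple


class SectionName(enum.Enum):
    TITLE = "TITLE"
    ABSTRACT = "ABSTRACT"
    RESULTS = "RESULTS"
    FIGURE_LEGEND = "FIGURE_LEGEND"
    DISCUSSION = "DISCUSSION"
    OTHER = "OTHER"


#: Sections shown for full-text articles: title/abstract plus the sections
#: most relevant to experimental results.
RELEVANT_SECTIONS = frozenset(
    {
        SectionName.TITLE,
        SectionName.ABSTRACT,
        SectionName.RESULTS,
        SectionName.FIGURE_LEGEND,
        SectionName.DISCUSSION,
    }
)


@dataclass(frozen=True)
class Section:
    name: SectionName
    text: str


@dataclass(frozen=True)
class Document:
    """One identified text unit (abstract or full-text article)."""

    doc_id: str
    sections: Tuple[Section, ...]
    pub_types: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        object.__setattr__(self, "sections", tuple(self.sections))
        object.__setattr__(self, "pub_types", tuple(self.pub_types))

    def section_text(self, name: SectionName) -> str:
        """Concatenated text of all sections with the given name."""
        return " ".join(s.text for s in self.sections if s.name == name)

    def get_section(self, name: SectionName) -> Optional[Section]:
        for s in self.sections:
            if s.name == name:
                return s
        return None


@dataclass(frozen=True)
class Sentence:
    """A sentence located inside one section of a document."""

    doc_id: str
    section_name: SectionName
    index: int
    span: Tuple[int, int]
    text: str

    def sort_key(self) -> Tuple[str, int]:
        return (self.section_name.value, self.index)


class Category(enum.Enum):
    PROTEIN = "PROTEIN"
    PROTEIN_COMPLEX = "PROTEIN_COMPLEX"
    PROTEIN_FAMILY = "PROTEIN_FAMILY"
    PROTEIN_PART = "PROTEIN_PART"
    CHEMICAL = "CHEMICAL"
    SITE = "SITE"
    SPECIES = "SPECIES"
    OTHER = "OTHER"


#: Categories acceptable as kinase or substrate slot fillers.
PROTEIN_LIKE = frozenset(
    {Category.PROTEIN, Category.PROTEIN_COMPLEX, Category.PROTEIN_FAMILY}
)


@dataclass(frozen=True)
class EntityMention:
    category: Category
    span: Tuple[int, int]
    text: str
    sentence: Sentence
    rule: str = ""  # id of the classification rule that fired (audit trail)

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("mention text must be non-empty")


class SiteKind(enum.Enum):
    RESIDUE_POSITION = "RESIDUE_POSITION"
    RESIDUE_TYPE = "RESIDUE_TYPE"
    REGION = "REGION"


class Residue(enum.Enum):
    SER = "Ser"
    THR = "Thr"
    TYR = "Tyr"
    OTHER_AA = "Other"
    NONE = "None"


_RESIDUE_FULL = {
    Residue.SER: "Serine",
    Residue.THR: "Threonine",
    Residue.TYR: "Tyrosine",
    Residue.OTHER_AA: "Residue",
}


@dataclass(frozen=True)
class SiteSpec:
    """A normalized phosphorylation site.

    The most specific available form is kept: a residue with a position
    (Ser-391), a bare residue type (serine), or a protein region/domain
    (C-terminal domain).
    """

    kind: SiteKind
    residue: Residue = Residue.NONE
    position: Optional[int] = None
    region_text: Optional[str] = None
    surface: str = ""

    def __post_init__(self) -> None:
        if self.kind is SiteKind.RESIDUE_POSITION:
            if self.residue is Residue.NONE or self.position is None:
                raise ValueError("RESIDUE_POSITION requires residue and position")
            if self.position <= 0:
                raise ValueError("position must be positive")
        elif self.kind is SiteKind.RESIDUE_TYPE:
            if self.position is not None:
                raise ValueError("RESIDUE_TYPE carries no position")
            if self.residue is Residue.NONE:
                raise ValueError("RESIDUE_TYPE requires a residue")
        elif self.kind is SiteKind.REGION:
            if not self.region_text:
                raise ValueError("REGION requires region_text")

    def normalized(self) -> str:
        """Canonical display/grouping form: 'Ser-391', 'Serine', region text."""
        if self.kind is SiteKind.RESIDUE_POSITION:
            return f"{self.residue.value}-{self.position}"
        if self.kind is SiteKind.RESIDUE_TYPE:
            return _RESIDUE_FULL[self.residue]
        return self.region_text or ""

    def key(self) -> Tuple:
        if self.kind is SiteKind.RESIDUE_POSITION:
            return (0, self.position, self.residue.value)
        if self.kind is SiteKind.RESIDUE_TYPE:
            return (1, 0, self.residue.value)
        return (2, 0, self.region_text or "")


@dataclass(frozen=True)
class PhosphoEvent:
    """One extracted phosphorylation assertion.

    At least one of kinase/substrate is present. ``anaphors`` records
    unresolved anaphoric slot fillers ("this residue", "the enzyme") seen
    at extraction time; document assembly consumes them.
    """

    kinase: Optional[EntityMention]
    substrate: Optional[EntityMention]
    sites: Tuple[SiteSpec, ...]
    trigger: Tuple[int, int]
    trigger_text: str
    sentence_refs: Tuple[Sentence, ...]
    pattern_id: str
    anaphors: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kinase is None and self.substrate is None and not self.anaphors:
            raise ValueError("event needs a kinase, a substrate, or an anaphor")
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "sentence_refs", tuple(self.sentence_refs))

    def with_(self, **kw) -> "PhosphoEvent":
        return replace(self, **kw)


@dataclass(frozen=True)
class SummaryRow:
    """Document-level collapsed (kinase, substrate, sites) tuple."""

    doc_id: str
    kinase_text: str
    substrate_text: str
    site_texts: Tuple[str, ...]
    sentence_count: int
    evidence: Tuple[Sentence, ...]
    sections: frozenset

    def __post_init__(self) -> None:
        if self.sentence_count != len(self.evidence):
            raise ValueError("sentence_count must equal |evidence|")

    @property
    def complete(self) -> bool:
        return bool(self.kinase_text and self.substrate_text and self.site_texts)


@dataclass
class AnnotatedDocument:
    document: Document
    events: list = field(default_factory=list)
    mentions: list = field(default_factory=list)
    summary: list = field(default_factory=list)


@dataclass(frozen=True)
class TriageResult:
    doc_id: str
    potential: bool
    positive: bool
    matched_triggers: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.positive and not self.potential:
            raise ValueError("positive implies potential")
        if self.potential != bool(self.matched_triggers):
            raise ValueError("matched_triggers non-empty iff potential")


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f: float
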