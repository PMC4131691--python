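"""Sentence segmentation, tokenization, POS tagging and shallow chunking.

The tagger is deliberately self-contained: a closed-class lexicon plus
suffix rules over a coarse 10-tag set. Hand-written phosphorylation
patterns only need coarse distinctions (noun phrase vs verb group,
preposition boundaries), so no statistical model is required or wanted —
the pipeline must behave identically on every machine.

A different tagger can be plugged in: any callable mapping a token list to
an equal-length list of :class:`Tag` satisfies the contract.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

from .model import SectionName, Sentence
from .resources import load_lexicon_pairs


class Tag(enum.Enum):
    NOUN = "NOUN"
    VERB = "VERB"
    AUX = "AUX"
    ADJ = "ADJ"
    ADV = "ADV"
    DET = "DET"
    PREP = "PREP"
    CONJ = "CONJ"
    PUNCT = "PUNCT"
    NUM = "NUM"


@dataclass(frozen=True)
class Token:
    text: str
    span: Tuple[int, int]  # section-relative, half-open
    tag: Optional[Tag] = None

    def with_tag(self, tag: Tag) -> "Token":
        return Token(self.text, self.span, tag)


class ChunkKind(enum.Enum):
    NP = "NP"
    VG = "VG"


@dataclass(frozen=True)
class Chunk:
    kind: ChunkKind
    start: int  # token index, inclusive
    end: int  # token index, exclusive
    head_index: int  # absolute token index of the headword

    def __post_init__(self) -> None:
        if not (self.start <= self.head_index < self.end):
            raise ValueError("head_index must lie inside the token range")


# ---------------------------------------------------------------------------
# sentence segmentation

# Abbreviations that a period never terminates a sentence after.
_ABBREVS = {
    "e.g", "i.e", "fig", "figs", "et al", "al", "vs", "cf", "ca", "approx",
    "dr", "st", "no", "ref", "refs", "resp", "spp", "subsp",
}

_BOUNDARY = re.compile(r"[.!?]+(\s+)(?=[A-Z0-9“‘\"'(])")


def _protected(text: str, punct_pos: int) -> bool:
    """True if the period at punct_pos ends an abbreviation or initial."""
    before = text[:punct_pos]
    m = re.search(r"(\S+)$", before)
    if not m:
        return True
    word = m.group(1).rstrip(".").lower()
    if word in _ABBREVS:
        return True
    if re.search(r"\bet\s+al$", before.rstrip("."), flags=re.IGNORECASE):
        return True
    # single capital letter: genus initial ("S. cerevisiae") or middle initial
    if re.fullmatch(r"[A-Z]", word, flags=re.IGNORECASE) and len(word) == 1:
        return True
    return False


def split_sentences(
    section_text: str,
    doc_id: str = "",
    section_name: SectionName = SectionName.ABSTRACT,
) -> List[Sentence]:
    """Deterministically split section text into sentences.

    Does not split inside common abbreviations (``e.g.``, ``Fig.``,
    ``et al.``), after single-letter initials, or within decimal numbers
    (the boundary pattern requires whitespace after the period).
    """
    if not section_text.strip():
        return []
    cut_points = []
    for m in _BOUNDARY.finditer(section_text):
        if _protected(section_text, m.start()):
            continue
        cut_points.append((m.end(1) - len(m.group(1)), m.end(1)))
    sentences: List[Sentence] = []
    prev = 0
    for punct_end, next_start in cut_points:
        raw = section_text[prev:punct_end]
        start = prev + (len(raw) - len(raw.lstrip()))
        end = prev + len(raw.rstrip())
        if end > start:
            sentences.append(
                Sentence(doc_id, section_name, len(sentences), (start, end),
                         section_text[start:end])
            )
        prev = next_start
    tail = section_text[prev:]
    if tail.strip():
        start = prev + (len(tail) - len(tail.lstrip()))
        end = prev + len(tail.rstrip())
        sentences.append(
            Sentence(doc_id, section_name, len(sentences), (start, end),
                     section_text[start:end])
        )
    return sentences


# ---------------------------------------------------------------------------
# tokenization

# A word: alphanumeric/Greek core, optionally extended by internal hyphens,
# slashes or apostrophes; or a bare negative/elliptical number ("-73");
# otherwise any single non-space character.
_WORD = re.compile(
    r"[A-Za-z0-9Ͱ-Ͽ]+(?:[-/'’][A-Za-z0-9Ͱ-Ͽ]+)*"
    r"|-\d+"
    r"|[^\sA-Za-z0-9]"
)

_POSSESSIVE = re.compile(r"^(.*?)(['’]s?)$")


def _split_slashes(text: str) -> List[str]:
    """Split a slash compound only when every part is a plain lowercase word.

    ``and/or`` splits; ``FLT3/ITD`` and ``S/T`` stay whole so that surface
    variants of kinase names surface verbatim.
    """
    if "/" not in text:
        return [text]
    parts = text.split("/")
    if all(p.isalpha() and p.islower() and len(p) >= 2 for p in parts):
        out = []
        for i, p in enumerate(parts):
            if i:
                out.append("/")
            out.append(p)
        return out
    return [text]


def tokenize(text: str, offset: int = 0) -> List[Token]:
    """Tokenize, keeping hyphenated biochemical names as single tokens.

    ``CDK1-cyclin-B``, ``Ser-391`` and ``FLT3/ITD`` are one token each;
    parentheses and other punctuation are split off; possessive ``'s`` is
    split off its host.
    """
    tokens: List[Token] = []
    for m in _WORD.finditer(text):
        raw, start = m.group(0), m.start()
        pieces: List[Tuple[str, int]] = []
        pm = _POSSESSIVE.match(raw)
        if pm and pm.group(1) and re.search(r"[A-Za-z0-9]$", pm.group(1)):
            host, poss = pm.group(1), pm.group(2)
            rel = 0
            for part in _split_slashes(host):
                pieces.append((part, rel))
                rel += len(part)
            pieces.append((poss, len(host)))
        else:
            rel = 0
            for part in _split_slashes(raw):
                pieces.append((part, rel))
                rel += len(part)
        for part, rel in pieces:
            s = offset + start + rel
            tokens.append(Token(part, (s, s + len(part))))
    return tokens


# ---------------------------------------------------------------------------
# POS tagging

_GREEK_WORDS = (
    "alpha", "beta", "gamma", "delta", "epsilon", "kappa", "sigma", "zeta",
)


class LexiconSuffixTagger:
    """Default tagger: closed-class lexicon + suffix rules + noun fallback.

    Unknown capitalized or digit-bearing tokens default to NOUN, which is
    the right call for gene/protein symbols.
    """

    def __init__(self) -> None:
        self.lexicon = {
            w.lower(): Tag[t] for w, t in load_lexicon_pairs("closed_class.tsv")
        }

    def __call__(self, tokens: Sequence[Token]) -> List[Tag]:
        tags = [self._tag_one(t.text) for t in tokens]
        self._contextual_retag(tokens, tags)
        return tags

    def _tag_one(self, text: str) -> Tag:
        low = text.lower()
        if low in self.lexicon:
            return self.lexicon[low]
        if re.fullmatch(r"[^\w\s]+", text) or text in ("(", ")", "[", "]"):
            return Tag.PUNCT
        if re.fullmatch(r"-?\d+(?:[.,]\d+)*", text):
            return Tag.NUM
        if low.endswith("-phosphorylated"):
            return Tag.ADJ  # adjectival trigger compound, e.g. Ser-391-phosphorylated
        if low.endswith("ly") and low.isalpha():
            return Tag.ADV
        if any(low.endswith(s) for s in ("tion", "sion", "ment", "ness", "ity", "ysis")):
            return Tag.NOUN
        if any(low.endswith(s) for s in ("ylates", "ylated", "ylate", "ylating")):
            return Tag.VERB
        if low.isalpha() and any(low.endswith(s) for s in ("ates", "ated")):
            return Tag.VERB
        if low.isalpha() and low.endswith("ed") and len(low) > 4:
            return Tag.VERB
        if low.isalpha() and any(
            low.endswith(s) for s in ("al", "ic", "ous", "ive", "ary", "able", "ible")
        ):
            return Tag.ADJ
        return Tag.NOUN

    @staticmethod
    def _contextual_retag(tokens: Sequence[Token], tags: List[Tag]) -> None:
        # participle used attributively: "the phosphorylated forms",
        # "increased GSK-3B expression" -> ADJ, not VERB
        for i, tok in enumerate(tokens):
            if tags[i] is not Tag.VERB or not tok.text.lower().endswith("ed"):
                continue
            nxt = tags[i + 1] if i + 1 < len(tags) else None
            prev = tags[i - 1] if i > 0 else None
            if nxt in (Tag.NOUN, Tag.ADJ, Tag.NUM) and prev in (
                None, Tag.DET, Tag.ADJ, Tag.CONJ, Tag.PREP, Tag.PUNCT,
            ):
                tags[i] = Tag.ADJ


_default_tagger: Optional[LexiconSuffixTagger] = None


def default_tagger() -> LexiconSuffixTagger:
    global _default_tagger
    if _default_tagger is None:
        _default_tagger = LexiconSuffixTagger()
    return _default_tagger


def pos_tag(
    tokens: Sequence[Token],
    tagger: Optional[Callable[[Sequence[Token]], List[Tag]]] = None,
) -> List[Token]:
    """Tag every token exactly once.

    A plugged tagger must return exactly one tag per token; a length
    mismatch is a contract violation.
    """
    tagger = tagger or default_tagger()
    tags = tagger(tokens)
    if len(tags) != len(tokens):
        raise ValueError(
            f"tagger contract violation: {len(tokens)} tokens, {len(tags)} tags"
        )
    return [t.with_tag(tag) for t, tag in zip(tokens, tags)]


# ---------------------------------------------------------------------------
# chunking

_NP_TAGS = {Tag.DET, Tag.ADJ, Tag.NOUN, Tag.NUM}


def chunk(tagged: Sequence[Token]) -> List[Chunk]:
    """Flat, non-overlapping NP and VG chunks.

    NP = optional determiner + premodifiers + head noun(s), optionally a
    trailing number bound to the head ("serine 391"); head is the
    rightmost noun. VG = auxiliaries/adverbs + main verb(s).
    """
    chunks: List[Chunk] = []
    n = len(tagged)
    i = 0
    while i < n:
        tag = tagged[i].tag
        if tag in (Tag.AUX, Tag.VERB) or (
            tag is Tag.ADV
            and i + 1 < n
            and tagged[i + 1].tag in (Tag.AUX, Tag.VERB)
        ):
            j = i
            saw_verb = False
            while j < n and tagged[j].tag in (Tag.AUX, Tag.ADV, Tag.VERB):
                if tagged[j].tag is Tag.VERB:
                    saw_verb = True
                elif saw_verb:
                    break  # adverb after the main verb ends the group
                j += 1
            head = i
            for k in range(i, j):
                if tagged[k].tag is Tag.VERB:
                    head = k
            if not saw_verb:
                head = j - 1  # bare copula group
            chunks.append(Chunk(ChunkKind.VG, i, j, head))
            i = j
        elif tag in _NP_TAGS:
            j = i
            while j < n and tagged[j].tag in _NP_TAGS:
                j += 1
            # trim the tail so the chunk ends on a noun (or noun + number)
            end = j
            while end > i:
                last = tagged[end - 1].tag
                if last is Tag.NOUN:
                    break
                if (
                    last is Tag.NUM
                    and end - 1 > i
                    and tagged[end - 2].tag is Tag.NOUN
                ):
                    break
                end -= 1
            if end > i and any(tagged[k].tag is Tag.NOUN for k in range(i, end)):
                head = max(k for k in range(i, end) if tagged[k].tag is Tag.NOUN)
                chunks.append(Chunk(ChunkKind.NP, i, end, head))
            i = j
        else:
            i += 1
    return chunks


def preprocess_sentence(
    text: str,
    offset: int = 0,
    tagger: Optional[Callable[[Sequence[Token]], List[Tag]]] = None,
) -> Tuple[List[Token], List[Chunk]]:
    """tokenize -> tag -> chunk in one call."""
    tokens = pos_tag(tokenize(text, offset), tagger)
    return tokens, chunk(tokens)
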