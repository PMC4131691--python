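"""Semantic classification of noun phrases and parsing of site mentions.

Categories are assigned by rules over phrase headwords, affixes and
morphology, applied in a fixed priority order; the rule that fired is
recorded on every mention so classifications can be audited.
"""

from __future__ import annotations

import functools
import re
from typing import List, Optional, Sequence, Tuple

from .linguistic_preprocess import (
    Chunk,
    ChunkKind,
    Tag,
    Token,
    split_sentences,
)
from .model import (
    Category,
    EntityMention,
    Residue,
    SectionName,
    Sentence,
    SiteKind,
    SiteSpec,
)
from .resources import cached_lines, cached_word_set, load_lexicon_pairs

# ---------------------------------------------------------------------------
# site grammar

_RESIDUE_BY_NAME = {
    "serine": Residue.SER, "ser": Residue.SER, "s": Residue.SER,
    "threonine": Residue.THR, "thr": Residue.THR, "t": Residue.THR,
    "tyrosine": Residue.TYR, "tyr": Residue.TYR, "y": Residue.TYR,
    "histidine": Residue.OTHER_AA, "his": Residue.OTHER_AA, "h": Residue.OTHER_AA,
}

_FULL_NAMES = {"serine", "threonine", "tyrosine", "histidine"}
_THREE_LETTER = {"ser", "thr", "tyr", "his"}

# "Ser-391", "S391", "serine 391", "pS473", "Tyr(654)"
_RES_POS = re.compile(
    r"^p?(serine|threonine|tyrosine|histidine|ser|thr|tyr|his|[STYH])"
    r"(?:[-\s]|\()?(\d+)\)?$",
    re.IGNORECASE,
)
# elliptical right conjunct: "-73" or bare "73" (residue from the left conjunct)
_BARE_POS = re.compile(r"^-?(\d+)$")

_REGION = re.compile(
    r"^(?:the\s+)?("
    r"[A-Za-z0-9]+[-\s]termin(?:al|us)(?:\s+(?:domain|region|tail|end|half|part))?"
    r"|\S{1,40}(?:\s\S{1,40}){0,3}?\s(?:domain|region|motif|loop|repeat)s?"
    r")$",
    re.IGNORECASE,
)

_NOISE_WORDS = {"residue", "residues", "position", "positions", "site", "sites",
                "at", "the", "of"}


def _strip_noise(text: str) -> str:
    words = [w for w in text.split() if w.lower() not in _NOISE_WORDS]
    return " ".join(words)


def _parse_conjunct(text: str, inherited: Residue) -> Optional[SiteSpec]:
    text = text.strip().strip(",")
    if not text:
        return None
    stripped = _strip_noise(text)
    m = _RES_POS.match(stripped)
    if m:
        name, pos = m.group(1), int(m.group(2))
        low = name.lower()
        if len(name) == 1:
            # one-letter codes only with an uppercase letter (S64, pY, T308)
            if not name.isupper():
                return None
            residue = _RESIDUE_BY_NAME[low]
        else:
            residue = _RESIDUE_BY_NAME[low]
        return SiteSpec(SiteKind.RESIDUE_POSITION, residue, pos, surface=text)
    m = _BARE_POS.match(stripped)
    if m and inherited is not Residue.NONE:
        return SiteSpec(
            SiteKind.RESIDUE_POSITION, inherited, int(m.group(1)), surface=text
        )
    m = _REGION.match(text)
    if m:
        return SiteSpec(SiteKind.REGION, region_text=m.group(1), surface=text)
    low = stripped.lower()
    if low in _THREE_LETTER:
        return SiteSpec(SiteKind.RESIDUE_TYPE, _RESIDUE_BY_NAME[low], surface=text)
    singular = low[:-1] if low.endswith("s") else low
    if singular in _FULL_NAMES:
        return SiteSpec(
            SiteKind.RESIDUE_TYPE, _RESIDUE_BY_NAME[singular], surface=text
        )
    return None


_EMBEDDED_POS = re.compile(
    r"\b(?:p?(?:Ser|Thr|Tyr|His|serine|threonine|tyrosine|histidine)"
    r"[-\s]?\(?\d+\)?|[STYH]\d+)\b",
    re.IGNORECASE,
)

_CONJ_SPLIT = re.compile(r"\s*(?:,|\band\b|\bor\b|\bas well as\b)\s*|(?<=\d)/(?=[A-Za-z-]?\d|[STYH]\d)")


def parse_site_mention(text: str) -> List[SiteSpec]:
    """Parse a candidate site string into normalized site specifications.

    Recognizes residue+position forms (``Ser-391``, ``S391``,
    ``serine 391``, ``pS473``, ``Tyr(654)``), bare residue types
    (``serine``, ``Tyr``), regions/domains (``C-terminal domain``), and
    coordination, including elliptical right conjuncts (``Ser-63 and
    -73``). The most specific reading wins; an unparseable string yields
    an empty list.
    """
    text = text.strip()
    if not text:
        return []
    # try the whole string first (regions may contain spaces/commas)
    whole = _parse_conjunct(text, Residue.NONE)
    if whole is not None and whole.kind is not SiteKind.RESIDUE_TYPE:
        return [whole]
    parts = [p for p in _CONJ_SPLIT.split(text) if p and p.strip()]
    specs: List[SiteSpec] = []
    inherited = Residue.NONE
    for part in parts:
        spec = _parse_conjunct(part, inherited)
        if spec is None:
            continue
        specs.append(spec)
        if spec.kind is SiteKind.RESIDUE_POSITION:
            inherited = spec.residue
    if not specs:
        # nested forms ("serine residue Ser-391"): accept embedded
        # residue-position tokens, but only when everything around them is
        # site vocabulary — otherwise the string is not a site mention
        remainder = _EMBEDDED_POS.sub(" ", text)
        leftover = [
            w for w in re.findall(r"[A-Za-z-]+", remainder)
            if w.lower() not in _NOISE_WORDS
            and w.lower().rstrip("s") not in _FULL_NAMES
            and w.lower() not in ("and", "or")
        ]
        if not leftover:
            for m in _EMBEDDED_POS.finditer(text):
                spec = _parse_conjunct(m.group(0), Residue.NONE)
                if spec is not None and spec not in specs:
                    specs.append(spec)
    if not specs and whole is not None:
        return [whole]
    # most-specific-wins: drop bare residue types when a positioned site
    # of the same residue is present ("serine residue, Ser-391")
    if any(s.kind is SiteKind.RESIDUE_POSITION for s in specs):
        specs = [
            s for s in specs
            if not (
                s.kind is SiteKind.RESIDUE_TYPE
                and any(
                    p.kind is SiteKind.RESIDUE_POSITION and p.residue is s.residue
                    for p in specs
                )
            )
        ]
    return specs


# ---------------------------------------------------------------------------
# chunk classification

_GREEK = {
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "kappa", "lambda", "sigma", "omega",
}


@functools.lru_cache(maxsize=1)
def _head_table() -> dict:
    return {w.lower(): v for w, v in load_lexicon_pairs("head_lexicon.tsv")}


def _head_category_hint(head: str) -> Optional[str]:
    return _head_table().get(head.lower())


def _is_complex_name(token_text: str) -> bool:
    """Hyphenated name joining >=2 independent protein names (CDK1-cyclin-B)."""
    if "-" not in token_text:
        return False
    complex_parts = cached_word_set("complex_parts.txt")
    independent = 0
    for part in token_text.split("-"):
        if not part or part[0].isdigit():
            continue  # numbered suffix ("3B" in GSK-3B), not a second protein
        if any(c.isdigit() for c in part) or part.lower() in complex_parts:
            independent += 1
    return independent >= 2


def _protein_like(text: str) -> bool:
    """Protein-name morphology: digit-bearing symbol (Crm1, p53),
    -ase/-in suffix, Greek-letter modifier, or a short all-caps symbol."""
    if (
        any(c.isdigit() for c in text)
        and any(c.isalpha() for c in text)
        and not re.fullmatch(r"\d+[-/]?\w{0,2}", text)
    ):
        return True
    low = text.lower()
    parts = re.split(r"[-/]", low)
    if any(p in _GREEK for p in parts):
        return True
    if low.isalpha() and len(low) > 4 and (low.endswith("ase") or low.endswith("in")):
        return True
    if text.isupper() and 2 <= len(text) <= 6:
        return True
    return False


def np_text(tokens: Sequence[Token], chunk: Chunk, drop_det: bool = True) -> str:
    toks = list(tokens[chunk.start:chunk.end])
    if drop_det:
        while toks and toks[0].tag is Tag.DET:
            toks = toks[1:]
    return " ".join(t.text for t in toks)


def classify_np(tokens: Sequence[Token], chunk: Chunk) -> Tuple[Category, str]:
    """Classify one NP chunk; returns (category, rule id).

    Priority: site grammar > headword lexicon > protein morphology >
    part-words > species gazetteer > OTHER. Exactly one rule accounts for
    each label.
    """
    head = tokens[chunk.head_index].text
    text = np_text(tokens, chunk)
    # 1. site grammar
    if parse_site_mention(text):
        return Category.SITE, "site-grammar"
    # 2. headword lexicon
    hint = _head_category_hint(head)
    if hint == "KINASE_HEAD":
        premods = [tokens[k].text for k in range(chunk.start, chunk.head_index)]
        if head.lower().endswith("s") or not any(_protein_like(p) for p in premods):
            return Category.PROTEIN_FAMILY, "head:kinase-generic"
        return Category.PROTEIN, "head:kinase-named"
    if hint is not None:
        return Category[hint], f"head:{head.lower()}"
    if _is_complex_name(head):
        return Category.PROTEIN_COMPLEX, "hyphen-complex"
    # 3. protein morphology
    if _protein_like(head):
        return Category.PROTEIN, "morphology"
    # 4. part-words
    if head.lower() in cached_word_set("part_words.txt"):
        return Category.PROTEIN_PART, "part-word"
    # 5. species gazetteer
    if text.lower() in cached_word_set("species_gazetteer.txt") or (
        head.lower() in cached_word_set("species_gazetteer.txt")
    ):
        return Category.SPECIES, "species-gazetteer"
    return Category.OTHER, "default"


def classify_chunks(
    tokens: Sequence[Token], chunks: Sequence[Chunk], sentence: Sentence
) -> List[EntityMention]:
    """Assign exactly one semantic category to every NP chunk."""
    mentions = []
    for ch in chunks:
        if ch.kind is not ChunkKind.NP:
            continue
        category, rule = classify_np(tokens, ch)
        start = tokens[ch.start].span[0]
        end = tokens[ch.end - 1].span[1]
        text = sentence.text[
            start - sentence.span[0]: end - sentence.span[0]
        ] if sentence.text else " ".join(t.text for t in tokens[ch.start:ch.end])
        mentions.append(
            EntityMention(category, (start, end), text or np_text(tokens, ch, False),
                          sentence, rule)
        )
    return mentions


# ---------------------------------------------------------------------------
# species detection

@functools.lru_cache(maxsize=1)
def _gazetteer_patterns() -> List[Tuple[str, re.Pattern]]:
    names = sorted(
        (line for line in cached_lines("species_gazetteer.txt")),
        key=len,
        reverse=True,  # longest match wins
    )
    return [
        (name, re.compile(rf"(?<![A-Za-z]){re.escape(name)}(?![A-Za-z])",
                          re.IGNORECASE))
        for name in names
    ]


def detect_species(document) -> List[EntityMention]:
    """Case-insensitive gazetteer scan over all sections; longest match wins.

    Species are surfaced (for highlighting), not resolved to a taxon of the
    substrate.
    """
    mentions: List[EntityMention] = []
    patterns = _gazetteer_patterns()
    for section in document.sections:
        sentences = split_sentences(section.text, document.doc_id, section.name)
        covered: List[Tuple[int, int]] = []
        for name, pat in patterns:
            for m in pat.finditer(section.text):
                if any(m.start() < e and m.end() > s for s, e in covered):
                    continue
                covered.append((m.start(), m.end()))
                sent = next(
                    (s for s in sentences
                     if s.span[0] <= m.start() and m.end() <= s.span[1]),
                    None,
                )
                if sent is None:
                    continue
                mentions.append(
                    EntityMention(Category.SPECIES, (m.start(), m.end()),
                                  m.group(0), sent, "species-gazetteer")
                )
    mentions.sort(key=lambda m: (m.sentence.section_name.value, m.span))
    return mentions
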