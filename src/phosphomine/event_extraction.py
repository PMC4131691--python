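"""Pattern-based extraction of phosphorylation events from single sentences.

Sentences are first *simplified* into clauses (discourse-prefix stripping,
clause splitting, removal of uninformative parentheticals, distribution of
coordinated entities), then a small inventory of declarative patterns is
matched over the chunk-annotated clause. Each pattern is data, not code:
see ``resources/patterns.tsv``.

Slot filling is content-driven: a noun phrase assigned to the substrate
slot that actually parses as a site ("phosphorylated Y654 ...") fills the
site slot instead, which is what forces the V3 reading of
"KINASE phosphorylated SITE of SUBSTRATE".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .linguistic_preprocess import (
    Chunk,
    ChunkKind,
    Tag,
    Token,
    preprocess_sentence,
    split_sentences,
)
from .model import (
    Category,
    Document,
    EntityMention,
    PhosphoEvent,
    PROTEIN_LIKE,
    SectionName,
    Sentence,
    SiteSpec,
)
from .resources import cached_word_set, load_lexicon_pairs, resource_lines
from .term_classifier import classify_np, parse_site_mention, _protein_like


# ---------------------------------------------------------------------------
# configuration and rule inventory

@dataclass(frozen=True)
class PatternRule:
    pattern_id: str
    trigger_form: str  # verbal_active | verbal_passive | nominal | adjectival
    slots: Tuple[Tuple[str, str, str], ...]  # (slot, role, requirement)

    def slot_map(self) -> Dict[str, Tuple[str, str]]:
        return {s: (r, q) for s, r, q in self.slots}


def load_pattern_rules(directory=None) -> Tuple[PatternRule, ...]:
    rules = []
    for line in resource_lines("patterns.tsv", directory):
        pattern_id, form, template = line.split("\t")
        slots = []
        for item in template.split():
            slot, role = item.split("=")
            req = "none"
            if role.endswith("*"):
                role, req = role[:-1], "strict"
            elif role.endswith("+"):
                role, req = role[:-1], "any"
            slots.append((slot, role, req))
        rules.append(PatternRule(pattern_id, form, tuple(slots)))
    return tuple(rules)


def load_triggers(directory=None) -> Dict[str, str]:
    """word -> form (nominal|verbal), lower-cased."""
    return {
        w.lower(): form for w, form in load_lexicon_pairs("triggers.tsv", directory)
    }


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable switches of the IE engine.

    ``kinase_mode='recall'`` additionally accepts subject NPs of category
    OTHER as kinases when the clause carries a kinase cue word, trading
    precision for recall on the kinase slot.
    """

    kinase_mode: str = "precision"  # 'precision' | 'recall'
    abstracts_only: bool = False
    rules: Tuple[PatternRule, ...] = field(default_factory=load_pattern_rules)
    triggers: Tuple[Tuple[str, str], ...] = field(
        default_factory=lambda: tuple(sorted(load_triggers().items()))
    )

    def __post_init__(self) -> None:
        if self.kinase_mode not in ("precision", "recall"):
            raise ValueError("kinase_mode must be 'precision' or 'recall'")

    @property
    def trigger_map(self) -> Dict[str, str]:
        return dict(self.triggers)


DEFAULT_CONFIG = ExtractionConfig()


# ---------------------------------------------------------------------------
# clause representation

@dataclass(frozen=True)
class Clause:
    """A simplified clause with provenance into its source sentence.

    ``segments`` are (start, end) spans of the *section* text whose
    concatenation is ``text``; they let clause-local offsets be mapped back
    to section offsets after material has been deleted around them.
    """

    text: str
    segments: Tuple[Tuple[int, int], ...]
    sentence: Sentence

    def map_span(self, start: int, end: int) -> Optional[Tuple[int, int]]:
        """Clause-local span -> section span, or None if it crosses a cut."""
        pos = 0
        for s, e in self.segments:
            length = e - s
            if pos <= start and end <= pos + length:
                return (s + (start - pos), s + (end - pos))
            pos += length
        return None


def _clause_from_segments(
    segments: Sequence[Tuple[int, int]], sentence: Sentence
) -> Clause:
    base = sentence.span[0]
    text = "".join(sentence.text[s - base: e - base] for s, e in segments)
    return Clause(text, tuple(segments), sentence)


def _delete_range(
    segments: Sequence[Tuple[int, int]], cut_start: int, cut_end: int
) -> List[Tuple[int, int]]:
    """Remove the clause-local range [cut_start, cut_end) from segments."""
    out: List[Tuple[int, int]] = []
    pos = 0
    for s, e in segments:
        length = e - s
        seg_lo, seg_hi = pos, pos + length
        keep_left = max(seg_lo, min(cut_start, seg_hi))
        keep_right = max(seg_lo, min(cut_end, seg_hi))
        if keep_left > seg_lo:
            out.append((s, s + (keep_left - seg_lo)))
        if keep_right < seg_hi:
            out.append((s + (keep_right - seg_lo), e))
        pos = seg_hi
    return [(s, e) for s, e in out if e > s]


_DISCOURSE = re.compile(
    r"^.{0,140}?\b(?:report|reports|reported|show|shows|showed|shown|"
    r"demonstrate|demonstrates|demonstrated|found|find|reveal|reveals|"
    r"revealed|suggest|suggests|suggested|indicate|indicates|indicated|"
    r"confirm|confirmed|observe|observed)\b.{0,140}?\bthat\s+",
    re.IGNORECASE,
)

_CLAUSE_SPLIT = re.compile(r",\s+(?:and|but|whereas|while)\s+|;\s+")

_PAREN = re.compile(r"\s*\(([^()]*)\)")


def _paren_informative(content: str) -> bool:
    if parse_site_mention(content):
        return True
    return any(_protein_like(w) for w in re.findall(r"[\w/-]+", content))


def simplify_sentence(sentence: Sentence) -> List[Clause]:
    """Split a sentence into simplified clauses with span provenance.

    Applied in order: (a) strip a sentence-initial discourse frame ending
    in a "that"-complementizer ("Here, we report that X" -> "X"); (b) drop
    parentheticals carrying no entity or site mention; (c) split clause
    coordination at ", and"/", but" and semicolons; (d) distribute
    coordinated same-category protein NPs around a trigger verb into
    clause copies.
    """
    clause = _clause_from_segments([sentence.span], sentence)
    # (a) discourse prefix
    m = _DISCOURSE.match(clause.text)
    if m:
        clause = _clause_from_segments(
            _delete_range(clause.segments, 0, m.end()), sentence
        )
    # (b) uninformative parentheticals
    while True:
        hit = next(
            (p for p in _PAREN.finditer(clause.text)
             if not _paren_informative(p.group(1))),
            None,
        )
        if hit is None:
            break
        clause = _clause_from_segments(
            _delete_range(clause.segments, hit.start(), hit.end()), sentence
        )
    # (c) clause coordination
    clauses: List[Clause] = []
    cursor = 0
    for m in _CLAUSE_SPLIT.finditer(clause.text):
        if m.start() > cursor:
            clauses.append(
                _clause_from_segments(
                    _delete_range(
                        _delete_range(clause.segments, m.start(), len(clause.text)),
                        0, cursor,
                    ),
                    sentence,
                )
            )
        cursor = m.end()
    tail = _clause_from_segments(
        _delete_range(clause.segments, 0, cursor), sentence
    )
    if tail.text.strip():
        clauses.append(tail)
    # (d) coordination distribution
    out: List[Clause] = []
    for cl in clauses:
        out.extend(_distribute_coordination(cl))
    return out


def _distribute_coordination(clause: Clause) -> List[Clause]:
    tokens, chunks = preprocess_sentence(clause.text)
    nps = [c for c in chunks if c.kind is ChunkKind.NP]
    for i, left in enumerate(nps):
        # NP CONJ NP directly adjacent?
        conj_idx = left.end
        if conj_idx >= len(tokens) or tokens[conj_idx].tag is not Tag.CONJ:
            continue
        right = next((np for np in nps if np.start == conj_idx + 1), None)
        if right is None:
            continue
        cat_l, _ = classify_np(tokens, left)
        cat_r, _ = classify_np(tokens, right)
        if cat_l is not cat_r or cat_l not in PROTEIN_LIKE:
            continue
        # only distribute when a trigger verb governs the coordination
        follows_vg = any(
            c.kind is ChunkKind.VG and c.start == right.end for c in chunks
        )
        precedes_vg = any(
            c.kind is ChunkKind.VG and c.end == left.start for c in chunks
        )
        if not (follows_vg or precedes_vg):
            continue
        span_l = (tokens[left.start].span[0], tokens[left.end - 1].span[1])
        span_r = (tokens[right.start].span[0], tokens[right.end - 1].span[1])
        conj_span = tokens[conj_idx].span
        keep_left = _clause_from_segments(
            _delete_range(clause.segments, span_l[1], span_r[1]), clause.sentence
        )
        keep_right = _clause_from_segments(
            _delete_range(clause.segments, span_l[0], conj_span[1]), clause.sentence
        )
        return [keep_left, keep_right]
    return [clause]


# ---------------------------------------------------------------------------
# trigger detection

_ADJ_TRIGGER = re.compile(r"^(.*\S)-phosphorylated$", re.IGNORECASE)

_PASSIVE_AUX = {"is", "are", "was", "were", "be", "been", "being", "am",
                "get", "gets", "got"}


@dataclass(frozen=True)
class _Trigger:
    index: int  # token index in the clause
    form: str  # matches PatternRule.trigger_form
    vg: Optional[Chunk]
    site_prefix: str = ""  # adjectival form only


def _find_triggers(
    tokens: Sequence[Token], chunks: Sequence[Chunk], trigger_map: Dict[str, str]
) -> List[_Trigger]:
    vgs = [c for c in chunks if c.kind is ChunkKind.VG]
    found = []
    for i, tok in enumerate(tokens):
        low = tok.text.lower()
        form = trigger_map.get(low)
        if form == "verbal" and tok.tag is Tag.VERB:
            vg = next((v for v in vgs if v.start <= i < v.end), None)
            passive = False
            if vg is not None:
                passive = any(
                    tokens[k].text.lower() in _PASSIVE_AUX
                    for k in range(vg.start, i)
                )
            elif i > 0 and tokens[i - 1].text.lower() in _PASSIVE_AUX:
                passive = True
            found.append(
                _Trigger(i, "verbal_passive" if passive else "verbal_active", vg)
            )
        elif form == "nominal" and tok.tag is Tag.NOUN:
            found.append(_Trigger(i, "nominal", None))
        else:
            m = _ADJ_TRIGGER.match(tok.text)
            if m and parse_site_mention(m.group(1)):
                found.append(_Trigger(i, "adjectival", None, m.group(1)))
    return found


# ---------------------------------------------------------------------------
# slot material around a trigger

_ANAPHOR_HEADS = {
    "residue": "site", "residues": "site", "site": "site", "sites": "site",
    "protein": "substrate", "substrate": "substrate", "enzyme": "kinase",
    "kinase": "kinase",
}

_SITE_PREPS = {"at", "on", "in", "within"}


@dataclass
class _NPGroup:
    chunks: List[Chunk]
    text: str
    span: Tuple[int, int]  # clause-local char span


def _np_group_at(
    tokens: Sequence[Token], nps: Sequence[Chunk], start_tok: int, clause_text: str
) -> Optional[Tuple[_NPGroup, int]]:
    """Collect NP (CONJ NP|NUM)* starting at token index start_tok."""
    first = next((np for np in nps if np.start == start_tok), None)
    if first is None:
        return None
    group = [first]
    i = first.end
    while i + 1 < len(tokens) and tokens[i].tag in (Tag.CONJ, Tag.PUNCT):
        if tokens[i].tag is Tag.PUNCT and tokens[i].text != ",":
            break
        nxt = next((np for np in nps if np.start == i + 1), None)
        if nxt is not None:
            group.append(nxt)
            i = nxt.end
            continue
        if tokens[i + 1].tag is Tag.NUM:  # elliptical conjunct "-73"
            i += 2
            continue
        break
    start = tokens[first.start].span[0]
    end = tokens[i - 1].span[1]
    return _NPGroup(group, clause_text[start:end], (start, end)), i


def _collect_pps(
    tokens: Sequence[Token],
    chunks: Sequence[Chunk],
    start_tok: int,
    clause_text: str,
) -> List[Tuple[str, _NPGroup]]:
    nps = [c for c in chunks if c.kind is ChunkKind.NP]
    vgs = [c for c in chunks if c.kind is ChunkKind.VG]
    pps = []
    i = start_tok
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        if tok.tag is Tag.PREP:
            got = _np_group_at(tokens, nps, i + 1, clause_text)
            if got is not None:
                group, nxt = got
                pps.append((tok.text.lower(), group))
                i = nxt
                continue
        if any(v.start <= i < v.end and tokens[v.head_index].tag is Tag.VERB
               for v in vgs):
            break  # a new predicate ends the adjunct field
        if tok.tag is Tag.PUNCT and tok.text in (";",):
            break
        i += 1
    return pps


# ---------------------------------------------------------------------------
# mention construction

def _build_mention(
    tokens: Sequence[Token],
    np: Chunk,
    category: Category,
    rule: str,
    clause: Clause,
) -> Optional[EntityMention]:
    """Mention = head + protein-like premodifiers; leading species/quality
    words are excluded from the mention string (the NP span survives in the
    clause provenance)."""
    stop = cached_word_set("premod_stop.txt")
    head = np.head_index
    first = head
    for k in range(head - 1, np.start - 1, -1):
        t = tokens[k]
        low = t.text.lower()
        if low in stop or t.tag in (Tag.DET, Tag.ADJ):
            break
        if _protein_like(t.text):
            first = k
            continue
        if t.tag is Tag.NOUN and (t.text[0].isupper() or low in _GREEK_EXTRA):
            first = k
            continue
        break
    start = tokens[first].span[0]
    end = tokens[head].span[1]
    mapped = clause.map_span(start, end)
    sentence = clause.sentence
    if mapped is None:
        return EntityMention(category, sentence.span,
                             clause.text[start:end], sentence, rule)
    base = sentence.span[0]
    text = sentence.text[mapped[0] - base: mapped[1] - base]
    return EntityMention(category, mapped, text, sentence, rule)


_GREEK_EXTRA = {"tau", "alpha", "beta", "gamma", "delta", "kappa", "sigma"}


# ---------------------------------------------------------------------------
# rule matching

_KINASE_SLOT_OK = PROTEIN_LIKE
_SUBSTRATE_SLOT_OK = PROTEIN_LIKE | {Category.PROTEIN_PART}


def _anaphor_kind(tokens: Sequence[Token], np: Chunk) -> Optional[str]:
    head = tokens[np.head_index].text.lower()
    kind = _ANAPHOR_HEADS.get(head)
    if kind is None:
        return None
    first = tokens[np.start]
    if first.tag is Tag.DET and first.text.lower() in ("this", "that", "these",
                                                       "those", "the"):
        # "the enzyme"/"this residue" with no specifying premodifier
        if np.head_index - np.start <= 1:
            return kind
    return None


class _ClauseContext:
    """Chunk-level material of one clause, shared across rule attempts."""

    def __init__(self, clause: Clause, config: ExtractionConfig):
        self.clause = clause
        self.config = config
        self.tokens, self.chunks = preprocess_sentence(clause.text)
        self.nps = [c for c in self.chunks if c.kind is ChunkKind.NP]
        self.triggers = _find_triggers(self.tokens, self.chunks,
                                       config.trigger_map)

    def subject_np(self, trig: _Trigger) -> Optional[Chunk]:
        left_edge = trig.vg.start if trig.vg else trig.index
        cands = [np for np in self.nps if np.end <= left_edge]
        return cands[-1] if cands else None

    def object_np(self, trig: _Trigger) -> Optional[Chunk]:
        right_edge = trig.vg.end if trig.vg else trig.index + 1
        for np in self.nps:
            if np.start < right_edge:
                continue
            between = self.tokens[right_edge:np.start]
            if any(t.tag not in (Tag.ADV, Tag.ADJ) for t in between):
                return None
            return np
        return None

    def np_of_trigger(self, trig: _Trigger) -> Optional[Chunk]:
        return next(
            (np for np in self.nps if np.start <= trig.index < np.end), None
        )

    def resolve_np(self, np: Chunk, role: str):
        """-> ('kinase'|'substrate', mention) | ('site', specs) |
        ('anaphor', kind) | None"""
        text_start = self.tokens[np.start].span[0]
        text_end = self.tokens[np.end - 1].span[1]
        surface = self.clause.text[text_start:text_end]
        anaphor = _anaphor_kind(self.tokens, np)
        if anaphor is not None:
            return ("anaphor", anaphor)
        specs = parse_site_mention(
            " ".join(t.text for t in self.tokens[np.start:np.end]
                     if t.tag is not Tag.DET)
        )
        if specs:
            return ("site", tuple(specs))
        category, crule = classify_np(self.tokens, np)
        if role == "KINASE":
            ok = category in _KINASE_SLOT_OK
            if not ok and self.config.kinase_mode == "recall":
                cue = re.search(r"\bkinase", self.clause.text, re.IGNORECASE)
                head = self.tokens[np.head_index].text.lower()
                ok = category is Category.OTHER and (
                    cue is not None or head.endswith("ase")
                )
            if ok:
                m = _build_mention(self.tokens, np, category, crule, self.clause)
                return ("kinase", m) if m else None
            return None
        if role == "SUBSTRATE":
            if category in _SUBSTRATE_SLOT_OK:
                m = _build_mention(self.tokens, np, category, crule, self.clause)
                return ("substrate", m) if m else None
            return None
        return None


def _try_rule(
    rule: PatternRule, trig: _Trigger, ctx: _ClauseContext
) -> Optional[PhosphoEvent]:
    kinase = substrate = None
    sites: List[SiteSpec] = []
    anaphors: List[str] = []
    satisfied: Dict[str, bool] = {}

    def take(resolution, role: str) -> bool:
        nonlocal kinase, substrate
        if resolution is None:
            return False
        kind, payload = resolution
        if kind == "anaphor":
            anaphors.append(payload)
            return True
        if kind == "site":
            for s in payload:
                if s not in sites:
                    sites.append(s)
            return role == "SITE"
        if kind == "kinase" and kinase is None:
            kinase = payload
            return role == "KINASE"
        if kind == "substrate" and substrate is None:
            substrate = payload
            return role == "SUBSTRATE"
        return False

    slot_map = rule.slot_map()
    if rule.trigger_form == "adjectival":
        if "prefix" in slot_map:
            specs = parse_site_mention(trig.site_prefix)
            satisfied["prefix"] = bool(specs)
            sites.extend(specs)
        if "next_np" in slot_map:
            got = _np_group_at(
                ctx.tokens, ctx.nps, trig.index + 1, ctx.clause.text
            ) or _np_group_at(ctx.tokens, ctx.nps, trig.index, ctx.clause.text)
            np = got[0].chunks[0] if got else next(
                (n for n in ctx.nps if n.start > trig.index), None
            )
            role = slot_map["next_np"][0]
            satisfied["next_np"] = bool(
                np is not None and take(ctx.resolve_np(np, role), role)
            )
    else:
        pp_anchor = trig.index + 1
        trig_np = ctx.np_of_trigger(trig) if rule.trigger_form == "nominal" else None
        if trig_np is not None:
            pp_anchor = trig_np.end
        if "premod" in slot_map and rule.trigger_form == "nominal":
            role = slot_map["premod"][0]
            ok = False
            if trig_np is not None and trig_np.start < trig.index:
                sub = Chunk(ChunkKind.NP, trig_np.start, trig.index,
                            _rightmost_noun(ctx.tokens, trig_np.start, trig.index))
                ok = take(ctx.resolve_np(sub, role), role)
            satisfied["premod"] = ok
        if "subject" in slot_map and rule.trigger_form.startswith("verbal"):
            role = slot_map["subject"][0]
            np = ctx.subject_np(trig)
            satisfied["subject"] = bool(
                np is not None and take(ctx.resolve_np(np, role), role)
            )
        obj_end = None
        if "object" in slot_map and rule.trigger_form.startswith("verbal"):
            role = slot_map["object"][0]
            obj = ctx.object_np(trig)
            ok = False
            if obj is not None:
                got = _np_group_at(ctx.tokens, ctx.nps, obj.start,
                                   ctx.clause.text)
                if role == "SITE" and got is not None:
                    group, obj_end = got
                    specs = parse_site_mention(group.text)
                    if specs:
                        for s in specs:
                            if s not in sites:
                                sites.append(s)
                        ok = True
                if not ok:
                    ok = take(ctx.resolve_np(obj, role), role)
                    obj_end = obj.end
            satisfied["object"] = ok
        if rule.trigger_form.startswith("verbal"):
            pp_anchor = obj_end if obj_end is not None else (
                trig.vg.end if trig.vg else trig.index + 1
            )
        pps = _collect_pps(ctx.tokens, ctx.chunks, pp_anchor, ctx.clause.text)
        for slot in ("of_pp", "at_pp", "by_pp"):
            if slot not in slot_map:
                continue
            role = slot_map[slot][0]
            ok = False
            for prep, group in pps:
                if slot == "of_pp" and prep != "of":
                    continue
                if slot == "by_pp" and prep != "by":
                    continue
                if slot == "at_pp" and prep not in _SITE_PREPS:
                    continue
                if slot == "at_pp" or role == "SITE":
                    specs = parse_site_mention(group.text)
                    if specs:
                        for s in specs:
                            if s not in sites:
                                sites.append(s)
                        ok = True
                    continue
                res = ctx.resolve_np(group.chunks[0], role)
                if res is not None and take(res, role):
                    ok = True
                    break
                if res is not None and res[0] == "site":
                    ok = True  # content override counts as 'any' resolution
            satisfied[slot] = ok

    for slot, role, req in rule.slots:
        if req == "strict" and not satisfied.get(slot, False):
            return None
        if req == "any" and slot not in satisfied:
            return None
        if req == "any" and not satisfied.get(slot, False):
            # 'any' requires the slot to have resolved to something
            return None

    if kinase is None and substrate is None and not anaphors:
        return None
    trig_tok = ctx.tokens[trig.index]
    mapped = ctx.clause.map_span(*trig_tok.span)
    trig_span = mapped if mapped is not None else ctx.clause.sentence.span
    return PhosphoEvent(
        kinase=kinase,
        substrate=substrate,
        sites=tuple(sites),
        trigger=trig_span,
        trigger_text=trig_tok.text,
        sentence_refs=(ctx.clause.sentence,),
        pattern_id=rule.pattern_id,
        anaphors=tuple(anaphors),
    )


def _rightmost_noun(tokens: Sequence[Token], start: int, end: int) -> int:
    for k in range(end - 1, start - 1, -1):
        if tokens[k].tag is Tag.NOUN:
            return k
    return end - 1


def match_patterns(
    clause: Clause, config: ExtractionConfig = DEFAULT_CONFIG
) -> List[PhosphoEvent]:
    """Match the pattern inventory over one simplified clause.

    Every trigger yields at most one event: rules are tried in inventory
    order and the first rule whose required slots fill wins (documented
    tie-break: lowest rule index).
    """
    ctx = _ClauseContext(clause, config)
    events: List[PhosphoEvent] = []
    for trig in ctx.triggers:
        for rule in config.rules:
            if rule.trigger_form != trig.form:
                continue
            event = _try_rule(rule, trig, ctx)
            if event is not None:
                events.append(event)
                break
    return events


def extract_sentence_events(
    sentence: Sentence, config: ExtractionConfig = DEFAULT_CONFIG
) -> List[PhosphoEvent]:
    """Full per-sentence pipeline: simplify -> chunk -> classify -> match."""
    low = sentence.text.lower()
    if not any(t in low for t in ("phospho",)):
        return []  # cheap pre-filter: every trigger contains this stem
    events = []
    for clause in simplify_sentence(sentence):
        events.extend(match_patterns(clause, config))
    return events


def extract_document_events(
    document: Document, config: ExtractionConfig = DEFAULT_CONFIG
) -> List[PhosphoEvent]:
    """Sentence-level events for every retained section, in document order."""
    from .document_assembly import select_sections

    doc = select_sections(document, abstracts_only=config.abstracts_only)
    events = []
    for section in doc.sections:
        for sentence in split_sentences(section.text, doc.doc_id, section.name):
            events.extend(extract_sentence_events(sentence, config))
    return events
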