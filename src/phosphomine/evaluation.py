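"""Document-level scoring of extracted annotations against gold, and
inter-annotator agreement.

Matching is document-level, not sentence-level: a predicted slot value
counts as correct if the gold annotations for the same document contain a
matching value anywhere. Two match policies are provided: EXACT
(case-insensitive surface string) and SITE_NORMALIZED (site-grammar
equality, so "Ser-391" == "serine 391").
"""

from __future__ import annotations

import enum
from typing import Dict, Iterable, List, Mapping, Sequence, Set

from .model import EvalCounts, PRF
from .term_classifier import parse_site_mention

#: per-document annotations: doc_id -> set of slot strings
Annotations = Mapping[str, Set[str]]

SLOTS = ("kinase", "substrate", "site")


class MatchPolicy(enum.Enum):
    EXACT = "exact"
    SITE_NORMALIZED = "normalized"


DEFAULT_POLICY = {
    "kinase": MatchPolicy.EXACT,
    "substrate": MatchPolicy.EXACT,
    "site": MatchPolicy.SITE_NORMALIZED,
}


def _canon(value: str, policy: MatchPolicy) -> str:
    value = " ".join(value.split())
    if policy is MatchPolicy.SITE_NORMALIZED:
        specs = parse_site_mention(value)
        if specs:
            return "|".join(sorted(s.normalized() for s in specs))
    return value.lower()


def compare_annotations(
    predicted: Annotations,
    gold: Annotations,
    slot: str = "site",
    match_policy: MatchPolicy | None = None,
) -> EvalCounts:
    """Document-level set comparison for one slot.

    Both annotation maps must cover the same documents; a mismatch raises
    with the offending ids listed.
    """
    if slot not in SLOTS:
        raise ValueError(f"unknown slot: {slot!r}")
    if match_policy is None:
        match_policy = DEFAULT_POLICY[slot]
    missing = sorted(set(predicted) ^ set(gold))
    if missing:
        raise ValueError(f"document sets differ; unmatched ids: {missing}")
    counts = EvalCounts()
    for doc_id in sorted(predicted):
        pred = {_canon(v, match_policy) for v in predicted[doc_id] if v}
        gld = {_canon(v, match_policy) for v in gold[doc_id] if v}
        counts = counts + EvalCounts(
            tp=len(pred & gld), fp=len(pred - gld), fn=len(gld - pred)
        )
    return counts


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def prf(counts: EvalCounts) -> PRF:
    """Precision/recall/F from TP/FP/FN tallies.

    Zero denominators yield 0 by convention, keeping batch evaluation
    total on degenerate inputs.
    """
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return PRF(p, r, f_score(p, r))


def inter_annotator_f(
    annotations_a: Annotations,
    annotations_b: Annotations,
    slot: str = "site",
    match_policy: MatchPolicy | None = None,
) -> PRF:
    """Agreement between two annotators, as an F-score.

    Annotator A is treated as gold and B is scored against it; swapping
    the arguments swaps precision and recall and leaves F unchanged, so
    the choice of reference annotator does not matter.
    """
    counts = compare_annotations(annotations_b, annotations_a, slot, match_policy)
    return prf(counts)
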