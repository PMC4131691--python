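"""Synthetic annotated corpora and the printed golden sentences.

The generator instantiates sentence templates — one per supported
construction (active/passive/nominal/adjectival, site-of-substrate,
coordinated sites, cross-sentence anaphora) plus distractors — from fixed
name pools, and emits gold annotations alongside, so every pipeline stage
can be regression-tested without any external corpus. Output is fully
determined by the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .model import Document, Section, SectionName

TEMPLATE_KINDS = (
    "V1", "V2", "V3", "N1", "N2", "A1",
    "cross_sentence", "distractor", "trigger_free",
)

#: Default template mix: weighted toward the simple verbal/nominal
#: constructions that dominate abstracts, with a sizeable distractor share
#: to measure false-positive behaviour.
DEFAULT_MIX: Dict[str, float] = {
    "V1": 0.14, "V2": 0.14, "V3": 0.10, "N1": 0.12, "N2": 0.10, "A1": 0.10,
    "cross_sentence": 0.10, "distractor": 0.15, "trigger_free": 0.05,
}

KINASE_POOL = (
    "CK2", "PKA", "GSK-3B", "CDK1", "PLK1", "ERK2", "AURKA", "PKC-delta",
    "FLT3", "ATM",
)
SUBSTRATE_POOL = (
    "Crm1", "Sox9", "beta-catenin", "p53", "STAT3", "Cdc25", "tau protein",
    "BAD", "H2AX", "Mdm2",
)
RESIDUES = ("Ser", "Thr", "Tyr")


@dataclass(frozen=True)
class GoldEvent:
    kinase: str  # surface string, "" when absent
    substrate: str
    sites: Tuple[str, ...]  # normalized forms, e.g. "Ser-391"
    n_sentences: int = 1


@dataclass(frozen=True)
class GoldDocument:
    doc_id: str
    kind: str
    events: Tuple[GoldEvent, ...]
    potential: bool  # trigger word present in title/abstract
    positive: bool  # at least one event with a substrate


@dataclass(frozen=True)
class FixtureConfig:
    n_documents: int = 100
    mix: Tuple[Tuple[str, float], ...] = tuple(sorted(DEFAULT_MIX.items()))
    seed: int = 7

    def __post_init__(self) -> None:
        keys = [k for k, _ in self.mix]
        if set(keys) - set(TEMPLATE_KINDS):
            raise ValueError(f"unknown template kinds: {set(keys) - set(TEMPLATE_KINDS)}")
        total = sum(p for _, p in self.mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"template proportions must sum to 1, got {total}")


def _site_forms(rng: random.Random) -> Tuple[str, str]:
    """(surface form for the sentence, normalized gold form)."""
    residue = rng.choice(RESIDUES)
    position = rng.randrange(2, 999)
    style = rng.randrange(3)
    if style == 0:
        surface = f"{residue}-{position}"
    elif style == 1:
        one_letter = {"Ser": "S", "Thr": "T", "Tyr": "Y"}[residue]
        surface = f"{one_letter}{position}"
    else:
        surface = {"Ser": "serine", "Thr": "threonine", "Tyr": "tyrosine"}[
            residue
        ] + f" {position}"
    return surface, f"{residue}-{position}"


def _sorted_sites(*normalized: str) -> Tuple[str, ...]:
    """Dedupe and order gold sites the way summary rows do: by position."""
    unique = dict.fromkeys(normalized)
    return tuple(sorted(unique, key=lambda s: (int(s.split("-")[1]), s)))


def _instantiate(kind: str, rng: random.Random) -> Tuple[str, Tuple[GoldEvent, ...], bool]:
    """-> (abstract text, gold events, trigger-word-present flag)."""
    kinase = rng.choice(KINASE_POOL)
    substrate = rng.choice(SUBSTRATE_POOL)
    site, gold_site = _site_forms(rng)
    if kind == "V1":
        text = f"{kinase} phosphorylates {substrate} at {site} in vivo."
        return text, (GoldEvent(kinase, substrate, (gold_site,)),), True
    if kind == "V2":
        if rng.random() < 0.5:
            text = f"{substrate} is phosphorylated at {site} by {kinase}."
        else:
            text = f"{substrate} was phosphorylated by {kinase} at {site}."
        return text, (GoldEvent(kinase, substrate, (gold_site,)),), True
    if kind == "V3":
        text = f"{kinase} directly phosphorylated {site} of {substrate}."
        return text, (GoldEvent(kinase, substrate, (gold_site,)),), True
    if kind == "N1":
        site2, gold_site2 = _site_forms(rng)
        text = (
            f"Phosphorylation of {substrate} on {site} and {site2} "
            f"was observed in these cells."
        )
        return text, (GoldEvent("", substrate,
                                _sorted_sites(gold_site, gold_site2)),), True
    if kind == "N2":
        text = f"{substrate} phosphorylation at {site} increased twofold."
        return text, (GoldEvent("", substrate, (gold_site,)),), True
    if kind == "A1":
        surface = f"{gold_site}-phosphorylated"
        text = f"{surface} {substrate} accumulates in the nucleus."
        return text, (GoldEvent("", substrate, (gold_site,)),), True
    if kind == "cross_sentence":
        text = (
            f"{substrate} is phosphorylated at {site}. "
            f"{kinase} phosphorylates this residue."
        )
        return text, (GoldEvent(kinase, substrate, (gold_site,), n_sentences=2),), True
    if kind == "distractor":
        sub = rng.randrange(3)
        if sub == 0:
            # contains the trigger string only inside a hyphen compound
            text = (
                f"The phosphorylation-dependent interaction of {substrate} "
                f"with {kinase} remains unclear."
            )
            return text, (), True
        if sub == 1:
            text = f"The phosphatase PP2A removes the phosphate group from {substrate}."
            return text, (), False
        text = f"Mutation of {site} in {substrate} abolished DNA binding."
        return text, (), False
    if kind == "trigger_free":
        text = f"{substrate} interacts with {kinase} in the nucleus."
        return text, (), False
    raise ValueError(f"unknown template kind: {kind}")


def _kind_sequence(config: FixtureConfig, rng: random.Random) -> List[str]:
    n = config.n_documents
    counts = {k: int(p * n) for k, p in config.mix}
    remainder = n - sum(counts.values())
    fractional = sorted(
        config.mix, key=lambda kp: (kp[1] * n) - int(kp[1] * n), reverse=True
    )
    for k, _ in fractional[:remainder]:
        counts[k] += 1
    seq = [k for k, c in counts.items() for _ in range(c)]
    rng.shuffle(seq)
    return seq


def generate_corpus(
    config: FixtureConfig,
) -> Tuple[List[Document], List[GoldDocument]]:
    """Generate a synthetic corpus with complete gold annotations.

    Regeneration with the same config (including seed) is byte-identical.
    """
    rng = random.Random(config.seed)
    documents: List[Document] = []
    gold: List[GoldDocument] = []
    for i, kind in enumerate(_kind_sequence(config, rng)):
        doc_id = f"SYN{i:06d}"
        abstract, events, has_trigger_word = _instantiate(kind, rng)
        title = f"Regulation of cell signaling, study {i}."
        documents.append(
            Document(
                doc_id,
                (
                    Section(SectionName.TITLE, title),
                    Section(SectionName.ABSTRACT, abstract),
                ),
                ("Journal Article",),
            )
        )
        positive = has_trigger_word and any(e.substrate for e in events)
        gold.append(GoldDocument(doc_id, kind, events, has_trigger_word, positive))
    return documents, gold


# ---------------------------------------------------------------------------
# golden sentences

_CRM1 = (
    "Here, we report that human Crm1 is phosphorylated at serine 391 in "
    "mitosis by CDK1-cyclin-B."
)
_FLT3 = (
    "In the experiments using COS-7 cells expressing FLT3/ITD and Wt or "
    "mutant beta-catenin, FLT3/ITD phosphorylated Y654, and this residue "
    "was essential for beta-catenin's nuclear localization by FLT3/ITD. "
    "In vitro kinase assays, using recombinant FLT3 and biotinylated "
    "beta-catenin peptide including Y654 showed that FLT3 directly "
    "phosphorylated Y654 of beta-catenin."
)
_SOX9 = (
    "Here we show, in the developing chick neural tube, that "
    "phosphorylation of Sox9 on S64 and S181 facilitates its SUMOylation, "
    "and the phosphorylated forms of Sox9 are essential for trunk neural "
    "crest delamination."
)
_GSK3B = (
    "Glycogen synthase kinase-3beta (GSK-3B) phosphorylates tau protein, "
    "and increased GSK-3B expression has been associated with "
    "neurofibrillary tangles."
)


def paper_golden_set() -> Tuple[List[Document], List[GoldDocument]]:
    """The published worked examples as mini-documents with their gold.

    Four abstracts: a substrate phosphorylated by a kinase complex
    (Crm1 / CDK1-cyclin-B / Ser-391); surface-variant kinase names
    producing two rows (FLT3 and FLT3/ITD, beta-catenin, Tyr-654);
    coordinated sites with no kinase (Sox9, Ser-64 + Ser-181); and a
    kinase/substrate pair without a site (GSK-3B / tau protein).
    """
    docs = [
        Document("23729730", (Section(SectionName.ABSTRACT, _CRM1),)),
        Document("22126602", (Section(SectionName.ABSTRACT, _FLT3),)),
        Document("23382206", (Section(SectionName.ABSTRACT, _SOX9),)),
        Document("21443865", (Section(SectionName.ABSTRACT, _GSK3B),)),
    ]
    gold = [
        GoldDocument(
            "23729730", "golden",
            (GoldEvent("CDK1-cyclin-B", "Crm1", ("Ser-391",)),),
            True, True,
        ),
        GoldDocument(
            "22126602", "golden",
            (
                GoldEvent("FLT3/ITD", "", ("Tyr-654",)),
                GoldEvent("FLT3", "beta-catenin", ("Tyr-654",)),
            ),
            True, True,
        ),
        GoldDocument(
            "23382206", "golden",
            (GoldEvent("", "Sox9", ("Ser-64", "Ser-181")),),
            True, True,
        ),
        GoldDocument(
            "21443865", "golden",
            (GoldEvent("GSK-3B", "tau protein", ()),),
            True, True,
        ),
    ]
    return docs, gold
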