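"""Promoter signal quantification and epigenetic non-responsiveness calls.

Sequencing-tag tracks (PolII, H3K4me2, H3K27me3 ChIP-seq; MCIp-seq DNA
methylation) are reduced to normalised promoter tag counts — the ChIP promoter
window is the 1,000 bp upstream of the TSS (strand-aware), the MCIp window is
±1,000 bp around the TSS regardless of strand.  Non-responsive targets are
then classified into five non-exclusive mechanisms, each thresholded at the
80th percentile of its feature over a reference gene universe:

1. high basal expression in the resistant line;
2. hyper-methylation (resistant / parental methylation fold-change);
3. hypo-methylation (parental / resistant fold-change);
4. high absolute methylation in the resistant line;
5. high H3K27me3 / H3K4me2 ratio.

Genes exceeding no threshold are "unknown".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import GeneAnnotation

logger = logging.getLogger(__name__)

MECHANISM_FEATURES = {
    1: "basal_expr_resistant",
    2: "hyper_fc",
    3: "hypo_fc",
    4: "meth_resistant",
    5: "k27_k4_ratio",
}


@dataclass
class TagTrack:
    """Replicated sequencing-tag positions for one assay."""

    assay: str  # polII | h3k4me2 | h3k27me3 | mcip
    replicates: list[list[tuple[str, int]]]  # per replicate: (chrom, position)
    library_sizes: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("TagTrack needs >=1 replicate")
        for rep in self.replicates:
            if any(pos < 0 for _, pos in rep):
                raise ValueError("negative tag position")
        if self.library_sizes is None:
            self.library_sizes = [len(rep) for rep in self.replicates]


@dataclass
class GeneEpigeneticProfile:
    gene_id: str
    basal_expr_resistant: float
    meth_parental: float
    meth_resistant: float
    h3k4me2: float
    h3k27me3: float
    pseudocount: float = 1.0
    hyper_fc: float = field(init=False)
    hypo_fc: float = field(init=False)
    k27_k4_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("basal_expr_resistant", "meth_parental", "meth_resistant",
                     "h3k4me2", "h3k27me3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.gene_id}: {name} must be >= 0")
        pc = self.pseudocount
        self.hyper_fc = (self.meth_resistant + pc) / (self.meth_parental + pc)
        self.hypo_fc = (self.meth_parental + pc) / (self.meth_resistant + pc)
        self.k27_k4_ratio = (self.h3k27me3 + pc) / (self.h3k4me2 + pc)


@dataclass
class MechanismCall:
    gene_id: str
    mechanisms: set[int]

    @property
    def unknown(self) -> bool:
        return not self.mechanisms


def promoter_signal(track: TagTrack, gene: GeneAnnotation, window: str = "chip") -> float:
    """Normalised promoter tag count for one gene.

    ``window='chip'``: [tss-1000, tss) on +, reflected on - strand.
    ``window='mcip'``: tss +- 1000 regardless of strand.
    Replicate counts are scaled to the mean library size, then averaged.
    """
    if window == "chip":
        if gene.strand == "+":
            lo, hi = gene.tss - 1000, gene.tss  # [lo, hi)
        else:
            lo, hi = gene.tss + 1, gene.tss + 1001
    elif window == "mcip":
        lo, hi = gene.tss - 1000, gene.tss + 1001  # inclusive of tss+-1000
    else:
        raise ValueError(f"unknown window kind {window!r}")
    if lo < 0:
        logger.info("gene %s: promoter window truncated at 0", gene.gene_id)
        lo = 0
    mean_lib = float(np.mean(track.library_sizes))
    counts = []
    for rep, lib in zip(track.replicates, track.library_sizes):
        c = sum(1 for chrom, pos in rep if chrom == gene.chrom and lo <= pos < hi)
        counts.append(c * (mean_lib / lib) if lib > 0 else 0.0)
    return float(np.mean(counts))


def feature_thresholds(
    profiles: Sequence[GeneEpigeneticProfile], percentile: float = 80.0
) -> dict[str, float]:
    """Per-feature percentile thresholds over the reference gene universe."""
    if not profiles:
        raise ValueError("empty reference universe")
    return {
        feat: float(np.percentile([getattr(p, feat) for p in profiles], percentile))
        for feat in MECHANISM_FEATURES.values()
    }


def classify_mechanisms(
    profiles: Sequence[GeneEpigeneticProfile],
    target_ids: Sequence[str] | None = None,
    percentile: float = 80.0,
) -> list[MechanismCall]:
    """Flag each target gene with the mechanisms whose feature exceeds its
    threshold (strict >); thresholds come from the full reference universe."""
    thr = feature_thresholds(profiles, percentile)
    by_id = {p.gene_id: p for p in profiles}
    ids = list(target_ids) if target_ids is not None else [p.gene_id for p in profiles]
    missing = [g for g in ids if g not in by_id]
    if missing:
        raise KeyError(f"target gene(s) not in reference universe: {missing[:5]}")
    calls = []
    for gid in ids:
        p = by_id[gid]
        mechs = {
            m for m, feat in MECHANISM_FEATURES.items() if getattr(p, feat) > thr[feat]
        }
        calls.append(MechanismCall(gid, mechs))
    return calls


def mechanism_fractions(calls: Sequence[MechanismCall]) -> dict:
    """Per-mechanism percentages, pairwise overlap (Jaccard, %) and % unknown."""
    n = len(calls)
    if n == 0:
        return {"fractions_pct": {m: 0.0 for m in MECHANISM_FEATURES},
                "overlap_pct": {}, "unknown_pct": 0.0}
    members = {m: {c.gene_id for c in calls if m in c.mechanisms} for m in MECHANISM_FEATURES}
    fractions = {m: 100.0 * len(members[m]) / n for m in MECHANISM_FEATURES}
    overlap = {}
    for a in MECHANISM_FEATURES:
        for b in MECHANISM_FEATURES:
            if a < b:
                union = members[a] | members[b]
                overlap[(a, b)] = 100.0 * len(members[a] & members[b]) / len(union) if union else 0.0
    unknown = 100.0 * sum(c.unknown for c in calls) / n
    return {"fractions_pct": fractions, "overlap_pct": overlap, "unknown_pct": unknown}


def direction_concordance(
    fc_expr: dict[str, float], fc_signal: dict[str, float]
) -> float:
    """Percent of genes whose expression and signal fold-changes share a sign.

    Fold-changes of exactly 1 (no change) are concordant only with each other.
    """
    if set(fc_expr) != set(fc_signal):
        diff = set(fc_expr) ^ set(fc_signal)
        raise KeyError(f"unpaired gene(s): {sorted(diff)[:5]}")
    if not fc_expr:
        raise ValueError("no genes to compare")

    def cat(v: float) -> int:
        if v == 1.0:
            return 0
        return 1 if v > 0 else -1

    agree = sum(cat(fc_expr[g]) == cat(fc_signal[g]) for g in fc_expr)
    return 100.0 * agree / len(fc_expr)


def h3k4_above_median(signals: dict[str, float]) -> tuple[dict[str, bool], float]:
    """Flag genes with H3K4me2 signal strictly above the cohort median."""
    if not signals:
        raise ValueError("signals is empty")
    med = float(np.median(list(signals.values())))
    flags = {g: v > med for g, v in signals.items()}
    pct = 100.0 * sum(flags.values()) / len(flags)
    return flags, pct
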