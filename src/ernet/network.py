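"""Mechanism classification and regulatory-network assembly.

Combines three evidence layers for each gene — the differential-expression
call, ChIP peak FDRs in its annotated regions, and motif-site FDRs in peaks
and in its upstream-1-kb promoter — into a mechanism label:

* DBGA (direct-binding genomic action): a passing peak contains a significant
  ERα motif;
* I-DBGA (indirect-binding genomic action): passing peaks carry significant
  non-ERα TF motifs but no significant ERα motif;
* genomic-unassigned: passing peaks but no significant motif at all;
* NGA (non-genomic action): no passing peak anywhere in the gene's regions,
  but >=1 significant TF motif in the promoter;
* unexplained: differential but with no supporting binding evidence;
* none: the gene is not differentially expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

ER_ALPHA = "ERalpha"

GENOMIC_MECHANISMS = {"DBGA", "I-DBGA", "genomic-unassigned"}


@dataclass
class Thresholds:
    alpha_peak: float = 0.05
    alpha_site: float = 0.05


@dataclass
class RegulatoryCall:
    gene_id: str
    mechanism: str  # DBGA | I-DBGA | NGA | genomic-unassigned | unexplained | none
    direction: str = ""  # up | down | ""
    supporting_tfs: list[tuple[str, float]] = field(default_factory=list)
    peak_ids: list[str] = field(default_factory=list)
    de_local_fdr: float = 1.0


@dataclass
class Edge:
    tf: str
    gene: str
    mechanism: str
    direction: str
    site_fdr: float = 1.0


@dataclass
class HubRecord:
    tf: str
    target_count: int
    p_value: float
    significant: bool = False


@dataclass
class Network:
    edges: list[Edge] = field(default_factory=list)
    hubs: list[HubRecord] = field(default_factory=list)
    timepoint: str = ""


def classify_target(
    gene_id: str,
    de_call: str,
    de_local_fdr: float,
    assigned_peaks: Sequence,  # PeakRecords assigned to this gene
    peak_site_fdrs: Mapping[str, Mapping[str, float]],  # peak_id -> tf -> site fdr
    promoter_site_fdrs: Mapping[str, float],  # tf -> site fdr in the 1-kb promoter
    thresholds: Thresholds = Thresholds(),
    er_name: str = ER_ALPHA,
) -> RegulatoryCall:
    """Label one gene's regulatory mechanism from the three evidence layers."""
    if de_call == "unchanged":
        return RegulatoryCall(gene_id, "none", de_local_fdr=de_local_fdr)
    direction = de_call
    passing = [p for p in assigned_peaks if p.peak_fdr <= thresholds.alpha_peak]
    if passing:
        er_hits: list[tuple[str, float]] = []
        other_hits: list[tuple[str, float]] = []
        peak_ids = []
        for p in passing:
            peak_ids.append(p.peak_id)
            for tf, fdr in peak_site_fdrs.get(p.peak_id, {}).items():
                if fdr <= thresholds.alpha_site:
                    (er_hits if tf == er_name else other_hits).append((tf, fdr))
        dedup_other = sorted({tf: f for tf, f in sorted(other_hits, reverse=True)}.items())
        if er_hits:
            support = [(er_name, min(f for _, f in er_hits))] + dedup_other
            return RegulatoryCall(gene_id, "DBGA", direction, support, peak_ids, de_local_fdr)
        if dedup_other:
            return RegulatoryCall(gene_id, "I-DBGA", direction, dedup_other, peak_ids, de_local_fdr)
        return RegulatoryCall(gene_id, "genomic-unassigned", direction, [], peak_ids, de_local_fdr)
    promoter_hits = sorted(
        (tf, f) for tf, f in promoter_site_fdrs.items() if f <= thresholds.alpha_site
    )
    if promoter_hits:
        return RegulatoryCall(gene_id, "NGA", direction, promoter_hits, [], de_local_fdr)
    return RegulatoryCall(gene_id, "unexplained", direction, [], [], de_local_fdr)


def assemble_network(calls: Sequence[RegulatoryCall], timepoint: str = "") -> Network:
    """One edge per (supporting TF, gene); DBGA edges are attributed to ERα."""
    edges = []
    for call in calls:
        if call.mechanism in {"none", "unexplained", "genomic-unassigned"}:
            continue
        if call.mechanism == "DBGA":
            fdr = dict(call.supporting_tfs).get(ER_ALPHA, 1.0)
            edges.append(Edge(ER_ALPHA, call.gene_id, "DBGA", call.direction, fdr))
            for tf, f in call.supporting_tfs:
                if tf != ER_ALPHA:
                    edges.append(Edge(tf, call.gene_id, "DBGA", call.direction, f))
        else:
            for tf, f in call.supporting_tfs:
                edges.append(Edge(tf, call.gene_id, call.mechanism, call.direction, f))
    edges.sort(key=lambda e: (e.tf, e.gene))
    return Network(edges=edges, timepoint=timepoint)


def compare_networks(net_a: Network, net_b: Network) -> dict:
    """Per-mechanism target overlap (|A∩B| / |A∪B|) and the shared-hub list."""
    def targets(net: Network, mech: str) -> set[str]:
        return {e.gene for e in net.edges if e.mechanism == mech}

    mechanisms = sorted(
        {e.mechanism for e in net_a.edges} | {e.mechanism for e in net_b.edges}
    )
    overlap = {}
    for mech in mechanisms:
        a, b = targets(net_a, mech), targets(net_b, mech)
        union = a | b
        overlap[mech] = 100.0 * len(a & b) / len(union) if union else 100.0
    hubs_a = {h.tf for h in net_a.hubs}
    hubs_b = {h.tf for h in net_b.hubs}
    return {"overlap_pct": overlap, "shared_hubs": sorted(hubs_a & hubs_b)}
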