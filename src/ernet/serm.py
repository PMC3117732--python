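"""SERM agonist / antagonist / partial classification of ERα targets.

A selective estrogen receptor modulator (SERM, e.g. 4-OH-tamoxifen or
endoxifen) is scored per gene from the signed fold-changes under E2, SERM and
E2+SERM treatment:

* agonist:    |FC_SERM| > 1 + 0.70 (|FC_E2| - 1)
* antagonist: |FC_SERM| < 1 + 0.35 (|FC_E2| - 1)  and
              |FC_E2+SERM| < 1 + 0.50 (|FC_E2| - 1)
* partial agonist/antagonist otherwise (ties included).

Signed fold-change convention: treatment/control when up-regulated, minus the
inverse ratio when down-regulated, and exactly 1 when the gene is absent in
both groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .network import GENOMIC_MECHANISMS


@dataclass
class SermFoldChanges:
    gene_id: str
    fc_e2: float
    fc_serm: float
    fc_combo: float

    def __post_init__(self) -> None:
        for name, v in (("fc_e2", self.fc_e2), ("fc_serm", self.fc_serm),
                        ("fc_combo", self.fc_combo)):
            if abs(v) < 1:
                raise ValueError(f"{self.gene_id}: |{name}| must be >= 1 (got {v})")


def signed_fold_change(
    expr_treat: float, expr_ctrl: float,
    present_treat: bool = True, present_ctrl: bool = True,
) -> float:
    """Signed linear fold-change; absent/absent is defined as 1."""
    if not present_treat and not present_ctrl:
        return 1.0
    if (present_treat and expr_treat <= 0) or (present_ctrl and expr_ctrl <= 0):
        raise ValueError("present expression values must be positive")
    if expr_treat >= expr_ctrl:
        return expr_treat / expr_ctrl
    return -expr_ctrl / expr_treat


def classify_serm(fcs: SermFoldChanges) -> str:
    """Classify one gene's SERM response; the inequalities are strict, ties
    fall to 'partial'."""
    e2 = abs(fcs.fc_e2)
    serm = abs(fcs.fc_serm)
    combo = abs(fcs.fc_combo)
    if serm > 1 + 0.70 * (e2 - 1):
        return "agonist"
    if serm < 1 + 0.35 * (e2 - 1) and combo < 1 + 0.50 * (e2 - 1):
        return "antagonist"
    return "partial"


def sign_discordant(fcs: SermFoldChanges) -> bool:
    """SERM response opposite in direction to the E2 response (flag only)."""
    return fcs.fc_e2 * fcs.fc_serm < 0


def is_serm_responsive(fcs: SermFoldChanges, fc_min: float = 1.20) -> bool:
    """Responsiveness prefilter: the SERM fold-change clears the effect-size bar."""
    return abs(fcs.fc_serm) >= fc_min


def serm_summary(
    calls: dict[str, str], mechanisms: dict[str, str], directions: dict[str, str] | None = None
) -> dict:
    """Cross-tabulate SERM effect x genomic/non-genomic (x direction) and test
    the agonist-vs-rest by genomic-vs-non-genomic association exactly.

    ``calls`` maps gene -> effect class, ``mechanisms`` gene -> mechanism label
    (DBGA/I-DBGA/... are genomic, NGA non-genomic); genes without a mechanism
    label are dropped.  The association p-value is a two-sided exact
    hypergeometric (Fisher) test.
    """
    rows = []
    for gene, effect in calls.items():
        mech = mechanisms.get(gene)
        if mech is None:
            continue
        cls = "genomic" if mech in GENOMIC_MECHANISMS else "non-genomic"
        rows.append(
            {"gene_id": gene, "effect": effect, "class": cls,
             "direction": (directions or {}).get(gene, "")}
        )
    if not rows:
        return {"table": pd.DataFrame(), "p_value": float("nan"), "counts_2x2": None}
    df = pd.DataFrame(rows)
    index_cols = ["effect", "class"] + (["direction"] if directions else [])
    table = df.groupby(index_cols).size().rename("count").reset_index()
    a = ((df["effect"] == "agonist") & (df["class"] == "genomic")).sum()
    b = ((df["effect"] == "agonist") & (df["class"] == "non-genomic")).sum()
    c = ((df["effect"] != "agonist") & (df["class"] == "genomic")).sum()
    d = ((df["effect"] != "agonist") & (df["class"] == "non-genomic")).sum()
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        p = 1.0  # degenerate margin: no contrast to test
    else:
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {"table": table, "p_value": float(p), "counts_2x2": [[int(a), int(b)], [int(c), int(d)]]}


def classify_serm_table(fc_list: Sequence[SermFoldChanges]) -> pd.DataFrame:
    """Vector convenience: one row per gene with class and discordance flag."""
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fc_list],
            "effect": [classify_serm(f) for f in fc_list],
            "sign_discordant": [sign_discordant(f) for f in fc_list],
        }
    )
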