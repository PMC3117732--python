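"""Classify SERM responses from E2 / SERM / E2+SERM fold-changes.

A SERM (e.g. tamoxifen) is an agonist on a gene when it reproduces >70% of
the E2 effect, an antagonist when it produces <35% and also suppresses the
combined treatment below 50%, and partial otherwise.
"""

from ernet.serm import SermFoldChanges, classify_serm, serm_summary

genes = [
    SermFoldChanges("TFF1", fc_e2=4.0, fc_serm=3.4, fc_combo=3.0),
    SermFoldChanges("GREB1", fc_e2=3.0, fc_serm=1.2, fc_combo=1.4),
    SermFoldChanges("CCND1", fc_e2=2.5, fc_serm=1.8, fc_combo=2.0),
]
calls = {g.gene_id: classify_serm(g) for g in genes}
for gid, effect in calls.items():
    print(f"{gid}: {effect}")

mechanisms = {"TFF1": "DBGA", "GREB1": "DBGA", "CCND1": "NGA"}
summary = serm_summary(calls, mechanisms)
print(f"agonist-vs-rest x genomic-vs-non-genomic exact p = {summary['p_value']:.3g}")
# the exact test asks whether the agonistic effect concentrates on genomic
# (DNA-binding) targets rather than non-genomic ones.
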