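# ernet

Empirical-Bayes construction of estrogen-receptor-α (ERα) transcription-factor
regulatory networks from two-condition expression data, ChIP peaks and motif
scans — with classification of each target's regulatory *mechanism*, exact hub
significance, SERM (selective estrogen receptor modulator) response rules and
promoter epigenetic non-responsiveness calls.

## Who this is for

Computational biologists building TF regulatory networks that distinguish
*how* a hormone-activated TF regulates each target:

* **DBGA** — direct-binding genomic action: ERα binds an estrogen response
  element (ERE) inside a ChIP peak at the gene;
* **I-DBGA** — indirect-binding genomic action: the peak carries a significant
  partner-TF motif (Sp1, AP-1, …) but no ERE — ERα is tethered;
* **NGA** — non-genomic action: no peak anywhere in the gene's regions, but a
  significant TF motif in the upstream-1-kb promoter points at signalling-
  cascade regulation.

## The models

**Differential expression.** Probe-level log2 expression follows a
random-effects model G_ijkl = μ_il + b_ij + ε_ijkl with probe effect
b ~ N(0, δ²) and error ε ~ N(0, σ²). The condition-mean pair (μ_i1, μ_i2)
comes from three latent populations: up-regulated ~ BN(η₁, Σ₁) above the
y = x line, unchanged with μ_i1 = μ_i2 ~ N(λ, φ²) on the line, down-regulated
~ BN(η₋₁, Σ₋₁) below it. The latent means integrate out analytically and
θ = (ρ, η₁, Σ₁, η₋₁, Σ₋₁, λ, φ, σ, δ) is fitted by EM. A gene is called
up when P(up | data) ≥ c = 0.80 *and* its fold-change exceeds 20%; the local
FDR of a call is 1 − P(called class | data).

**Motif site FDR.** Each sequence gets one binding score: the best log2-odds
window over both strands of a TRANSFAC-style weight matrix against the
background base composition. Scores are calibrated against R = 10,000
sequences sampled from a 6th-order Markov model of the genome: the score
range is cut into k = 200 bins (sparse bins collapsed to occupancy ≥ 20), the
local FDR in bin b is min(1, (I·n_b/R)/m_b), bins below the score-range
midpoint are forced to FDR 1, and a cubic smoothing spline gives the FDR at
any score.

**Hub significance.** Under the null that the n_i TFs implicated at each of M
differential genes are drawn uniformly without replacement from n known TFs,
a TF's target count T is Poisson-binomial with p_i = n_i/n; the hub p-value
Pr(T ≥ t_obs) is computed exactly by convolution.

**SERM rules.** With signed fold-changes under E2, SERM and E2+SERM, a SERM is
an *agonist* on a gene if |FC_SERM| > 1 + 0.70(|FC_E2| − 1), an *antagonist*
if |FC_SERM| < 1 + 0.35(|FC_E2| − 1) and |FC_E2+SERM| < 1 + 0.50(|FC_E2| − 1),
otherwise *partial*.

**Epigenetic non-responsiveness.** Promoter signals (PolII/H3K4me2/H3K27me3
tags in the 1-kb upstream window; methylation in ±1 kb) feed five
non-exclusive mechanisms — high basal expression, hyper-methylation,
hypo-methylation, high methylation, high H3K27me3/H3K4me2 ratio — each
thresholded at its 80th percentile over a reference gene universe.

## Worked example

```python
from ernet import pipeline, simulate

bundle = simulate.simulate_regulatory_scenario(simulate.ScenarioConfig(), seed=31)
result = pipeline.run_scenario_pipeline(bundle, seed=32, R=5000)
print(pipeline.mechanism_accuracy(result, bundle.truth.mechanism))
for h in result.net.hubs[:3]:
    print(h.tf, h.target_count, h.p_value)
```

prints

```
0.96
ERalpha 35 1.18e-57
SP1 24 3.14e-35
E2F1 23 2.47e-33
```

96% of the 200 planted mechanism labels are recovered end-to-end (EM fit →
peak/promoter motif FDR calibration → decision flow), and the planted ERα hub
attains the smallest exact hub p-value. The `examples/` directory has one
short narrative script per capability (differential expression, motif FDR,
network + hubs, SERM rules, epigenetic mechanisms); each prints the numbers
it computes and says what they mean. A thin CLI mirrors the library:
`ernet diffexpr|motif-fdr|network|hubs|serm|epigenetics|simulate --help`.

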