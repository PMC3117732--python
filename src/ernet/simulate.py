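"""Synthetic-data generators for every input class the pipeline consumes.

Each generator draws from the same statistical structure its consumer assumes:
expression from the three-population random-effects model, sequences from a
Markov background with optionally planted motif instances, regulatory
scenarios with known mechanism labels, and log-normal promoter epigenetic
profiles.  All randomness flows from a single seed through independent named
sub-streams, so adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diffexpr import ExpressionDataset, GeneExpression, MixtureParams
from .epigenetics import GeneEpigeneticProfile
from .io import GeneAnnotation, MotifMatrix, PeakRecord
from .motif import MarkovBackground

# named sub-streams off the master seed
_STREAMS = {"expression": 1, "sequences": 2, "scenario": 3, "epigenetics": 4}


def _rng(seed: int | None, stream: str) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def default_mixture_params(
    rho: tuple[float, float, float] = (0.15, 0.70, 0.15),
    effect: float = 1.2,
) -> MixtureParams:
    """Study-condition defaults on the log2 microarray scale.

    The null population sits at lambda = 7 with between-gene SD phi = 1.5;
    differential populations are offset by ±effect (log2) with strongly
    correlated condition means; replicate and probe noise SDs are 0.3.
    """
    base = 7.0
    S = np.array([[2.0, 1.7], [1.7, 2.0]])
    return MixtureParams(
        rho=np.asarray(rho, dtype=float),
        eta1=np.array([base - effect / 2, base + effect / 2]),
        Sigma1=S.copy(),
        eta_neg1=np.array([base + effect / 2, base - effect / 2]),
        Sigma_neg1=S.copy(),
        lam=base,
        phi=1.5,
        sigma=0.3,
        delta=0.3,
    )


def simulate_expression(
    params: MixtureParams,
    I: int = 2000,
    probes_per_gene: int = 3,
    reps_per_condition: int = 3,
    seed: int | None = None,
    gene_ids: list[str] | None = None,
    populations: np.ndarray | None = None,
) -> tuple[ExpressionDataset, dict]:
    """Draw an expression dataset from the mixture model, returning the truth.

    ``populations`` optionally fixes each gene's latent Y_i in {1, 0, -1}
    (otherwise drawn from rho).
    """
    if I < 1:
        raise ValueError("I must be >= 1")
    params.validate()
    rng = _rng(seed, "expression")
    n, m = probes_per_gene, reps_per_condition
    if populations is None:
        Y = rng.choice([1, 0, -1], size=I, p=params.rho)
    else:
        Y = np.asarray(populations)
        if Y.shape != (I,):
            raise ValueError("populations must have length I")
    ids = gene_ids if gene_ids is not None else [f"g{i + 1:05d}" for i in range(I)]
    genes = []
    for i in range(I):
        if Y[i] == 1:
            mu = rng.multivariate_normal(params.eta1, params.Sigma1)
        elif Y[i] == -1:
            mu = rng.multivariate_normal(params.eta_neg1, params.Sigma_neg1)
        else:
            mu0 = rng.normal(params.lam, params.phi)
            mu = np.array([mu0, mu0])
        b = rng.normal(0, params.delta, n) if n > 1 else np.zeros(n)
        v1 = mu[0] + b[:, None] + rng.normal(0, params.sigma, (n, m))
        v2 = mu[1] + b[:, None] + rng.normal(0, params.sigma, (n, m))
        genes.append(GeneExpression(ids[i], v1, v2))
    truth = {"Y": Y, "gene_ids": ids, "seed": seed, "params": params}
    return ExpressionDataset(genes), truth


# ---------------------------------------------------------------------------
# Sequences and motifs
# ---------------------------------------------------------------------------

#: human-like base composition (GC ~ 0.41)
HUMAN_BASE_FREQS = np.array([0.295, 0.205, 0.205, 0.295])


def iid_background(freqs: np.ndarray = HUMAN_BASE_FREQS, order: int = 6) -> MarkovBackground:
    """A Markov background whose every context emits the same base distribution."""
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1) > 1e-9:
        raise ValueError("freqs must sum to 1")
    n_ctx = 4**order
    trans = np.tile(freqs, (n_ctx, 1))
    # start contexts distributed as iid products of freqs
    start = np.ones(n_ctx)
    for d in range(order):
        digits = (np.arange(n_ctx) // 4 ** (order - 1 - d)) % 4
        start *= freqs[digits]
    start /= start.sum()
    return MarkovBackground(order, trans, start)


def motif_from_consensus(
    consensus: str, motif_id: str, tf_name: str, strength: float = 0.95
) -> MotifMatrix:
    """Synthetic PWM putting ``strength`` on the consensus base per position
    (positions with N are uniform)."""
    cols = []
    for base in consensus.upper():
        if base == "N":
            cols.append(np.full(4, 0.25))
        else:
            col = np.full(4, (1 - strength) / 3)
            col["ACGT".index(base)] = strength
            cols.append(col)
    return MotifMatrix(motif_id, tf_name, np.stack(cols, axis=1))


def default_tf_motifs() -> dict[str, MotifMatrix]:
    """Synthetic stand-ins for the core TF motifs (ERE plus common partners).

    Widths of 12-13 bp at per-position strength 0.97 keep planted sites
    separable from the best background match even in 1-kb promoter windows.
    """
    return {
        "ERalpha": motif_from_consensus("GGTCANNNTGACC", "M_ERE", "ERalpha", 0.97),
        "SP1": motif_from_consensus("GGGGGCGGGGCC", "M_SP1", "SP1", 0.97),
        "E2F1": motif_from_consensus("TTTCGCGCCAAA", "M_E2F1", "E2F1", 0.97),
        "AP1": motif_from_consensus("TGACTCAGCATG", "M_AP1", "AP1", 0.97),
    }


def sample_motif_instance(motif: MotifMatrix, rng: np.random.Generator) -> str:
    """Sample one site from the PWM columns (consensus-sampled, not fixed)."""
    return "".join(
        "ACGT"[rng.choice(4, p=motif.probs[:, j] / motif.probs[:, j].sum())]
        for j in range(motif.width)
    )


def simulate_sequences_with_motifs(
    bg: MarkovBackground,
    motif: MotifMatrix,
    n_seqs: int,
    length: int,
    plant_rate: float,
    seed: int | None = None,
) -> tuple[dict[str, str], dict]:
    """Background sequences with motif instances planted in ``plant_rate`` of
    them at uniform positions; returns the sequences and the planted truth."""
    if not 0 <= plant_rate <= 1:
        raise ValueError("plant_rate must be in [0,1]")
    if length < motif.width:
        raise ValueError("length must be >= motif width")
    from .motif import sample_sequences

    rng = _rng(seed, "sequences")
    base_seed = int(rng.integers(2**31 - 1))
    seqs = sample_sequences(bg, R=n_seqs, length=length, seed=base_seed)
    planted = rng.random(n_seqs) < plant_rate
    positions: dict[str, int] = {}
    out = {}
    for i, seq in enumerate(seqs):
        name = f"seq{i + 1:05d}"
        if planted[i]:
            pos = int(rng.integers(0, length - motif.width + 1))
            site = sample_motif_instance(motif, rng)
            seq = seq[:pos] + site + seq[pos + motif.width:]
            positions[name] = pos
        out[name] = seq
    truth = {"positions": positions, "plant_rate": plant_rate, "seed": seed}
    return out, truth


# ---------------------------------------------------------------------------
# Full regulatory scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Gene counts per planted mechanism and generation knobs.

    Decoy classes exercise the gating logic: ``n_decoy_de`` genes are
    differential with no binding evidence (truth: unexplained) and
    ``n_decoy_peak`` genes carry a strong ERE peak but are not differential
    (truth: none).
    """

    # ERalpha is the planted hub: its DBGA target count dominates every
    # partner TF so the hub ranking has a designed answer
    n_dbga: int = 40
    n_idbga: int = 25
    n_nga: int = 25
    n_decoy_de: int = 20
    n_decoy_peak: int = 20
    n_null: int = 70
    promoter_length: int = 1000
    peak_length: int = 45
    peak_fdr_true: float = 0.001
    bg_order: int = 3
    effect: float = 2.0  # log2 shift of differential populations
    idbga_tf: str = "SP1"
    nga_tf: str = "E2F1"

    @property
    def n_genes(self) -> int:
        return (self.n_dbga + self.n_idbga + self.n_nga
                + self.n_decoy_de + self.n_decoy_peak + self.n_null)


@dataclass
class ScenarioTruth:
    mechanism: dict[str, str]
    population: dict[str, int]
    planted_hub_tf: str
    seed: int | None
    config: ScenarioConfig


@dataclass
class ScenarioBundle:
    expression: ExpressionDataset
    peaks: list[PeakRecord]
    promoters: dict[str, str]
    motifs: dict[str, MotifMatrix]
    annotation: dict[str, GeneAnnotation]
    background: MarkovBackground
    truth: ScenarioTruth


def simulate_regulatory_scenario(
    config: ScenarioConfig = ScenarioConfig(), seed: int | None = None
) -> ScenarioBundle:
    """Generate a full input bundle with known DBGA/I-DBGA/NGA labels.

    DBGA genes get a passing peak with a planted ERE; I-DBGA genes a passing
    peak with the configured partner motif; NGA genes no peak but a planted
    promoter motif; decoys and nulls per :class:`ScenarioConfig`.
    """
    if config.n_genes < 1:
        raise ValueError("scenario needs >=1 gene")
    if min(config.n_dbga, config.n_idbga, config.n_nga,
           config.n_decoy_de, config.n_decoy_peak, config.n_null) < 0:
        raise ValueError("gene counts must be >= 0")
    rng = _rng(seed, "scenario")
    motifs = default_tf_motifs()
    bg = iid_background(order=config.bg_order)

    labels = (["DBGA"] * config.n_dbga + ["I-DBGA"] * config.n_idbga
              + ["NGA"] * config.n_nga + ["unexplained"] * config.n_decoy_de
              + ["none"] * (config.n_decoy_peak + config.n_null))
    has_peak = ([True] * (config.n_dbga + config.n_idbga) + [False] * config.n_nga
                + [False] * config.n_decoy_de + [True] * config.n_decoy_peak
                + [False] * config.n_null)
    I = config.n_genes
    ids = [f"g{i + 1:04d}" for i in range(I)]

    # expression: differential genes alternate up/down
    Y = np.zeros(I, dtype=int)
    flip = 1
    for i, lab in enumerate(labels):
        if lab in {"DBGA", "I-DBGA", "NGA", "unexplained"}:
            Y[i] = flip
            flip = -flip
    params = default_mixture_params(effect=config.effect)
    expr_seed = int(rng.integers(2**31 - 1))
    expression, _ = simulate_expression(
        params, I=I, seed=expr_seed, gene_ids=ids, populations=Y
    )

    # annotation: genes spaced on one synthetic chromosome, promoter = 1 kb upstream
    spacing = 10_000
    annotation = {}
    for i, gid in enumerate(ids):
        tss = 5_000 + i * spacing
        annotation[gid] = GeneAnnotation(
            gid, "chr1", tss, "+",
            regions={
                "promoter": [(tss - config.promoter_length, tss)],
                "intron": [(tss + 500, tss + 2_500)],
                "downstream": [(tss + 2_500, tss + 4_500)],
            },
        )

    # sequences
    from .motif import sample_sequences

    seq_seed = int(rng.integers(2**31 - 1))
    raw_proms = sample_sequences(bg, R=I, length=config.promoter_length, seed=seq_seed)
    peak_seed = int(rng.integers(2**31 - 1))
    raw_peaks = sample_sequences(bg, R=I, length=config.peak_length, seed=peak_seed)

    def plant(seq: str, motif: MotifMatrix) -> str:
        pos = int(rng.integers(0, len(seq) - motif.width + 1))
        return seq[:pos] + sample_motif_instance(motif, rng) + seq[pos + motif.width:]

    promoters: dict[str, str] = {}
    peaks: list[PeakRecord] = []
    for i, gid in enumerate(ids):
        prom = raw_proms[i]
        if labels[i] == "NGA":
            prom = plant(prom, motifs[config.nga_tf])
        promoters[gid] = prom
        if has_peak[i]:
            pk = raw_peaks[i]
            if labels[i] == "I-DBGA":
                pk = plant(pk, motifs[config.idbga_tf])
            else:  # DBGA and decoy peaks carry an ERE
                pk = plant(pk, motifs["ERalpha"])
            tss = annotation[gid].tss
            start = tss - config.promoter_length // 2
            peaks.append(PeakRecord(
                f"peak_{gid}", "chr1", start, start + config.peak_length,
                pk, config.peak_fdr_true, assigned_gene=gid,
            ))

    truth = ScenarioTruth(
        mechanism=dict(zip(ids, labels)),
        population={gid: int(y) for gid, y in zip(ids, Y)},
        planted_hub_tf="ERalpha",
        seed=seed,
        config=config,
    )
    return ScenarioBundle(expression, peaks, promoters, motifs, annotation, bg, truth)


# ---------------------------------------------------------------------------
# Epigenetic profiles
# ---------------------------------------------------------------------------

def simulate_epigenetic_profiles(
    N: int,
    seed: int | None = None,
    effect_config: dict[int, tuple[int, float]] | None = None,
) -> tuple[list[GeneEpigeneticProfile], dict]:
    """I.i.d. log-normal promoter features for N genes.

    ``effect_config`` maps mechanism -> (n_planted, multiplier): the first
    n_planted genes get that mechanism's feature multiplied, recorded in the
    returned truth.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = _rng(seed, "epigenetics")
    # log-normal around ~30 tags with unit log-SD: typical promoter tag counts
    draw = lambda: rng.lognormal(mean=np.log(30.0), sigma=1.0, size=N)
    basal, mp, mr, k4, k27 = draw(), draw(), draw(), draw(), draw()
    planted: dict[int, list[int]] = {}
    if effect_config:
        feature_arrays = {1: basal, 2: mr, 3: mp, 4: mr, 5: k27}
        for mech, (n_planted, mult) in effect_config.items():
            arr = feature_arrays[mech]
            arr[:n_planted] *= mult
            planted[mech] = list(range(n_planted))
    profiles = [
        GeneEpigeneticProfile(f"g{i + 1:05d}", basal[i], mp[i], mr[i], k4[i], k27[i])
        for i in range(N)
    ]
    return profiles, {"planted": planted, "seed": seed}
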