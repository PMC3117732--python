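"""Empirical Bayes three-population mixture model for two-condition expression.

Probe-level log2 expression is modelled with a random-effects model

    G_ijkl = mu_il + b_ij + eps_ijkl,   b_ij ~ N(0, delta^2),  eps ~ N(0, sigma^2)

where ``i`` indexes genes, ``j`` probes, ``k`` replicates and ``l`` in {1, 2}
conditions (condition 1 is the reference).  The pair of latent condition means
(mu_i1, mu_i2) comes from one of three latent populations indicated by
Y_i in {1, 0, -1}:

* Y_i = 1   (up-regulated):   (mu_i1, mu_i2) ~ BN(eta_1, Sigma_1), centre above y = x;
* Y_i = 0   (unchanged):      mu_i1 = mu_i2 = mu_i ~ N(lambda, phi^2);
* Y_i = -1  (down-regulated): (mu_i1, mu_i2) ~ BN(eta_-1, Sigma_-1), centre below y = x.

Because everything is linear-Gaussian given Y_i, the probe effects and
condition means integrate out analytically: a gene's stacked observation
vector is multivariate normal with covariance

    sigma^2 I + delta^2 Z Z' + X Sigma_Y X'      (Y = +-1)
    sigma^2 I + delta^2 Z Z' + phi^2 1 1'        (Y = 0)

and the model is fitted by EM over the latent (Y_i, mu_il, b_ij).  Posterior
population probabilities give per-gene calls and an Efron-style local FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-6
_WEIGHT_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneExpression:
    """Probe-by-replicate log2 expression for one gene under two conditions."""

    gene_id: str
    values1: np.ndarray  # shape (n_probes, m1)
    values2: np.ndarray  # shape (n_probes, m2)

    def __post_init__(self) -> None:
        self.values1 = np.atleast_2d(np.asarray(self.values1, dtype=float))
        self.values2 = np.atleast_2d(np.asarray(self.values2, dtype=float))
        if self.values1.shape[0] != self.values2.shape[0]:
            raise ValueError(
                f"gene {self.gene_id}: probe count differs between conditions"
            )
        if self.values1.shape[1] < 1 or self.values2.shape[1] < 1:
            raise ValueError(f"gene {self.gene_id}: need >=1 replicate per condition")
        if not (np.isfinite(self.values1).all() and np.isfinite(self.values2).all()):
            raise ValueError(f"gene {self.gene_id}: non-finite expression value")

    @property
    def n_probes(self) -> int:
        return self.values1.shape[0]

    @property
    def m1(self) -> int:
        return self.values1.shape[1]

    @property
    def m2(self) -> int:
        return self.values2.shape[1]

    def stacked(self) -> np.ndarray:
        """Flatten to 1-D, probe-major, condition-1 replicates first."""
        return np.concatenate(
            [np.concatenate([self.values1[j], self.values2[j]]) for j in range(self.n_probes)]
        )


class ExpressionDataset:
    """An ordered collection of :class:`GeneExpression` records."""

    def __init__(self, genes: Iterable[GeneExpression]):
        self.genes = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id in dataset")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class MixtureParams:
    """Parameter vector theta of the three-population mixture.

    rho = (P(up), P(null), P(down)); eta_* / Sigma_* are the bivariate centres
    and covariances of the up and down populations; (lam, phi) locate the null
    population along y = x; sigma is the replicate-error SD and delta the
    probe-effect SD, shared across genes.
    """

    rho: np.ndarray
    eta1: np.ndarray
    Sigma1: np.ndarray
    eta_neg1: np.ndarray
    Sigma_neg1: np.ndarray
    lam: float
    phi: float
    sigma: float
    delta: float

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.eta1 = np.asarray(self.eta1, dtype=float)
        self.Sigma1 = np.asarray(self.Sigma1, dtype=float)
        self.eta_neg1 = np.asarray(self.eta_neg1, dtype=float)
        self.Sigma_neg1 = np.asarray(self.Sigma_neg1, dtype=float)

    def validate(self) -> None:
        if self.rho.shape != (3,) or abs(self.rho.sum() - 1.0) > 1e-6 or (self.rho < 0).any():
            raise ValueError("rho must be a 3-probability vector summing to 1")
        for name, S in (("Sigma1", self.Sigma1), ("Sigma_neg1", self.Sigma_neg1)):
            if S.shape != (2, 2):
                raise ValueError(f"{name} must be 2x2")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        for name, v in (("phi", self.phi), ("sigma", self.sigma), ("delta", self.delta)):
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.eta1[1] > self.eta1[0]:
            raise ValueError("eta1 must lie above the y=x line (eta1[1] > eta1[0])")
        if not self.eta_neg1[1] < self.eta_neg1[0]:
            raise ValueError("eta_neg1 must lie below the y=x line")


@dataclass
class GenePosterior:
    gene_id: str
    p_up: float
    p_null: float
    p_down: float
    fc: float
    call: str = "unchanged"
    local_fdr: float = 1.0


@dataclass
class FitResult:
    params: MixtureParams
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    n_restarts: int = 1

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else float("nan")


# ---------------------------------------------------------------------------
# Design matrices and structure groups
# ---------------------------------------------------------------------------

def _design(n: int, m1: int, m2: int) -> tuple[np.ndarray, np.ndarray | None]:
    """Condition design X (N x 2) and probe design Z (N x n; None when n == 1)."""
    N = n * (m1 + m2)
    X = np.zeros((N, 2))
    Z = np.zeros((N, n)) if n > 1 else None
    row = 0
    for j in range(n):
        for _ in range(m1):
            X[row, 0] = 1.0
            if Z is not None:
                Z[row, j] = 1.0
            row += 1
        for _ in range(m2):
            X[row, 1] = 1.0
            if Z is not None:
                Z[row, j] = 1.0
            row += 1
    return X, Z


class _StructureGroup:
    """Genes sharing (n_probes, m1, m2); their E-step matrices are shared."""

    def __init__(self, n: int, m1: int, m2: int, idx: list[int], data: np.ndarray):
        self.n, self.m1, self.m2 = n, m1, m2
        self.idx = np.asarray(idx)
        self.data = data  # (n_genes_in_group, N)
        self.X, self.Z = _design(n, m1, m2)
        self.N = self.X.shape[0]


def _group_dataset(dataset: ExpressionDataset) -> list[_StructureGroup]:
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for i, g in enumerate(dataset):
        buckets.setdefault((g.n_probes, g.m1, g.m2), []).append(i)
    groups = []
    for (n, m1, m2), idx in sorted(buckets.items()):
        data = np.stack([dataset.genes[i].stacked() for i in idx])
        groups.append(_StructureGroup(n, m1, m2, idx, data))
    return groups


def _population_system(
    group: _StructureGroup, params: MixtureParams, pop: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (A, prior mean of u, prior cov of u) for latent u given Y = pop.

    u = (mu_i1, mu_i2, b_i1..b_in) for pop = +-1, (mu_i, b_i1..b_in) for pop = 0.
    """
    n = group.n
    has_b = group.Z is not None
    nb = n if has_b else 0
    if pop == 0:
        A = np.empty((group.N, 1 + nb))
        A[:, 0] = 1.0
        if has_b:
            A[:, 1:] = group.Z
        m_u = np.concatenate([[params.lam], np.zeros(nb)])
        P = np.diag(np.concatenate([[params.phi**2], np.full(nb, params.delta**2)]))
    else:
        eta, Sig = (
            (params.eta1, params.Sigma1) if pop == 1 else (params.eta_neg1, params.Sigma_neg1)
        )
        A = np.empty((group.N, 2 + nb))
        A[:, :2] = group.X
        if has_b:
            A[:, 2:] = group.Z
        m_u = np.concatenate([eta, np.zeros(nb)])
        P = np.zeros((2 + nb, 2 + nb))
        P[:2, :2] = Sig
        if has_b:
            P[2:, 2:] = np.eye(nb) * params.delta**2
    return A, m_u, P


def _estep_group(group: _StructureGroup, params: MixtureParams):
    """Per-population log-likelihoods and latent posteriors for one group.

    Returns dict pop -> (loglik per gene, E[u] per gene, posterior cov of u,
    A, prior mean m_u).
    """
    out = {}
    for pop in (1, 0, -1):
        A, m_u, P = _population_system(group, params, pop)
        K = A @ P @ A.T + params.sigma**2 * np.eye(group.N)
        try:
            cho = cho_factor(K, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            gene = group.idx[0]
            raise FloatingPointError(
                f"non-positive-definite marginal covariance (group containing gene index {gene})"
            ) from exc
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        D = group.data - (A @ m_u)  # (n_genes, N)
        KinvD = cho_solve(cho, D.T).T
        ll = -0.5 * (group.N * math.log(2 * math.pi) + logdet + (D * KinvD).sum(axis=1))
        AP = A @ P  # (N, dim_u)
        Eu = m_u + KinvD @ AP
        Pc = P - AP.T @ cho_solve(cho, AP)
        out[pop] = (ll, Eu, Pc, A, m_u)
    return out


# ---------------------------------------------------------------------------
# Likelihood and posteriors
# ---------------------------------------------------------------------------

def per_gene_logliks(dataset: ExpressionDataset, params: MixtureParams) -> np.ndarray:
    """(I, 3) matrix of per-gene conditional log-likelihoods for Y = 1, 0, -1."""
    params.validate()
    L = np.empty((len(dataset), 3))
    for group in _group_dataset(dataset):
        es = _estep_group(group, params)
        for col, pop in enumerate((1, 0, -1)):
            L[group.idx, col] = es[pop][0]
    return L

def marginal_loglik(dataset: ExpressionDataset, params: MixtureParams) -> float:
    """Observed-data log-likelihood: sum over genes of the rho-weighted mixture."""
    L = per_gene_logliks(dataset, params)
    return float(_mixture_loglik(L, params.rho))


def _mixture_loglik(L: np.ndarray, rho: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        A = L + np.log(np.maximum(rho, 1e-300))
    mx = A.max(axis=1)
    return float((mx + np.log(np.exp(A - mx[:, None]).sum(axis=1))).sum())


def _responsibilities(L: np.ndarray, rho: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        A = L + np.log(np.maximum(rho, 1e-300))
    A -= A.max(axis=1, keepdims=True)
    W = np.exp(A)
    W /= W.sum(axis=1, keepdims=True)
    return W  # columns: up, null, down


def posterior_probs(dataset: ExpressionDataset, params: MixtureParams) -> list[GenePosterior]:
    """Posterior population probabilities and signed linear fold-changes.

    fc uses the posterior-mean condition means (population-weighted E[mu_il]):
    ratio 2^(mu2-mu1) when >= 1, else the minus inverse ratio.
    """
    params.validate()
    I = len(dataset)
    L = np.empty((I, 3))
    mu_hat = np.empty((I, 2))
    for group in _group_dataset(dataset):
        es = _estep_group(group, params)
        ll = np.stack([es[pop][0] for pop in (1, 0, -1)], axis=1)
        W = _responsibilities(ll, params.rho)
        mus = np.empty((len(group.idx), 3, 2))
        for col, pop in enumerate((1, 0, -1)):
            Eu = es[pop][1]
            mus[:, col, :] = Eu[:, :2] if pop != 0 else Eu[:, [0, 0]]
        L[group.idx] = ll
        mu_hat[group.idx] = (W[:, :, None] * mus).sum(axis=1)
    W = _responsibilities(L, params.rho)
    out = []
    for i, gid in enumerate(dataset.gene_ids()):
        ratio = 2.0 ** (mu_hat[i, 1] - mu_hat[i, 0])
        fc = ratio if ratio >= 1.0 else -1.0 / ratio
        out.append(GenePosterior(gid, float(W[i, 0]), float(W[i, 1]), float(W[i, 2]), float(fc)))
    return out


def classify_genes(
    posteriors: Sequence[GenePosterior], c: float = 0.80, fc_min: float = 1.20
) -> tuple[list[GenePosterior], float]:
    """Call genes up/down/unchanged with posterior threshold c and a fold-change filter.

    A gene is called up when p_up >= c and fc >= fc_min, down when p_down >= c
    and fc <= -fc_min, else unchanged.  The local FDR of a called gene is
    1 - p_called; the set-level FDR of the call list is the mean local FDR over
    called genes (NaN when nothing is called).
    """
    if not 0 < c < 1:
        raise ValueError("c must be in (0,1)")
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    called_fdrs = []
    out = []
    for p in posteriors:
        call, lfdr = "unchanged", 1.0
        if p.p_up >= c and p.fc >= fc_min:
            call, lfdr = "up", 1.0 - p.p_up
        elif p.p_down >= c and p.fc <= -fc_min:
            call, lfdr = "down", 1.0 - p.p_down
        if call != "unchanged":
            called_fdrs.append(lfdr)
        out.append(replace(p, call=call, local_fdr=lfdr))
    set_fdr = float(np.mean(called_fdrs)) if called_fdrs else float("nan")
    return out, set_fdr


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def moment_init(dataset: ExpressionDataset) -> MixtureParams:
    """Method-of-moments initialization from a 3-way partition of gene mean pairs.

    Genes whose condition-mean difference exceeds +-1 pooled SD seed the up and
    down populations; the rest seed the null.
    """
    means = np.array([[g.values1.mean(), g.values2.mean()] for g in dataset])
    d = means[:, 1] - means[:, 0]
    s = max(d.std(), 1e-3)
    up, down = d > s, d < -s
    null = ~(up | down)
    I = len(dataset)
    rho = np.maximum([up.sum() / I, null.sum() / I, down.sum() / I], 0.02)
    rho = rho / rho.sum()

    def centre(mask, fallback):
        return means[mask].mean(axis=0) if mask.sum() >= 2 else np.asarray(fallback)

    def cov2(mask):
        if mask.sum() >= 5:
            C = np.cov(means[mask].T) + np.eye(2) * 0.01
            if np.linalg.eigvalsh(C).min() > 0:
                return C
        return np.eye(2) * max(d.var(), 0.1)

    lam = float(means[null].mean()) if null.any() else float(means.mean())
    phi = float(max(means[null].mean(axis=1).std(), 0.1)) if null.sum() >= 2 else 1.0
    eta1 = centre(up, [lam - s, lam + s])
    if eta1[1] <= eta1[0]:
        eta1 = np.array([lam - s, lam + s])
    eta_neg1 = centre(down, [lam + s, lam - s])
    if eta_neg1[1] >= eta_neg1[0]:
        eta_neg1 = np.array([lam + s, lam - s])

    # replicate noise: pooled within-probe variance; probe effect: between-probe spread
    resid, probe_var = [], []
    for g in dataset:
        for vals in (g.values1, g.values2):
            if vals.shape[1] > 1:
                resid.append(vals.var(axis=1, ddof=1).mean())
            if vals.shape[0] > 1:
                probe_var.append(vals.mean(axis=1).var(ddof=1))
    sigma = math.sqrt(max(np.mean(resid), 0.01)) if resid else 0.3
    delta = math.sqrt(max(np.mean(probe_var) - sigma**2 / 2, 0.01)) if probe_var else 0.3
    return MixtureParams(rho, eta1, cov2(up), eta_neg1, cov2(down), lam, phi, sigma, delta)


def _jitter(params: MixtureParams, rng: np.random.Generator) -> MixtureParams:
    p = replace(params)
    p.rho = np.maximum(params.rho + rng.normal(0, 0.03, 3), 0.01)
    p.rho /= p.rho.sum()
    p.eta1 = params.eta1 + rng.normal(0, 0.3, 2)
    if p.eta1[1] <= p.eta1[0]:
        p.eta1 = p.eta1[::-1] + [0.0, 1e-3]
    p.eta_neg1 = params.eta_neg1 + rng.normal(0, 0.3, 2)
    if p.eta_neg1[1] >= p.eta_neg1[0]:
        p.eta_neg1 = p.eta_neg1[::-1] + [1e-3, 0.0]
    p.lam = params.lam + rng.normal(0, 0.3)
    p.phi = abs(params.phi * math.exp(rng.normal(0, 0.2)))
    p.sigma = abs(params.sigma * math.exp(rng.normal(0, 0.2)))
    p.delta = abs(params.delta * math.exp(rng.normal(0, 0.2)))
    return p


def _em_once(
    dataset: ExpressionDataset,
    params: MixtureParams,
    tol: float,
    max_iter: int,
) -> FitResult:
    groups = _group_dataset(dataset)
    I = len(dataset)
    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        # --- E-step (also yields the current observed-data log-likelihood) ---
        L = np.empty((I, 3))
        estats = []
        for group in groups:
            es = _estep_group(group, params)
            L[group.idx] = np.stack([es[pop][0] for pop in (1, 0, -1)], axis=1)
            estats.append((group, es))
        trace.append(_mixture_loglik(L, params.rho))
        W = _responsibilities(L, params.rho)

        # --- M-step accumulators ---
        sw = W.sum(axis=0)  # per-population weight: up, null, down
        eta_acc = {1: np.zeros(2), -1: np.zeros(2)}
        Sig_acc = {1: np.zeros((2, 2)), -1: np.zeros((2, 2))}
        lam_acc = phi_acc = 0.0
        b2_acc = b_den = 0.0
        r2_acc = r_den = 0.0
        for group, es in estats:
            Wg = W[group.idx]
            for col, pop in enumerate((1, 0, -1)):
                ll, Eu, Pc, A, m_u = es[pop]
                w = Wg[:, col]
                wsum = w.sum()
                if pop != 0:
                    mu = Eu[:, :2]
                    eta_acc[pop] += w @ mu
                    dev = mu  # recentred below once eta is known; store raw moments
                    Sig_acc[pop] += (w[:, None, None] * (dev[:, :, None] * dev[:, None, :])).sum(
                        axis=0
                    ) + wsum * Pc[:2, :2]
                else:
                    lam_acc += w @ Eu[:, 0]
                    phi_acc += w @ (Eu[:, 0] ** 2) + wsum * Pc[0, 0]
                if group.Z is not None:
                    off = 2 if pop != 0 else 1
                    B = Eu[:, off:]
                    b2_acc += (w[:, None] * B**2).sum() + wsum * np.trace(Pc[off:, off:])
                resid = group.data - Eu @ A.T
                r2_acc += (w[:, None] * resid**2).sum() + wsum * np.trace(A @ Pc @ A.T)
            if group.Z is not None:
                b_den += group.n * len(group.idx)
            r_den += group.N * len(group.idx)

        rho = sw / I
        if (rho < _WEIGHT_FLOOR).any():
            logger.warning("mixture weight floored at %g", _WEIGHT_FLOOR)
            rho = np.maximum(rho, _WEIGHT_FLOOR)
            rho /= rho.sum()
        eta1 = eta_acc[1] / max(sw[0], 1e-12)
        eta_neg1 = eta_acc[-1] / max(sw[2], 1e-12)
        Sigma1 = Sig_acc[1] / max(sw[0], 1e-12) - np.outer(eta1, eta1)
        Sigma_neg1 = Sig_acc[-1] / max(sw[2], 1e-12) - np.outer(eta_neg1, eta_neg1)
        for S in (Sigma1, Sigma_neg1):
            S += np.eye(2) * _VAR_FLOOR
            S[:] = (S + S.T) / 2
        lam = lam_acc / max(sw[1], 1e-12)
        phi2 = max(phi_acc / max(sw[1], 1e-12) - lam**2, _VAR_FLOOR)
        delta2 = max(b2_acc / b_den, _VAR_FLOOR) if b_den > 0 else params.delta**2
        sigma2 = max(r2_acc / r_den, _VAR_FLOOR)

        new = MixtureParams(
            rho, eta1, Sigma1, eta_neg1, Sigma_neg1,
            float(lam), math.sqrt(phi2), math.sqrt(sigma2), math.sqrt(delta2),
        )
        # keep the population labels on their side of y = x
        if new.eta1[1] <= new.eta1[0] or new.eta_neg1[1] >= new.eta_neg1[0]:
            if new.eta1[1] <= new.eta1[0] and new.eta_neg1[1] >= new.eta_neg1[0]:
                new = replace(
                    new,
                    rho=new.rho[[2, 1, 0]],
                    eta1=new.eta_neg1, Sigma1=new.Sigma_neg1,
                    eta_neg1=new.eta1, Sigma_neg1=new.Sigma1,
                )
            else:  # degenerate: nudge the offending centre across the line
                if new.eta1[1] <= new.eta1[0]:
                    m = new.eta1.mean()
                    new = replace(new, eta1=np.array([m - 1e-3, m + 1e-3]))
                if new.eta_neg1[1] >= new.eta_neg1[0]:
                    m = new.eta_neg1.mean()
                    new = replace(new, eta_neg1=np.array([m + 1e-3, m - 1e-3]))
        params = new

        if it > 0 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
    trace.append(marginal_loglik(dataset, params))
    return FitResult(params, trace, n_iter=len(trace) - 1, converged=converged)


def fit_em(
    dataset: ExpressionDataset,
    init: MixtureParams | str = "auto",
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 1,
    seed: int | None = None,
) -> FitResult:
    """Fit the mixture by EM; best of ``n_restarts`` (first uses the moment init)."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if len(dataset) < 50:
        logger.warning("EM fit on %d genes; >=50 recommended", len(dataset))
    base = moment_init(dataset) if init == "auto" else init
    base.validate()
    rng = np.random.default_rng(seed)
    best: FitResult | None = None
    for r in range(max(1, n_restarts)):
        start = base if r == 0 else _jitter(base, rng)
        res = _em_once(dataset, start, tol, max_iter)
        if best is None or res.loglik > best.loglik:
            best = res
    best.n_restarts = max(1, n_restarts)
    return best
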