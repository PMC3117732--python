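"""PWM motif scanning and local-FDR calibration against a Markov background.

A TF motif is a position probability matrix (PWM).  Each sequence receives one
binding score: the maximum, over all offsets and both strands, of the summed
log2 odds of the PWM against a 0-order background.  Scores of real sequences
are calibrated against scores of R sequences sampled from an order-k Markov
model of the genomic background (default order 6): the score range is cut into
k bins, sparsely occupied bins are collapsed, and the local FDR in bin b is

    FDR_b = min(1, (I * n_b / R) / m_b)

with m_b observed-score and n_b null-score counts, I observed sequences and R
null sequences.  Bins below the midpoint of the score range are forced to
FDR 1, and a cubic smoothing spline through (bin midpoint, FDR_b) gives the
local FDR at an arbitrary score, clamped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LSQUnivariateSpline, UnivariateSpline, interp1d

from .io import MotifMatrix

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else (N) = 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, code in _BASE_TO_INT.items():
        out[arr == ord(base)] = code
    return out


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Markov background
# ---------------------------------------------------------------------------

@dataclass
class MarkovBackground:
    """Order-k Markov chain over {A,C,G,T}.

    ``transition`` has shape (4**order, 4): row c is the next-base distribution
    given the integer-encoded context c.  ``start`` is the empirical context
    frequency used to seed sampling.
    """

    order: int
    transition: np.ndarray
    start: np.ndarray

    def stationary_base_freqs(self) -> np.ndarray:
        """Marginal base frequencies implied by start-context x transition."""
        return self.start @ self.transition

    def zero_order(self) -> np.ndarray:
        return self.stationary_base_freqs()


def _context_codes(codes: np.ndarray, order: int) -> np.ndarray:
    """Rolling base-4 context codes for every position >= order; -1 where any N."""
    n = len(codes)
    if n <= order:
        return np.empty(0, dtype=np.int64)
    if order == 0:
        return np.zeros(n, dtype=np.int64)
    valid = codes < 4
    ctx = np.zeros(n - order, dtype=np.int64)
    ok = np.ones(n - order, dtype=bool)
    for d in range(order):
        c = codes[d : d + n - order]
        ctx = ctx * 4 + np.where(c < 4, c, 0)
        ok &= valid[d : d + n - order]
    ctx[~ok] = -1
    return ctx


def train_background(
    sequences: dict[str, str] | list[str], order: int = 6, pseudocount: float = 1.0
) -> MarkovBackground:
    """Estimate the background Markov chain from training sequences.

    Transition rows are (count + pseudocount) / (row total + 4 * pseudocount);
    the start distribution is the empirical frequency of contexts.
    """
    if isinstance(sequences, dict):
        sequences = list(sequences.values())
    n_ctx = 4**order
    counts = np.zeros((n_ctx, 4))
    start_counts = np.zeros(n_ctx)
    used = 0
    total_len = 0
    for seq in sequences:
        codes = _encode(seq)
        if len(codes) < order + 1:
            logger.warning("skipping training sequence shorter than order+1")
            continue
        used += 1
        total_len += len(codes)
        ctx = _context_codes(codes, order)
        nxt = codes[order:]
        ok = (ctx >= 0) & (nxt < 4)
        np.add.at(counts, (ctx[ok], nxt[ok]), 1.0)
        np.add.at(start_counts, ctx[ok], 1.0)
    if used == 0:
        raise ValueError("no training sequence of length >= order+1")
    if total_len < n_ctx:
        logger.warning("training length %d < 4^%d contexts; estimates are diffuse", total_len, order)
    trans = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    if start_counts.sum() == 0:
        start = np.full(n_ctx, 1.0 / n_ctx)
    else:
        start = start_counts / start_counts.sum()
    return MarkovBackground(order, trans, start)


def sample_sequences(
    bg: MarkovBackground, R: int = 10_000, length: int = 45, seed: int | None = None
) -> list[str]:
    """Sample R sequences of the given length from the background chain."""
    if length <= bg.order:
        raise ValueError("length must exceed the background order")
    rng = np.random.default_rng(seed)
    n_ctx = 4**bg.order
    ctx = rng.choice(n_ctx, size=R, p=bg.start)
    out = np.empty((R, length), dtype=np.int64)
    # emit the start context itself, then chain transitions
    c = ctx.copy()
    for d in range(bg.order - 1, -1, -1):
        out[:, d] = c % 4
        c //= 4
    cum = np.cumsum(bg.transition, axis=1)
    for pos in range(bg.order, length):
        u = rng.random(R)
        nxt = (u[:, None] > cum[ctx]).sum(axis=1)
        out[:, pos] = nxt
        ctx = (ctx * 4 + nxt) % n_ctx if bg.order > 0 else ctx
    lut = np.array(list(_BASES))
    return ["".join(row) for row in lut[out]]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _logodds(motif: MotifMatrix, bg0: np.ndarray) -> np.ndarray:
    """(5, width) log2-odds with an all-zero row for N bases."""
    bg0 = np.asarray(bg0, dtype=float)
    if bg0.shape != (4,) or abs(bg0.sum() - 1) > 1e-6 or (bg0 <= 0).any():
        raise ValueError("bg0 must be a strictly positive 4-probability vector")
    lo = np.zeros((5, motif.width))
    lo[:4] = np.log2(motif.probs / bg0[:, None])
    return lo


def scan_score(motif: MotifMatrix, sequence: str, bg0: np.ndarray) -> float:
    """Best log2-odds window score over both strands of one sequence."""
    if len(sequence) < motif.width:
        raise ValueError(
            f"sequence length {len(sequence)} < motif width {motif.width}"
        )
    return float(scan_scores(motif, [sequence], bg0)[0])


def scan_scores(motif: MotifMatrix, sequences: list[str], bg0: np.ndarray) -> np.ndarray:
    """Vectorised max-window score for a batch of equal-or-varied-length sequences."""
    lo = _logodds(motif, bg0)
    lo_rc = lo[[3, 2, 1, 0, 4], ::-1]  # reverse-complement strand
    W = motif.width
    scores = np.empty(len(sequences))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        if len(s) < W:
            raise ValueError(f"sequence {i} shorter than motif width {W}")
        by_len.setdefault(len(s), []).append(i)
    for L, idx in by_len.items():
        enc = np.stack([_encode(sequences[i]) for i in idx])  # (n, L)
        n_off = L - W + 1
        best = np.full(len(idx), -np.inf)
        for o in range(n_off):
            window = enc[:, o : o + W]
            fwd = lo[window, np.arange(W)].sum(axis=1)
            rev = lo_rc[window, np.arange(W)].sum(axis=1)
            best = np.maximum(best, np.maximum(fwd, rev))
        scores[idx] = best
    return scores


# ---------------------------------------------------------------------------
# Local-FDR curve
# ---------------------------------------------------------------------------

@dataclass
class ScoreFdrCurve:
    """Binned observed vs null score counts with a spline-smoothed local FDR."""

    motif_id: str
    bin_edges: np.ndarray  # len = n_bins + 1 (after collapsing)
    m_b: np.ndarray
    n_b: np.ndarray
    R: int
    I: int
    fdr_b: np.ndarray
    forced_below: float = -np.inf  # scores <= this evaluate to exactly 1
    _spline: object = field(default=None, repr=False)

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _collapse_bins(edges: np.ndarray, m: np.ndarray, n: np.ndarray, min_bin: int):
    """Merge bins left-to-right until each holds >= min_bin observed scores.

    A deficient tail is merged into the last kept bin, so sum(m) and sum(n)
    are conserved.
    """
    new_edges = [edges[0]]
    new_m, new_n = [], []
    acc_m = acc_n = 0.0
    for b in range(len(m)):
        acc_m += m[b]
        acc_n += n[b]
        if acc_m >= min_bin:
            new_edges.append(edges[b + 1])
            new_m.append(acc_m)
            new_n.append(acc_n)
            acc_m = acc_n = 0.0
    if acc_m > 0 or acc_n > 0:
        if new_m:
            new_m[-1] += acc_m
            new_n[-1] += acc_n
            new_edges[-1] = edges[-1]
        else:
            new_edges.append(edges[-1])
            new_m.append(acc_m)
            new_n.append(acc_n)
    return np.array(new_edges), np.array(new_m), np.array(new_n)


def build_fdr_curve(
    observed_scores: np.ndarray,
    null_scores: np.ndarray,
    motif_id: str = "",
    k: int = 200,
    min_bin: int = 20,
) -> ScoreFdrCurve:
    """Bin observed vs null scores and fit the smoothed local-FDR curve."""
    obs = np.asarray(observed_scores, dtype=float)
    null = np.asarray(null_scores, dtype=float)
    if obs.size == 0:
        raise ValueError("observed_scores is empty")
    if null.size == 0:
        raise ValueError("null_scores is empty")
    lo = min(obs.min(), null.min())
    hi = max(obs.max(), null.max())
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, k + 1)
    m, _ = np.histogram(obs, bins=edges)
    n, _ = np.histogram(null, bins=edges)
    edges, m, n = _collapse_bins(edges, m.astype(float), n.astype(float), min_bin)
    if len(m) < 2:
        raise ValueError("degenerate score distribution")
    I, R = obs.size, null.size
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.minimum(1.0, (I * n / R) / m)
    fdr = np.where(m > 0, fdr, 1.0)
    midpoint = 0.5 * (lo + hi)
    forced = edges[1:] <= midpoint
    fdr[forced] = 1.0
    curve = ScoreFdrCurve(motif_id, edges, m, n, R, I, fdr,
                          forced_below=midpoint if forced.any() else -np.inf)
    curve._spline = _fit_spline(curve.midpoints(), fdr)
    return curve


def _fit_spline(x: np.ndarray, y: np.ndarray):
    """Cubic smoothing spline with knot count tied to the unique FDR values."""
    n_knots = len(np.unique(y))
    if len(x) >= 5 and n_knots >= 2:
        try:
            q = np.linspace(0, 1, min(n_knots, len(x) - 2) + 2)[1:-1]
            knots = np.unique(np.quantile(x, q))
            knots = knots[(knots > x[0]) & (knots < x[-1])]
            if len(knots) > 0:
                return LSQUnivariateSpline(x, y, knots, k=3)
            return UnivariateSpline(x, y, k=3, s=len(x) * 1e-4)
        except Exception:  # pragma: no cover - spline degeneracies
            pass
    return interp1d(x, y, kind="linear", bounds_error=False,
                    fill_value=(y[0], y[-1]))


def site_fdr(curve: ScoreFdrCurve, score: float) -> float:
    """Local FDR at a score: spline value clamped to [0,1]; boundary values
    beyond the fitted range; exactly 1 in the forced low-score region."""
    s = float(score)
    if s <= curve.forced_below:
        return 1.0
    mids = curve.midpoints()
    s_clamped = min(max(s, mids[0]), mids[-1])
    val = float(curve._spline(s_clamped))
    return min(max(val, 0.0), 1.0)


def site_fdrs(curve: ScoreFdrCurve, scores: np.ndarray) -> np.ndarray:
    return np.array([site_fdr(curve, s) for s in np.asarray(scores, dtype=float)])
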