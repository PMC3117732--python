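"""Tests for Markov background training/sampling, PWM scanning and FDR curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ernet import motif, simulate
from ernet.io import MotifMatrix
from ernet.motif import (
    MarkovBackground, ScoreFdrCurve, build_fdr_curve, revcomp,
    sample_sequences, scan_score, scan_scores, site_fdr, train_background,
    _fit_spline,
)

UNIFORM4 = np.full(4, 0.25)


class TestBackground:
    def test_order0_symmetric_input(self):
        bg = train_background(["ACGT"], order=0)
        np.testing.assert_allclose(bg.transition[0], UNIFORM4)

    def test_order1_hand_count(self):
        # "A"*10: 9 A->A transitions, pseudocount 1: (9+1)/(9+4)
        bg = train_background(["AAAAAAAAAA"], order=1)
        assert bg.transition[0, 0] == pytest.approx(10 / 13)

    def test_rows_normalized(self):
        bg = train_background(["ACGTACGTGGCC", "TTGACA"], order=2)
        np.testing.assert_allclose(bg.transition.sum(axis=1), 1.0, atol=1e-9)

    def test_short_sequences_skipped_then_error(self, caplog):
        bg = train_background(["AC", "ACGTACGT"], order=3)
        assert bg.order == 3
        with pytest.raises(ValueError, match="no training sequence"):
            train_background(["AC"], order=3)


class TestSampling:
    def test_deterministic_under_seed(self, background_order2):
        a = sample_sequences(background_order2, R=20, length=50, seed=42)
        b = sample_sequences(background_order2, R=20, length=50, seed=42)
        assert a == b

    def test_pure_a_background(self):
        bg = train_background(["A" * 500], order=1)
        seqs = sample_sequences(bg, R=200, length=100, seed=1)
        frac_a = np.mean([s.count("A") / len(s) for s in seqs])
        assert frac_a >= 0.95

    def test_mononucleotide_frequencies_match(self):
        bg = simulate.iid_background(order=2)
        seqs = sample_sequences(bg, R=2000, length=500, seed=3)
        counts = np.zeros(4)
        for s in seqs:
            for i, b in enumerate("ACGT"):
                counts[i] += s.count(b)
        freqs = counts / counts.sum()
        np.testing.assert_allclose(freqs, bg.stationary_base_freqs(), atol=0.01)

    def test_length_must_exceed_order(self, background_order2):
        with pytest.raises(ValueError, match="length"):
            sample_sequences(background_order2, R=5, length=2, seed=0)


class TestScan:
    def test_motif_equal_to_background_scores_zero(self):
        m = MotifMatrix("M_U", "U", np.full((4, 6), 0.25))
        assert scan_score(m, "ACGTACGTAC", UNIFORM4) == pytest.approx(0.0, abs=1e-12)

    def test_pseudocounted_polyA_motif_arithmetic(self):
        # TRANSFAC counts 10/0/0/0 with 0.01 pseudocount per cell:
        # per-column log2((10.01/10.04)/0.25); 4 columns on "AAAA"
        p_a = 10.01 / 10.04
        col = np.array([p_a, 0.01 / 10.04, 0.01 / 10.04, 0.02 / 10.04])
        col = col / col.sum()
        m = MotifMatrix("M_A", "A4", np.tile(col[:, None], (1, 4)))
        expected = 4 * np.log2(col[0] / 0.25)
        assert scan_score(m, "AAAA", UNIFORM4) == pytest.approx(expected, abs=1e-9)

    def test_n_bases_contribute_zero(self, ere_motif):
        w = ere_motif.width
        assert scan_score(ere_motif, "N" * w, UNIFORM4) == pytest.approx(0.0)

    def test_too_short_sequence(self, ere_motif):
        with pytest.raises(ValueError, match="width"):
            scan_score(ere_motif, "ACG", UNIFORM4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=13, max_size=40))
    def test_strand_symmetry(self, seq):
        m = simulate.default_tf_motifs()["ERalpha"]
        a = scan_score(m, seq, UNIFORM4)
        b = scan_score(m, revcomp(seq), UNIFORM4)
        assert a == pytest.approx(b, abs=1e-9)


def _fixture_curve(fdrs, lo=0.0, hi=10.0, forced_below=-np.inf):
    edges = np.linspace(lo, hi, len(fdrs) + 1)
    curve = ScoreFdrCurve("m", edges, np.full(len(fdrs), 30.0),
                          np.full(len(fdrs), 30.0), 100, 100,
                          np.asarray(fdrs, dtype=float), forced_below=forced_below)
    curve._spline = _fit_spline(curve.midpoints(), curve.fdr_b)
    return curve


class TestFdrCurve:
    def test_counts_conserved_after_collapse(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(0, 1, 500)
        null = rng.normal(0, 1, 3000)
        curve = build_fdr_curve(obs, null, k=200, min_bin=20)
        assert curve.m_b.sum() == 500
        assert curve.n_b.sum() == 3000

    def test_top_bin_without_null_scores_fdr_zero(self):
        rng = np.random.default_rng(1)
        obs = np.concatenate([rng.normal(0, 1, 400), rng.normal(12, 0.3, 100)])
        null = rng.normal(0, 1, 5000)
        curve = build_fdr_curve(obs, null, k=50, min_bin=20)
        assert curve.fdr_b[-1] == 0.0

    def test_bins_below_midpoint_forced_to_one(self):
        rng = np.random.default_rng(2)
        obs = rng.normal(0, 1, 2000)
        null = rng.normal(0, 1, 2000)
        curve = build_fdr_curve(obs, null, k=100, min_bin=20)
        mid = 0.5 * (curve.bin_edges[0] + curve.bin_edges[-1])
        below = curve.bin_edges[1:] <= mid
        assert below.any()
        assert (curve.fdr_b[below] == 1.0).all()

    def test_degenerate_distribution_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_fdr_curve(np.full(5, 1.0), np.full(5, 1.0), k=10, min_bin=20)

    def test_null_observed_scores_calibrate_to_one(self, background_order2, ere_motif):
        """Observed scores drawn from the calibrated null give FDR ~ 1 above midpoint."""
        bg0 = background_order2.zero_order()
        obs = scan_scores(ere_motif,
                          sample_sequences(background_order2, 3000, 45, seed=4), bg0)
        null = scan_scores(ere_motif,
                           sample_sequences(background_order2, 3000, 45, seed=5), bg0)
        curve = build_fdr_curve(obs, null)
        mid = 0.5 * (curve.bin_edges[0] + curve.bin_edges[-1])
        mids = curve.midpoints()
        above = mids > mid
        # evaluate the smoothed estimate: raw tail bins at occupancy 20 carry
        # ~0.3 binomial SD even when observed == null in distribution
        smoothed = np.array([site_fdr(curve, s) for s in mids[above]])
        assert np.abs(smoothed - 1.0).max() <= 0.15


class TestSiteFdr:
    def test_forced_region_returns_one(self):
        curve = _fixture_curve([1, 1, 1, 0.5, 0.1, 0.0], forced_below=5.0)
        assert site_fdr(curve, 2.0) == 1.0

    def test_constant_curve(self):
        curve = _fixture_curve([0.3] * 8)
        for s in (-5.0, 0.1, 5.0, 20.0):
            assert site_fdr(curve, s) == pytest.approx(0.3, abs=1e-6)

    def test_spline_tracks_bin_values(self):
        fdrs = [1.0, 1.0, 0.9, 0.7, 0.5, 0.3, 0.15, 0.05, 0.0, 0.0]
        curve = _fixture_curve(fdrs)
        for m, f in zip(curve.midpoints(), fdrs):
            assert abs(site_fdr(curve, m) - f) <= 0.1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_output_in_unit_interval(self, score):
        curve = _fixture_curve([1.0, 0.9, 0.4, 0.2, 0.6, 0.05, 0.0], forced_below=1.0)
        assert 0.0 <= site_fdr(curve, score) <= 1.0

    def test_boundary_values_beyond_range(self):
        fdrs = [1.0, 0.8, 0.4, 0.1, 0.0]
        curve = _fixture_curve(fdrs)
        assert site_fdr(curve, 1e6) == pytest.approx(site_fdr(curve, curve.midpoints()[-1]))


class TestPlantedPower:
    def test_planted_strong_motif_detected(self, ere_motif):
        """50% planted sites: >=80% of them get site FDR < 0.05."""
        bg = simulate.iid_background(order=3)
        seqs, truth = simulate.simulate_sequences_with_motifs(
            bg, ere_motif, n_seqs=1000, length=45, plant_rate=0.5, seed=9)
        bg0 = bg.zero_order()
        obs = scan_scores(ere_motif, list(seqs.values()), bg0)
        null = scan_scores(ere_motif, sample_sequences(bg, 5000, 45, seed=10), bg0)
        curve = build_fdr_curve(obs, null)
        fdrs = {sid: site_fdr(curve, s) for sid, s in zip(seqs, obs)}
        planted = [fdrs[sid] for sid in truth["positions"]]
        assert np.mean(np.array(planted) < 0.05) >= 0.80
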