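"""Unit and property tests for the three-population EB expression model."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from ernet import diffexpr, simulate
from ernet.diffexpr import (
    ExpressionDataset, GeneExpression, MixtureParams,
    classify_genes, fit_em, marginal_loglik, posterior_probs,
)


def quad_gene_logliks(g1_vals, g2_vals, params):
    """Numerical-integration oracle: per-population marginal likelihood of a
    single-probe gene, integrating the latent condition means on a grid."""
    g1, g2 = np.asarray(g1_vals), np.asarray(g2_vals)
    s = params.sigma

    def data_lik(mu1, mu2):
        return (np.prod(stats.norm.pdf(g1, mu1, s))
                * np.prod(stats.norm.pdf(g2, mu2, s)))

    out = {}
    for pop in (1, -1):
        eta, Sig = (params.eta1, params.Sigma1) if pop == 1 else (
            params.eta_neg1, params.Sigma_neg1)
        rv = stats.multivariate_normal(eta, Sig)
        val, _ = integrate.dblquad(
            lambda y, x: rv.pdf([x, y]) * data_lik(x, y),
            eta[0] - 8, eta[0] + 8, lambda x: eta[1] - 8, lambda x: eta[1] + 8,
            epsabs=1e-12, epsrel=1e-10,
        )
        out[pop] = math.log(val)
    val, _ = integrate.quad(
        lambda m: stats.norm.pdf(m, params.lam, params.phi) * data_lik(m, m),
        params.lam - 10 * params.phi, params.lam + 10 * params.phi,
        epsabs=1e-13, limit=200,
    )
    out[0] = math.log(val)
    return out


class TestMarginalLoglik:
    def test_matches_quadrature_oracle(self, simple_params):
        ds = ExpressionDataset([GeneExpression("g", [[6.4]], [[7.9]])])
        ora = quad_gene_logliks([6.4], [7.9], simple_params)
        rho = simple_params.rho
        expected = math.log(rho[0] * math.exp(ora[1]) + rho[1] * math.exp(ora[0])
                            + rho[2] * math.exp(ora[-1]))
        assert marginal_loglik(ds, simple_params) == pytest.approx(expected, abs=1e-6)

    def test_null_only_closed_form(self, simple_params):
        # rho=(0,1,0) floored slightly to satisfy validation; compare the pure
        # null population likelihood against the closed-form normal density.
        p = simple_params
        params = MixtureParams(np.array([0.0, 1.0, 0.0]), p.eta1, p.Sigma1,
                               p.eta_neg1, p.Sigma_neg1, p.lam, p.phi, p.sigma, p.delta)
        lam = params.lam
        ds = ExpressionDataset([GeneExpression("g", [[lam]], [[lam]])])
        # (g1,g2) ~ N(lam*1, phi^2*11' + sigma^2 I); at the mean the density is
        # 1/(2*pi*sqrt(det))
        C = params.phi**2 * np.ones((2, 2)) + params.sigma**2 * np.eye(2)
        expected = math.log(1.0 / (2 * math.pi * math.sqrt(np.linalg.det(C))))
        assert marginal_loglik(ds, params) == pytest.approx(expected, abs=1e-10)

    def test_duplicating_genes_doubles_loglik(self, simple_params, tiny_dataset):
        ll = marginal_loglik(tiny_dataset, simple_params)
        doubled = ExpressionDataset(
            list(tiny_dataset)
            + [GeneExpression(g.gene_id + "_copy", g.values1, g.values2)
               for g in tiny_dataset]
        )
        assert marginal_loglik(doubled, simple_params) == pytest.approx(2 * ll, rel=1e-12)


class TestPosteriors:
    def test_posteriors_match_quadrature_oracle(self, simple_params):
        genes = [("a", [6.2, 6.5], [7.8, 8.1]), ("b", [7.0, 7.2], [7.1, 6.9]),
                 ("c", [8.3, 8.1], [6.2, 6.4])]
        ds = ExpressionDataset(
            [GeneExpression(n, [v1], [v2]) for n, v1, v2 in genes])
        posts = posterior_probs(ds, simple_params)
        rho = simple_params.rho
        for (name, v1, v2), post in zip(genes, posts):
            ora = quad_gene_logliks(v1, v2, simple_params)
            w = np.array([rho[0] * math.exp(ora[1]), rho[1] * math.exp(ora[0]),
                          rho[2] * math.exp(ora[-1])])
            w /= w.sum()
            assert post.p_up == pytest.approx(w[0], abs=1e-5)
            assert post.p_null == pytest.approx(w[1], abs=1e-5)
            assert post.p_down == pytest.approx(w[2], abs=1e-5)

    def test_probabilities_normalized(self, simple_params, tiny_dataset):
        for p in posterior_probs(tiny_dataset, simple_params):
            assert p.p_up + p.p_null + p.p_down == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_equal_condition_means(self, simple_params):
        ds = ExpressionDataset([GeneExpression("g", [[7.0]], [[7.0]])])
        (p,) = posterior_probs(ds, simple_params)
        assert p.p_up == pytest.approx(p.p_down, abs=1e-12)

    def test_far_up_gene_is_confident(self, simple_params):
        # a gene 10 joint SDs above the y=x line
        ds = ExpressionDataset([GeneExpression("g", [[6.0, 6.0]], [[9.5, 9.5]])])
        (p,) = posterior_probs(ds, simple_params)
        assert p.p_up > 0.999

    def test_condition_swap_mirrors_posteriors(self, simple_params, tiny_dataset):
        p = simple_params
        mirrored = MixtureParams(
            p.rho[[2, 1, 0]],
            p.eta_neg1[::-1], p.Sigma_neg1[::-1, ::-1].copy(),
            p.eta1[::-1], p.Sigma1[::-1, ::-1].copy(),
            p.lam, p.phi, p.sigma, p.delta,
        )
        swapped = ExpressionDataset(
            [GeneExpression(g.gene_id, g.values2, g.values1) for g in tiny_dataset])
        for a, b in zip(posterior_probs(tiny_dataset, simple_params),
                        posterior_probs(swapped, mirrored)):
            assert a.p_up == pytest.approx(b.p_down, abs=1e-10)
            assert a.p_null == pytest.approx(b.p_null, abs=1e-10)


class TestClassify:
    @pytest.mark.parametrize(
        "p_up,p_down,fc,expected_call,expected_lfdr",
        [
            (0.90, 0.05, 1.5, "up", 0.10),
            (0.95, 0.01, 1.10, "unchanged", 1.0),  # fails the 20% filter
            (0.45, 0.45, 1.5, "unchanged", 1.0),
            (0.05, 0.90, -1.5, "down", 0.10),
        ],
    )
    def test_call_rules(self, p_up, p_down, fc, expected_call, expected_lfdr):
        post = diffexpr.GenePosterior("g", p_up, 1 - p_up - p_down, p_down, fc)
        (out,), set_fdr = classify_genes([post])
        assert out.call == expected_call
        assert out.local_fdr == pytest.approx(expected_lfdr)

    def test_empty_input(self):
        out, set_fdr = classify_genes([])
        assert out == [] and math.isnan(set_fdr)

    def test_set_fdr_is_mean_local_fdr(self):
        posts = [diffexpr.GenePosterior("a", 0.9, 0.1, 0.0, 2.0),
                 diffexpr.GenePosterior("b", 0.85, 0.15, 0.0, 2.0)]
        _, set_fdr = classify_genes(posts)
        assert set_fdr == pytest.approx((0.1 + 0.15) / 2)


class TestEM:
    def test_loglik_monotone(self):
        params = simulate.default_mixture_params()
        ds, _ = simulate.simulate_expression(params, I=150, seed=11)
        fit = fit_em(ds, max_iter=60, seed=0)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-10 * np.abs(trace[:-1])).all()

    def test_null_data_yields_no_calls(self):
        """Zero-effect data: the null population dominates and nothing is called.

        The directional components can legally collapse onto the y=x line (a
        nested-mixture degeneracy), so rho_null need not reach 1; the
        substantive guarantee is that no gene is called differential.
        """
        params = simulate.default_mixture_params()
        params.rho = np.array([0.005, 0.99, 0.005])
        ds, _ = simulate.simulate_expression(
            params, I=400, seed=12, populations=np.zeros(400, dtype=int))
        fit = fit_em(ds, max_iter=800, seed=0)
        assert fit.params.rho[1] >= 0.8
        posts, _ = classify_genes(posterior_probs(ds, fit.params))
        assert sum(p.call != "unchanged" for p in posts) == 0

    def test_single_probe_genes_supported(self):
        params = simulate.default_mixture_params()
        ds, _ = simulate.simulate_expression(params, I=120, probes_per_gene=1, seed=3)
        fit = fit_em(ds, max_iter=40, seed=0)
        assert np.isfinite(fit.loglik)


class TestCalibration:
    def test_local_fdr_matches_false_call_rate(self):
        """Mean local FDR among called genes tracks the realised error rate."""
        params = simulate.default_mixture_params()
        ds, truth = simulate.simulate_expression(params, I=2000, seed=21)
        fit = fit_em(ds, max_iter=300, seed=1)
        posts = posterior_probs(ds, fit.params)
        posts, set_fdr = classify_genes(posts)
        label = {1: "up", 0: "unchanged", -1: "down"}
        true_call = dict(zip(truth["gene_ids"], (label[y] for y in truth["Y"])))
        called = [p for p in posts if p.call != "unchanged"]
        realized = np.mean([true_call[p.gene_id] != p.call for p in called])
        assert set_fdr == pytest.approx(realized, abs=0.05)
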