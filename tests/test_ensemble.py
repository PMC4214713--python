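"""Posterior moments, sequential updating and significance testing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from minedesign import (
    DataSet,
    EnsemblePosterior,
    NumericalDegeneracyError,
    TruthConfig,
    bh_stepup,
    fit_posterior,
    significance_test,
    update_posterior,
)

from conftest import random_posterior


class TestFitPosterior:
    def test_no_data_returns_prior(self):
        post = fit_posterior(DataSet.empty(3), sigma=1.0, b=2.0)
        assert np.allclose(post.mu, 0.0)
        assert np.allclose(post.Gamma, 0.5 * np.eye(3))
        assert post.n_obs == 0

    def test_prior_scales_with_noise(self):
        post = fit_posterior(DataSet.empty(4), sigma=0.5, b=2.0)
        assert np.allclose(post.Gamma, (0.25 / 2.0) * np.eye(4))

    def test_single_observation_closed_form(self):
        # (X^T X + I)^{-1} = diag(1/2, 1) for X = [[1, 0]], b = sigma = 1
        post = fit_posterior(DataSet([[1.0, 0.0]], [1.0]), sigma=1.0, b=1.0)
        assert np.allclose(post.Gamma, np.diag([0.5, 1.0]))
        assert np.allclose(post.mu, [0.5, 0.0])

    def test_recovers_coefficients_against_naive_ridge(self):
        rng = np.random.default_rng(42)
        beta = np.array([1.0, -2.0, 0.0])
        X = rng.uniform(-1, 1, size=(5, 3))
        y = X @ beta
        sigma, b = 0.1, 1e-4
        post = fit_posterior(DataSet(X, y), sigma, b)
        # independent oracle: explicit-inverse ridge solve
        oracle = np.linalg.inv(X.T @ X + sigma**2 * b * np.eye(3)) @ X.T @ y
        assert np.all(np.abs(post.mu - beta) < 0.05)
        assert np.all(np.abs(oracle - beta) < 0.05)
        assert np.allclose(post.mu, oracle, atol=5e-3)

    def test_gamma_is_symmetric_positive_definite(self, rng):
        for _ in range(10):
            post = random_posterior(rng)
            G = post.Gamma
            assert np.linalg.norm(G - G.T) <= 1e-10 * np.linalg.norm(G)
            assert np.linalg.eigvalsh(G)[0] > 0

    @pytest.mark.parametrize("sigma,b", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_invalid_parameters_rejected(self, sigma, b):
        with pytest.raises(ValueError):
            fit_posterior(DataSet.empty(2), sigma, b)

    def test_non_finite_data_rejected(self):
        with pytest.raises(ValueError):
            DataSet([[np.nan, 0.0]], [1.0])
        with pytest.raises(ValueError):
            DataSet([[1.0, 0.0]], [np.inf])


class TestUpdatePosterior:
    def test_empty_update_is_identity(self, rng):
        post = random_posterior(rng, p=6)
        updated = update_posterior(post, np.empty((0, 6)), np.empty(0))
        assert np.array_equal(updated.Gamma, post.Gamma)
        assert updated.n_obs == post.n_obs

    def test_matches_fit_from_prior(self):
        prior = fit_posterior(DataSet.empty(2), 1.0, 1.0)
        updated = update_posterior(prior, [[1.0, 0.0]], [1.0])
        direct = fit_posterior(DataSet([[1.0, 0.0]], [1.0]), 1.0, 1.0)
        assert np.allclose(updated.Gamma, direct.Gamma, atol=1e-12)
        assert np.allclose(updated.mu, direct.mu, atol=1e-12)
        assert updated.n_obs == 1

    def test_sequential_batches_equal_one_shot(self, rng):
        X = rng.standard_normal((20, 10))
        y = rng.standard_normal(20)
        one_shot = fit_posterior(DataSet(X, y), 0.7, 0.3)
        seq = fit_posterior(DataSet(X[:8], y[:8]), 0.7, 0.3)
        seq = update_posterior(seq, X[8:], y[8:])
        assert np.linalg.norm(seq.Gamma - one_shot.Gamma) < 1e-8
        assert np.linalg.norm(seq.mu - one_shot.mu) < 1e-8

    def test_any_partition_equals_one_shot(self, rng):
        X = rng.standard_normal((12, 5))
        y = rng.standard_normal(12)
        one_shot = fit_posterior(DataSet(X, y), 1.2, 0.05)
        for cuts in ([3, 7], [1, 2, 11], [6]):
            post = fit_posterior(DataSet.empty(5), 1.2, 0.05)
            prev = 0
            for cut in cuts + [12]:
                post = update_posterior(post, X[prev:cut], y[prev:cut])
                prev = cut
            rel = np.linalg.norm(post.Gamma - one_shot.Gamma) / np.linalg.norm(one_shot.Gamma)
            assert rel < 1e-8

    def test_update_without_cached_stats(self, rng):
        # a posterior constructed from moments alone still updates exactly
        base = random_posterior(rng, p=4, n=6, sigma=1.3, b=0.2)
        bare = EnsemblePosterior(
            mu=base.mu.copy(), Gamma=base.Gamma.copy(), n_obs=base.n_obs,
            sigma=base.sigma, b=base.b,
        )
        Xn, yn = rng.standard_normal((3, 4)), rng.standard_normal(3)
        a = update_posterior(base, Xn, yn)
        c = update_posterior(bare, Xn, yn)
        assert np.allclose(a.Gamma, c.Gamma, atol=1e-9)
        assert np.allclose(a.mu, c.mu, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        post = random_posterior(rng, p=4)
        with pytest.raises(ValueError):
            update_posterior(post, np.ones((2, 5)), np.ones(2))
        with pytest.raises(ValueError):
            update_posterior(post, np.ones((2, 4)), np.ones(3))

    def test_loewner_monotone_in_data(self, rng):
        # adding observations never increases uncertainty in any direction
        post = fit_posterior(DataSet.empty(8), 0.9, 0.5)
        for _ in range(5):
            Xn = rng.standard_normal((3, 8))
            yn = rng.standard_normal(3)
            after = update_posterior(post, Xn, yn)
            probes = rng.standard_normal((100, 8))
            before_q = np.einsum("ij,jk,ik->i", probes, post.Gamma, probes)
            after_q = np.einsum("ij,jk,ik->i", probes, after.Gamma, probes)
            assert np.all(after_q <= before_q + 1e-10)
            post = after

    def test_parameter_recovery_at_high_information(self):
        # p=20, d=5, 20 experiments of N(0,1) rows at low noise: sup-norm
        # error below 0.01 in nearly all seeds
        p, d, sigma, b = 20, 5, 0.01, 1e-3
        master = np.random.default_rng(2024)
        beta = master.uniform(-2, 2, size=p)
        hits = 0
        for _ in range(50):
            X = master.standard_normal((20 * d, p))
            y = X @ beta + sigma * master.standard_normal(20 * d)
            post = fit_posterior(DataSet(X, y), sigma, b)
            hits += np.max(np.abs(post.mu - beta)) < 0.01
        assert hits >= 48


class TestBHStepup:
    def test_degenerate_inputs(self):
        assert bh_stepup([], 0.05).shape == (0,)
        assert not bh_stepup(np.ones(5), 0.05).any()
        assert bh_stepup(np.zeros(5), 0.05).all()

    def test_stepup_rescues_borderline_pvalue(self):
        # p_(2) = 0.011 <= 2 * 0.05 / 4 qualifies both smallest p-values
        sig = bh_stepup([0.01, 0.011, 0.9, 0.9], 0.05)
        assert sig.tolist() == [True, True, False, False]

    def test_matches_exhaustive_stepup_oracle(self, rng):
        # the BH set is the largest subset S with max(S) <= |S| alpha / m,
        # realized on the smallest p-values; enumerate all subsets for m=8
        m, alpha = 8, 0.07
        for _ in range(20):
            pvals = np.round(rng.uniform(0, 0.4, size=m), 3)
            best_k = 0
            for r in range(1, m + 1):
                for subset in itertools.combinations(range(m), r):
                    if max(pvals[list(subset)]) <= r * alpha / m:
                        best_k = max(best_k, r)
            expected = np.zeros(m, dtype=bool)
            if best_k:
                expected[np.argsort(pvals, kind="stable")[:best_k]] = True
            assert bh_stepup(pvals, alpha).tolist() == expected.tolist()

    def test_agrees_with_statsmodels(self, rng):
        for _ in range(20):
            pvals = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            alpha = float(rng.uniform(0.01, 0.2))
            ref = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
            assert bh_stepup(pvals, alpha).tolist() == ref.tolist()

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        pvals=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20),
        a1=st.floats(0.005, 0.5),
        a2=st.floats(0.005, 0.5),
    )
    def test_monotone_in_alpha(self, pvals, a1, a2):
        lo, hi = sorted([a1, a2])
        rej_lo = bh_stepup(pvals, lo)
        rej_hi = bh_stepup(pvals, hi)
        assert np.all(rej_hi | ~rej_lo)  # rejections at lo are kept at hi

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_stepup([0.5, 1.2], 0.05)
        with pytest.raises(ValueError):
            bh_stepup([0.5], 1.5)


class TestSignificance:
    def _posterior(self, mu, Gamma, sigma=1.0, b=1.0):
        mu = np.asarray(mu, dtype=float)
        return EnsemblePosterior(
            mu=mu, Gamma=np.asarray(Gamma, dtype=float), n_obs=1, sigma=sigma, b=b
        )

    def test_null_means_nothing_significant(self):
        post = self._posterior(np.zeros(4), np.eye(4))
        rep = significance_test(post, 0.05)
        assert np.allclose(rep.z, 0.0)
        assert np.allclose(rep.pvals, 1.0)
        assert not rep.significant.any()

    def test_two_sided_normal_pvalues_and_bh(self):
        # z = 3.2905 gives two-sided p = 0.001; BH thresholds (0.005, 0.01)
        post = self._posterior([3.2905, 0.0], np.eye(2))
        rep = significance_test(post, 0.01)
        assert np.allclose(rep.z, [3.2905, 0.0])
        assert round(rep.pvals[0], 3) == 0.001
        assert round(rep.pvals[1], 3) == 1.0
        assert rep.significant.tolist() == [True, False]

    def test_z_uses_posterior_standard_deviation(self):
        post = self._posterior([2.0, 2.0], np.diag([4.0, 0.25]))
        rep = significance_test(post, 0.05)
        assert np.allclose(rep.z, [1.0, 4.0])
        # p-values monotone decreasing in |z|
        assert rep.pvals[1] < rep.pvals[0]

    def test_bh_decisions_form_stepdown_set(self, rng):
        post = random_posterior(rng, p=20, n=40)
        rep = significance_test(post, 0.1)
        order = np.argsort(rep.pvals)
        sig_sorted = rep.significant[order]
        # once a coefficient is non-significant, all larger p-values are too
        if sig_sorted.any():
            last_true = np.nonzero(sig_sorted)[0][-1]
            assert sig_sorted[: last_true + 1].all()

    def test_degenerate_variance_raises(self):
        post = self._posterior([1.0, 1.0], np.diag([1.0, 0.0]))
        with pytest.raises(NumericalDegeneracyError):
            significance_test(post, 0.05)


class TestTruthConfig:
    def test_validation_errors_name_the_problem(self):
        with pytest.raises(ValueError, match="beta_true"):
            TruthConfig(p=3, beta_true=np.zeros(2), sigma=0.1, b=1.0)
        with pytest.raises(ValueError, match="sigma"):
            TruthConfig(p=2, beta_true=np.zeros(2), sigma=0.0, b=1.0)
        with pytest.raises(ValueError, match="alpha"):
            TruthConfig(p=2, beta_true=np.zeros(2), sigma=0.1, b=1.0, d=1, alpha=1.5)
        with pytest.raises(ValueError, match="d"):
            TruthConfig(p=2, beta_true=np.zeros(2), sigma=0.1, b=1.0, d=5)

    def test_n_nonzero(self):
        cfg = TruthConfig(p=4, beta_true=[1.0, 0.0, -2.0, 0.0], sigma=0.1, b=1.0, d=2)
        assert cfg.n_nonzero == 2
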