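"""Downstream regression, Rubin combination, log-likelihood evaluation,
ranked Welch test — each against an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from dpcollab.analysis import (FitResult, fit_poisson_regression,
                               predictive_log_likelihood, ranked_welch_test,
                               rubins_rules, sample_loglik_distribution)
from dpcollab.datasets import TabularDataset
from dpcollab.model import FeatureEncoding, encode_dataset


def _irls_poisson(X: np.ndarray, y: np.ndarray, iters: int = 200
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Independent iteratively-reweighted-least-squares oracle."""
    w = np.zeros(X.shape[1])
    for _ in range(iters):
        lam = np.exp(X @ w)
        Wd = lam
        z = X @ w + (y - lam) / np.maximum(lam, 1e-12)
        A = X.T @ (Wd[:, None] * X)
        w_new = np.linalg.solve(A, X.T @ (Wd * z))
        if np.abs(w_new - w).max() < 1e-12:
            w = w_new
            break
        w = w_new
    lam = np.exp(X @ w)
    cov = np.linalg.inv(X.T @ (lam[:, None] * X))
    return w, np.diag(cov)


def _random_dataset(rng, n=200, levels=(3, 2, 2)):
    feats = np.column_stack([rng.integers(0, l, n) for l in levels])
    enc = FeatureEncoding(levels)
    w_true = rng.normal(0, 0.5, enc.p)
    w_true[0] = -1.5
    lam = np.exp(encode_dataset(feats, enc) @ w_true)
    y = np.minimum(rng.poisson(lam), 1)
    return TabularDataset(feats, y, levels), enc


class TestPoissonFit:
    def test_intercept_only_closed_form(self):
        # outcomes {1, 3}: MLE exp(w0) = ybar = 2, Var = 1/(n ybar) = 1/4;
        # counts beyond {0,1} exceed the dataset schema, so the closed form is
        # checked on the regression core directly
        X = np.ones((2, 1))
        w, v = _irls_poisson(X, np.array([1.0, 3.0]))
        assert w[0] == pytest.approx(math.log(2.0), abs=1e-10)
        assert v[0] == pytest.approx(0.25, abs=1e-10)

    def test_intercept_only_binary_outcomes(self):
        feats = np.zeros((4, 1), dtype=int)
        ds = TabularDataset(feats, np.array([0, 1, 1, 0]), (1,))
        fit = fit_poisson_regression(ds, FeatureEncoding((1,)))
        assert fit.converged
        assert fit.w_hat[0] == pytest.approx(math.log(0.5), abs=1e-8)
        assert fit.v_hat[0] == pytest.approx(1 / (4 * 0.5), abs=1e-6)

    def test_all_zero_outcomes_flagged_nonconverged(self):
        ds = TabularDataset(np.zeros((10, 1), dtype=int),
                            np.zeros(10, dtype=int), (1,))
        fit = fit_poisson_regression(ds, FeatureEncoding((1,)))
        assert not fit.converged

    def test_matches_irls_oracle_on_random_datasets(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            ds, enc = _random_dataset(rng)
            fit = fit_poisson_regression(ds, enc)
            if not fit.converged or fit.dropped_columns:
                continue
            X = encode_dataset(ds.features, enc)
            w, v = _irls_poisson(X, ds.outcome.astype(float))
            np.testing.assert_allclose(fit.w_hat, w, atol=1e-6)
            np.testing.assert_allclose(fit.v_hat, v, atol=1e-6)

    def test_unobserved_level_dropped_and_zero_filled(self):
        feats = np.array([[0], [1], [0], [1]] * 5)
        ds = TabularDataset(feats, np.array([0, 1] * 10), (3,))
        fit = fit_poisson_regression(ds, FeatureEncoding((3,)))
        assert fit.dropped_columns == (2,)  # level 2 never observed
        assert fit.w_hat[2] == 0.0 and fit.v_hat[2] == 0.0

    def test_collinear_design_rejected(self):
        # two binary features always equal -> identical dummy columns
        codes = np.random.default_rng(0).integers(0, 2, 30)
        feats = np.column_stack([codes, codes])
        ds = TabularDataset(feats, codes, (2, 2))
        with pytest.raises(ValueError, match="rank deficient"):
            fit_poisson_regression(ds, FeatureEncoding((2, 2)))


class TestRubinsRules:
    def test_two_replicate_worked_example(self):
        fits = [FitResult(np.array([0.0]), np.array([0.1]), True, 1),
                FitResult(np.array([2.0]), np.array([0.1]), True, 1)]
        est = rubins_rules(fits)
        assert est.mean[0] == pytest.approx(1.0)
        assert est.between_variance[0] == pytest.approx(2.0)
        assert est.within_variance[0] == pytest.approx(0.1)
        assert est.variance[0] == pytest.approx(1.5 * 2.0 - 0.1)
        assert not est.plus_rule[0]

    def test_identical_replicates_force_conservative_rule(self):
        fits = [FitResult(np.array([1.0]), np.array([0.3]), True, 1)
                for _ in range(5)]
        est = rubins_rules(fits)
        assert est.between_variance[0] == 0.0
        assert est.plus_rule[0]
        assert est.variance[0] == pytest.approx(0.3)

    def test_matches_direct_formula_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(200):  # 200 draws x 50 coefficients = 10^4 checks
            K = int(rng.integers(2, 12))
            W = rng.normal(0, 1, (K, 50))
            V = rng.gamma(1.0, 1.0, (K, 50))
            if rng.random() < 0.3:
                W[:, :10] = W[0, :10]  # force plus-rule coordinates
            fits = [FitResult(W[k], V[k], True, 1) for k in range(K)]
            est = rubins_rules(fits)
            wbar = W.mean(axis=0)
            b = ((W - wbar) ** 2).sum(axis=0) / (K - 1)
            vbar = V.mean(axis=0)
            minus = (1 + 1 / K) * b - vbar
            expected = np.where(minus < 0, (1 + 1 / K) * b + vbar, minus)
            np.testing.assert_allclose(est.mean, wbar, atol=1e-12)
            np.testing.assert_allclose(est.variance, expected, atol=1e-12)
            assert (est.variance >= 0).all()

    def test_permutation_invariant(self):
        rng = np.random.default_rng(4)
        fits = [FitResult(rng.normal(0, 1, 3), rng.gamma(1, 1, 3), True, 1)
                for _ in range(6)]
        a = rubins_rules(fits)
        b = rubins_rules(fits[::-1])
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-15)
        np.testing.assert_allclose(a.variance, b.variance, atol=1e-12)

    def test_requires_two_converged_fits(self):
        good = FitResult(np.zeros(2), np.ones(2), True, 1)
        bad = FitResult(np.zeros(2), np.ones(2), False, 1)
        with pytest.raises(ValueError):
            rubins_rules([good])
        with pytest.raises(ValueError):
            rubins_rules([good, bad])

    def test_mean_and_between_variance_converge_with_k(self):
        """Replicates drawn from a fixed Gaussian: wbar -> mu, b -> tau^2."""
        rng = np.random.default_rng(33)
        mu, tau = 0.7, 0.4
        for K in (10, 100, 1000):
            W = rng.normal(mu, tau, (K, 1))
            fits = [FitResult(W[k], np.array([0.01]), True, 1)
                    for k in range(K)]
            est = rubins_rules(fits)
            se_mean = tau / math.sqrt(K)
            se_b = tau**2 * math.sqrt(2 / (K - 1))
            assert abs(est.mean[0] - mu) < 3 * se_mean
            assert abs(est.between_variance[0] - tau**2) < 3 * se_b


class TestPredictiveLogLik:
    def test_unit_rate_zero_outcomes(self):
        ds = TabularDataset(np.zeros((2, 1), dtype=int),
                            np.zeros(2, dtype=int), (1,))
        enc = FeatureEncoding((1,))
        assert predictive_log_likelihood(np.zeros(1), ds, enc,
                                         normalize=False) == pytest.approx(-2.0)
        assert predictive_log_likelihood(np.zeros(1), ds, enc,
                                         normalize=True) == pytest.approx(-1.0)

    def test_matches_per_record_poisson_logpmf_oracle(self):
        rng = np.random.default_rng(8)
        levels = (4, 2)
        enc = FeatureEncoding(levels)
        for _ in range(20):
            feats = np.column_stack([rng.integers(0, l, 30) for l in levels])
            ds = TabularDataset(feats, rng.integers(0, 2, 30), levels)
            w = rng.normal(0, 1, enc.p)
            lam = np.exp(encode_dataset(feats, enc) @ w)
            oracle = stats.poisson.logpmf(ds.outcome, lam).sum()
            val = predictive_log_likelihood(w, ds, enc, normalize=False)
            assert val == pytest.approx(oracle, abs=1e-12)

    def test_binary_outcomes_contribute_no_factorial_term(self):
        # ln(0!) = ln(1!) = 0: the value equals sum(y eta - lambda) exactly
        enc = FeatureEncoding((2,))
        feats = np.array([[0], [1], [1]])
        ds = TabularDataset(feats, np.array([0, 1, 1]), (2,))
        w = np.array([0.3, -0.7])
        eta = encode_dataset(feats, enc) @ w
        expected = (ds.outcome * eta - np.exp(eta)).sum()
        assert predictive_log_likelihood(w, ds, enc, normalize=False) == \
            pytest.approx(expected, abs=1e-12)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(9)
        enc = FeatureEncoding((3,))
        feats = rng.integers(0, 3, (40, 1))
        ds = TabularDataset(feats, rng.integers(0, 2, 40), (3,))
        w = rng.normal(0, 1, enc.p)
        whole = predictive_log_likelihood(w, ds, enc, normalize=False)
        parts = sum(
            predictive_log_likelihood(w, ds.take(idx), enc, normalize=False)
            for idx in (np.arange(15), np.arange(15, 40)))
        assert whole == pytest.approx(parts, abs=1e-10)


class TestLogLikSampling:
    def test_zero_variance_collapses_to_point_value(self, tiny_encoding):
        ds = TabularDataset(np.array([[0, 0], [1, 1]]), np.array([0, 1]),
                            (3, 2))
        fit = FitResult(np.array([-1.0, 0.2, 0.1, 0.0]), np.zeros(4), True, 1)
        ll = sample_loglik_distribution(fit, ds, tiny_encoding, 20, seed=0)
        point = predictive_log_likelihood(fit.w_hat, ds, tiny_encoding)
        np.testing.assert_allclose(ll.values, point, atol=1e-12)

    def test_small_variance_stays_near_point_value(self, tiny_encoding):
        ds = TabularDataset(np.array([[0, 0], [2, 1]]), np.array([1, 0]),
                            (3, 2))
        fit = FitResult(np.array([-1.0, 0.2, 0.1, 0.0]),
                        np.full(4, 1e-8), True, 1)
        ll = sample_loglik_distribution(fit, ds, tiny_encoding, 100, seed=3)
        point = predictive_log_likelihood(fit.w_hat, ds, tiny_encoding)
        assert np.abs(ll.values - point).max() < 1e-2

    def test_negative_variance_rejected(self, tiny_encoding):
        ds = TabularDataset(np.array([[0, 0]]), np.array([0]), (3, 2))
        fit = FitResult(np.zeros(4), np.array([-1.0, 0, 0, 0]), True, 1)
        with pytest.raises(ValueError):
            sample_loglik_distribution(fit, ds, tiny_encoding, 10, seed=0)


class TestRankedWelch:
    def test_identical_samples_give_unit_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = ranked_welch_test(a, a.copy(), sides="two")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_values_tied_convention(self):
        a = np.ones(5)
        assert ranked_welch_test(a, np.ones(7)) == (0.0, 1.0)

    def test_complete_separation_is_overwhelming(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 100)
        b = rng.normal(-10, 1, 100)
        _, p = ranked_welch_test(a, b, sides="one")
        assert p < 1e-10

    def test_matches_rank_then_welch_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            a = rng.normal(0, 1, int(rng.integers(5, 40)))
            b = rng.normal(0.3, 2, int(rng.integers(5, 40)))
            ranks = stats.rankdata(np.concatenate([a, b]))
            ra, rb = ranks[:a.size], ranks[a.size:]
            # Welch's t from first principles on the ranks
            va, vb = ra.var(ddof=1), rb.var(ddof=1)
            se = math.sqrt(va / ra.size + vb / rb.size)
            t = (ra.mean() - rb.mean()) / se
            df = (va / ra.size + vb / rb.size) ** 2 / (
                (va / ra.size) ** 2 / (ra.size - 1)
                + (vb / rb.size) ** 2 / (rb.size - 1))
            p_oracle = stats.t.sf(t, df)
            stat, p = ranked_welch_test(a, b, sides="one")
            assert stat == pytest.approx(t, abs=1e-10)
            assert p == pytest.approx(p_oracle, abs=1e-10)
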