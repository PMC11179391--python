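"""Downstream Poisson regression, Rubin's-rules combination, and predictive
log-likelihood evaluation.

The analysis model is the Poisson regression with log link shared with the
generative model's outcome part. Fits on K combined training sets are merged
with the fully-synthetic-data variant of Rubin's rules — mean
``wbar = mean_k(w_k)``, variance ``(1 + 1/K) b - vbar`` with between-replicate
variance ``b`` and mean within variance ``vbar``, falling back per coefficient
to the conservative ``(1 + 1/K) b + vbar`` where the first form is negative.
Utility is the predictive log-likelihood on a global test set; its sampling
distribution comes from Monte-Carlo draws of ``w`` from the diagonal Gaussian
``N(wbar, diag(vhat))``. Significance between log-likelihood sample sets uses
Welch's t-test on pooled mid-ranks (robust to unequal variance and
non-normality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .datasets import TabularDataset
from .model import FeatureEncoding, encode_dataset

__all__ = [
    "FitResult",
    "RubinEstimate",
    "LogLikSamples",
    "fit_poisson_regression",
    "rubins_rules",
    "predictive_log_likelihood",
    "sample_loglik_distribution",
    "ranked_welch_test",
]

_MAX_ITER = 100
_SCORE_TOL = 1e-8


@dataclass(frozen=True)
class FitResult:
    """One Poisson-regression fit: MLE, squared standard errors, diagnostics.

    ``w_hat``/``v_hat`` have the full encoded length p; columns whose category
    level was unobserved in the training data (recorded in ``dropped_columns``)
    are zero-filled.
    """

    w_hat: np.ndarray
    v_hat: np.ndarray
    converged: bool
    iterations: int
    dropped_columns: tuple[int, ...] = ()


@dataclass(frozen=True)
class RubinEstimate:
    """Combined posterior summary across K replicate fits."""

    mean: np.ndarray
    variance: np.ndarray
    between_variance: np.ndarray
    within_variance: np.ndarray
    plus_rule: np.ndarray  # bool per coefficient: conservative fallback used
    k: int


@dataclass(frozen=True)
class LogLikSamples:
    values: np.ndarray
    normalized: bool
    seed: int


def fit_poisson_regression(train: TabularDataset, enc: FeatureEncoding
                           ) -> FitResult:
    """Poisson MLE with log link; variances from the inverse Fisher information.

    Dummy columns for levels never observed in ``train`` are dropped from the
    design (and zero-filled in the returned vectors); genuine collinearity among
    observed columns raises. An all-zero outcome (MLE at -infinity) or a
    non-converged Newton/IRLS run returns ``converged=False``.
    """
    if train.n == 0:
        raise ValueError("empty training set")
    X = encode_dataset(train.features, enc)
    y = train.outcome.astype(float)
    observed = X.any(axis=0)
    dropped = tuple(int(i) for i in np.flatnonzero(~observed))
    Xo = X[:, observed]
    if np.linalg.matrix_rank(Xo) < Xo.shape[1]:
        names = np.array(enc.column_names())[observed]
        raise ValueError(
            "design matrix is rank deficient among observed columns: "
            + ", ".join(names))
    p = enc.p
    if not y.any():
        return FitResult(np.zeros(p), np.zeros(p), False, 0, dropped)
    model = sm.GLM(y, Xo, family=sm.families.Poisson())
    try:
        with np.errstate(all="ignore"):
            res = model.fit(maxiter=_MAX_ITER, tol=_SCORE_TOL)
    except Exception:
        return FitResult(np.zeros(p), np.zeros(p), False, _MAX_ITER, dropped)
    w = np.zeros(p)
    v = np.zeros(p)
    w[observed] = res.params
    # variance from the Fisher information evaluated exactly at the MLE
    # (the IRLS covariance uses the penultimate iteration's weights)
    with np.errstate(all="ignore"):
        lam_hat = np.exp(np.clip(Xo @ res.params, -700, 700))
        try:
            cov = np.linalg.inv(Xo.T @ (lam_hat[:, None] * Xo))
            v[observed] = np.diag(cov)
        except np.linalg.LinAlgError:
            v[observed] = np.diag(res.cov_params())
    # separation-like divergence: a dummy level with no positive outcomes has
    # its MLE at -infinity (the design is binary, so X.y == 0 detects it)
    separated = bool(np.any((Xo.T @ y == 0) & (Xo.sum(axis=0) > 0)))
    ok = bool(getattr(res, "converged", True)) and not separated \
        and np.all(np.isfinite(w)) and np.all(np.isfinite(v)) \
        and np.abs(res.params).max() < 1e3
    its = int(getattr(res, "fit_history", {}).get("iteration", _MAX_ITER)) \
        if hasattr(res, "fit_history") else _MAX_ITER
    return FitResult(w, v, ok, its, dropped)


def rubins_rules(fits: list[FitResult]) -> RubinEstimate:
    """Combine K replicate fits; the conservative fallback applies per
    coefficient wherever ``(1 + 1/K) b - vbar`` is negative."""
    k = len(fits)
    if k < 2:
        raise ValueError("Rubin's rules need at least two replicate fits")
    if not all(f.converged for f in fits):
        raise ValueError("all replicate fits must have converged")
    W = np.stack([f.w_hat for f in fits])          # (K, p)
    V = np.stack([f.v_hat for f in fits])
    mean = W.mean(axis=0)
    b = W.var(axis=0, ddof=1)
    vbar = V.mean(axis=0)
    minus = (1.0 + 1.0 / k) * b - vbar
    plus_rule = minus < 0
    variance = np.where(plus_rule, (1.0 + 1.0 / k) * b + vbar, minus)
    return RubinEstimate(mean, variance, b, vbar, plus_rule, k)


def predictive_log_likelihood(w: np.ndarray, test: TabularDataset,
                              enc: FeatureEncoding, normalize: bool = True
                              ) -> float:
    """``sum over test of [y ln(lambda) - lambda - ln(y!)]`` at
    ``lambda = exp(w . x)``; divided by the test size when ``normalize``."""
    if test.n == 0:
        raise ValueError("empty test set")
    X = encode_dataset(test.features, enc)
    y = test.outcome.astype(float)
    # cap the linear predictor so a pathological parameter draw yields a very
    # poor but finite log-likelihood instead of overflowing the sum
    eta = np.clip(X @ np.asarray(w, dtype=float), -700, 300)
    total = float((y * eta - np.exp(eta) - gammaln(y + 1.0)).sum())
    return total / test.n if normalize else total


def sample_loglik_distribution(est: RubinEstimate | FitResult,
                               test: TabularDataset, enc: FeatureEncoding,
                               n_samples: int = 100, seed: int = 0,
                               normalize: bool = True) -> LogLikSamples:
    """Monte-Carlo predictive log-likelihoods under the diagonal Gaussian
    parameter distribution (Rubin combination, or a single fit's MLE and
    squared standard errors)."""
    if isinstance(est, FitResult):
        mean, var = est.w_hat, est.v_hat
    else:
        mean, var = est.mean, est.variance
    if np.any(var < 0):
        raise ValueError("negative variance in parameter distribution")
    if test.n == 0:
        raise ValueError("empty test set")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(var)
    draws = mean[None, :] + sd[None, :] * rng.standard_normal(
        (n_samples, mean.size))
    X = encode_dataset(test.features, enc)
    y = test.outcome.astype(float)
    eta = np.clip(draws @ X.T, -700, 300)               # (S, n)
    vals = (y[None, :] * eta - np.exp(eta)
            - gammaln(y + 1.0)[None, :]).sum(axis=1)
    if normalize:
        vals = vals / test.n
    return LogLikSamples(vals, normalize, seed)


def ranked_welch_test(a: np.ndarray, b: np.ndarray, sides: str = "one"
                      ) -> tuple[float, float]:
    """Welch's t-test on pooled mid-ranks of the two sample sets.

    ``sides='one'`` (alias 'greater') tests mean(a) > mean(b) on the rank
    scale; 'less' the reverse; 'two' is two-sided. All values tied gives
    (0.0, 1.0) by convention.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("both sample sets need at least two values")
    alt = {"one": "greater", "greater": "greater", "less": "less",
           "two": "two-sided", "two-sided": "two-sided"}.get(sides)
    if alt is None:
        raise ValueError(f"unknown sidedness {sides!r}")
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra, rb = ranks[: a.size], ranks[a.size:]
    if np.var(ra) == 0 and np.var(rb) == 0:
        return 0.0, 1.0
    res = stats.ttest_ind(ra, rb, equal_var=False, alternative=alt)
    return float(res.statistic), float(res.pvalue)
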