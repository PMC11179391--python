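"""Numerical (epsilon, delta) accounting for the Poisson-subsampled Gaussian
mechanism under the add-remove neighbourhood relation.

The accountant discretizes the privacy-loss distribution (PLD) of a single
DP-SGD step, composes ``T`` steps by FFT convolution, and reads off
``delta(epsilon)``; ``epsilon(delta)`` is obtained by bisection. Both adjacency
directions (record added / record removed) are evaluated and the worse one is
reported. An independent Renyi-DP composition bound (integer orders, the
standard sampled-Gaussian-mechanism bound) is provided as a cross-check; the
PLD result must never exceed it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

__all__ = [
    "PrivacyParams",
    "compute_epsilon",
    "compute_delta",
    "rdp_epsilon",
    "calibrate_noise",
    "analytic_gaussian_epsilon",
]

_N_LGRID = 2**18
_N_XGRID = 2**20


@dataclass(frozen=True)
class PrivacyParams:
    """DP-SGD / accountant contract for one generative-model fit.

    ``noise_multiplier`` may be ``None`` before calibration; ``calibrated``
    fills it from (epsilon, delta, q, T).
    """

    epsilon: float = 1.0
    delta: float = 1e-6
    clip_norm: float = 4.0
    noise_multiplier: float | None = None
    subsampling_ratio: float = 0.5
    iterations: int = 2000

    def __post_init__(self) -> None:
        if self.epsilon < 0 or not 0 <= self.delta <= 1:
            raise ValueError("invalid (epsilon, delta)")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if not 0 < self.subsampling_ratio <= 1:
            raise ValueError("subsampling_ratio must lie in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if self.noise_multiplier is not None and self.noise_multiplier < 0:
            raise ValueError("noise_multiplier must be nonnegative")

    def calibrated(self) -> "PrivacyParams":
        if self.noise_multiplier is not None:
            return self
        sigma = calibrate_noise(self.epsilon, self.delta,
                                self.subsampling_ratio, self.iterations)
        return replace(self, noise_multiplier=sigma)

    def realized_epsilon(self) -> float:
        if self.noise_multiplier is None:
            raise ValueError("noise multiplier not set; calibrate first")
        return compute_epsilon(self.noise_multiplier, self.subsampling_ratio,
                               self.iterations, self.delta)


def _single_step_pld(sigma: float, q: float, direction: str,
                     l_max: float, n_grid: int) -> tuple[np.ndarray, np.ndarray]:
    """PMF of the per-step privacy loss on a uniform grid over [-l_max, l_max).

    Remove direction: loss log(P/Q) under P with P = (1-q)N(0,s^2)+qN(1,s^2),
    Q = N(0,s^2). Add direction: loss log(Q/P) under Q.
    """
    half_width = 14.0 * sigma + 1.0
    x = np.linspace(-half_width, 1.0 + half_width, _N_XGRID)
    dx = x[1] - x[0]
    log_ratio_gauss = (2.0 * x - 1.0) / (2.0 * sigma**2)  # log N(1,s)/N(0,s)
    # log((1-q) + q * exp(t)), stable for large |t|
    t = log_ratio_gauss
    big = t > 30
    loss_remove = np.where(
        big,
        np.log(q) + t,
        np.log((1.0 - q) + q * np.exp(np.minimum(t, 30.0))),
    )
    dens_q = norm.pdf(x, 0.0, sigma)
    dens_p = (1.0 - q) * dens_q + q * norm.pdf(x, 1.0, sigma)
    if direction == "remove":
        loss, dens = loss_remove, dens_p
    else:
        loss, dens = -loss_remove, dens_q
    grid = np.linspace(-l_max, l_max, n_grid, endpoint=False)
    dl = grid[1] - grid[0]
    idx = np.clip(np.round((loss + l_max) / dl).astype(np.int64), 0, n_grid - 1)
    pmf = np.bincount(idx, weights=dens * dx, minlength=n_grid)
    return grid, pmf


def _loss_moments(sigma: float, q: float, direction: str) -> tuple[float, float]:
    grid, pmf = _single_step_pld(sigma, q, direction, l_max=60.0 * (1 + 1 / sigma),
                                 n_grid=2**14)
    mass = pmf.sum()
    m1 = float((grid * pmf).sum() / mass)
    m2 = float((grid**2 * pmf).sum() / mass)
    return m1, max(m2 - m1**2, 0.0)


def _composed_plds(sigma: float, q: float, T: int, extra_range: float = 0.0
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Composed T-step PLD (grid, pmf) for both adjacency directions."""
    out = []
    for direction in ("remove", "add"):
        m1, var = _loss_moments(sigma, q, direction)
        l_max = max(30.0,
                    abs(T * m1) + 14.0 * np.sqrt(max(T * var, 1e-12)) + 10.0,
                    extra_range + 5.0)
        grid, pmf = _single_step_pld(sigma, q, direction, l_max, _N_LGRID)
        if T > 1:
            spectrum = np.fft.rfft(np.fft.ifftshift(pmf))
            composed = np.fft.fftshift(np.fft.irfft(spectrum**T, n=_N_LGRID))
            composed = np.clip(composed, 0.0, None)
        else:
            composed = pmf
        out.append((grid, composed))
    return out


def _delta_from_pld(grid: np.ndarray, pmf: np.ndarray, epsilon: float) -> float:
    tail = grid > epsilon
    return float((pmf[tail] * -np.expm1(epsilon - grid[tail])).sum())


def compute_delta(sigma: float, q: float, T: int, epsilon: float) -> float:
    """delta(epsilon) after T-fold composition (worse of the two directions)."""
    if sigma <= 0:
        return 1.0
    plds = _composed_plds(sigma, q, T, extra_range=abs(epsilon))
    return min(max(_delta_from_pld(g, p, epsilon) for g, p in plds), 1.0)


def compute_epsilon(sigma: float, q: float, T: int, delta: float) -> float:
    """Smallest epsilon with delta(epsilon) <= delta, by bisection over a
    composed PLD built once.

    Returns ``inf`` when sigma == 0 (no noise, no guarantee).
    """
    if sigma <= 0:
        return np.inf
    extra = 0.0
    for _ in range(6):
        plds = _composed_plds(sigma, q, T, extra_range=extra)
        cap = min(g[-1] for g, _ in plds) - 2.0

        def delta_of(eps: float) -> float:
            return max(_delta_from_pld(g, p, eps) for g, p in plds)

        if delta_of(cap) > delta:
            extra = 2.0 * max(cap + 2.0, 10.0)  # widen the grid and retry
            continue
        lo, hi = 0.0, cap
        if delta_of(0.0) <= delta:
            return 0.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if delta_of(mid) > delta:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-5 * max(hi, 1e-3):
                break
        return hi
    return np.inf


def rdp_epsilon(sigma: float, q: float, T: int, delta: float,
                orders: np.ndarray | None = None) -> float:
    """Independent upper bound via Renyi-DP composition (integer orders).

    Uses the standard sampled-Gaussian-mechanism RDP bound
    ``eps_alpha = log( sum_k C(alpha,k) (1-q)^(alpha-k) q^k e^(k(k-1)/(2 s^2)) )
    / (alpha - 1)`` composed over T steps and converted with
    ``eps = T eps_alpha + log(1/delta)/(alpha-1)``, minimized over orders.
    """
    if sigma <= 0:
        return np.inf
    if orders is None:
        orders = np.concatenate([np.arange(2, 65), [80, 128, 256, 512]])
    best = np.inf
    for alpha in orders:
        alpha = int(alpha)
        if q >= 1.0:
            eps_alpha = alpha / (2.0 * sigma**2)
        else:
            k = np.arange(alpha + 1)
            log_terms = (
                gammaln(alpha + 1) - gammaln(k + 1) - gammaln(alpha - k + 1)
                + (alpha - k) * np.log1p(-q)
                + k * np.log(q)
                + k * (k - 1) / (2.0 * sigma**2)
            )
            m = log_terms.max()
            eps_alpha = (m + np.log(np.exp(log_terms - m).sum())) / (alpha - 1)
        best = min(best, T * eps_alpha + np.log(1.0 / delta) / (alpha - 1))
    return float(best)


def analytic_gaussian_epsilon(sigma: float, delta: float) -> float:
    """Exact epsilon of the (unsubsampled) Gaussian mechanism, sensitivity 1.

    Inverts delta(eps) = Phi(1/(2 sigma) - eps sigma)
    - e^eps Phi(-1/(2 sigma) - eps sigma) by bisection.
    """
    def delta_of(eps: float) -> float:
        return float(norm.cdf(0.5 / sigma - eps * sigma)
                     - np.exp(eps) * norm.cdf(-0.5 / sigma - eps * sigma))

    lo, hi = 0.0, 1.0
    while delta_of(hi) > delta:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if delta_of(mid) > delta:
            lo = mid
        else:
            hi = mid
    return hi


_CALIBRATION_CACHE: dict[tuple[float, float, float, int], float] = {}


def calibrate_noise(epsilon_target: float, delta: float, q: float, T: int,
                    sigma_bounds: tuple[float, float] = (0.02, 1000.0)) -> float:
    """Smallest noise multiplier meeting the (epsilon, delta) target.

    Bisects sigma until ``compute_epsilon(sigma) in (0.999 * target, target]``.
    """
    if epsilon_target <= 0:
        raise ValueError("epsilon target must be positive")
    key = (round(epsilon_target, 12), delta, round(q, 12), int(T))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    lo, hi = sigma_bounds
    if compute_epsilon(hi, q, T, delta) > epsilon_target:
        raise ValueError("epsilon target unreachable within sigma bounds")
    if compute_epsilon(lo, q, T, delta) <= epsilon_target:
        raise ValueError("sigma lower bound already meets the target; widen bounds")
    eps_hi = 0.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        eps_mid = compute_epsilon(mid, q, T, delta)
        if eps_mid <= epsilon_target:
            hi, eps_hi = mid, eps_mid
        else:
            lo = mid
        if eps_hi > 0.999 * epsilon_target:
            break
    _CALIBRATION_CACHE[key] = hi
    return hi
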