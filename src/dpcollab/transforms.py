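"""Unconstrained parameterization of the generative model.

Variational inference runs in an unconstrained space ``z`` mapped bijectively
onto valid ``GenerativeParams``: a stick-breaking transform for the mixture
simplex and every component categorical, identity for the regression weights.
The layout groups all components' coordinates of one feature contiguously so
per-feature gradient work vectorizes over components and batch records.

All forward maps, log-Jacobians and their gradients are analytic; tests verify
them against finite differences and round trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, logit

from .model import FeatureEncoding, GenerativeParams

__all__ = [
    "stick_breaking_forward",
    "stick_breaking_inverse",
    "stick_breaking_logdet",
    "ParamLayout",
    "MeanFieldPosterior",
]

W_PRIOR_SCALE = 2.0  # zero-mean Gaussian prior scale on regression weights


def _offsets(L: int) -> np.ndarray:
    # at u = 0 the transform returns the uniform simplex
    return -np.log(np.arange(L - 1, 0, -1, dtype=float))


def stick_breaking_forward(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map unconstrained ``(..., L-1)`` to the simplex ``(..., L)``.

    Returns ``(theta, v)`` where ``v`` are the stick fractions (reused by the
    Jacobian and gradient formulas).
    """
    u = np.asarray(u, dtype=float)
    L = u.shape[-1] + 1
    v = expit(u + _offsets(L))
    one_minus = np.concatenate(
        [np.ones(u.shape[:-1] + (1,)), np.cumprod(1.0 - v, axis=-1)], axis=-1
    )
    theta = np.concatenate([v * one_minus[..., :-1], one_minus[..., -1:]], axis=-1)
    return theta, v


def stick_breaking_inverse(theta: np.ndarray) -> np.ndarray:
    """Inverse map from a simplex point (with positive entries) to u."""
    theta = np.asarray(theta, dtype=float)
    L = theta.shape[-1]
    remaining = 1.0 - np.concatenate(
        [np.zeros(theta.shape[:-1] + (1,)), np.cumsum(theta[..., :-1], axis=-1)],
        axis=-1,
    )
    v = theta[..., :-1] / remaining[..., :-1]
    return logit(v) - _offsets(L)


def stick_breaking_logdet(theta: np.ndarray, v: np.ndarray) -> np.ndarray:
    """log |d theta / d u| summed over one simplex (batched over leading axes).

    Floors guard against exact-zero sticks at extreme unconstrained values.
    """
    return (np.log(np.maximum(theta[..., :-1], 1e-300))
            + np.log(np.maximum(1.0 - v, 1e-300))).sum(axis=-1)


def stick_breaking_logdet_grad(v: np.ndarray) -> np.ndarray:
    """d(log|det J|)/du_k = 1 - v_k (L - k) for 0-indexed k, simplex size L."""
    L = v.shape[-1] + 1
    return 1.0 - v * (L - np.arange(L - 1, dtype=float))


@dataclass(frozen=True)
class ParamLayout:
    """Index layout of the flat unconstrained vector.

    ``[ pi-block (R-1) | feature 0 block (R, L_0 - 1) | ... | w (p) ]``
    """

    n_components: int
    level_counts: tuple[int, ...]

    @property
    def encoding(self) -> FeatureEncoding:
        return FeatureEncoding(self.level_counts)

    @property
    def p(self) -> int:
        return self.encoding.p

    @property
    def pi_slice(self) -> slice:
        return slice(0, self.n_components - 1)

    def theta_slice(self, j: int) -> slice:
        start = self.n_components - 1
        for jj in range(j):
            start += self.n_components * (self.level_counts[jj] - 1)
        return slice(start, start + self.n_components * (self.level_counts[j] - 1))

    @property
    def w_slice(self) -> slice:
        start = self.n_components - 1 + self.n_components * sum(
            l - 1 for l in self.level_counts
        )
        return slice(start, start + self.p)

    @property
    def dim(self) -> int:
        return self.w_slice.stop

    # ---- constrained <-> unconstrained ----
    def constrain(self, z: np.ndarray) -> GenerativeParams:
        pi, _ = stick_breaking_forward(z[self.pi_slice])
        R = self.n_components
        theta_by_feature = []
        for j, lj in enumerate(self.level_counts):
            u = z[self.theta_slice(j)].reshape(R, lj - 1)
            theta_by_feature.append(stick_breaking_forward(u)[0])
        theta = tuple(
            tuple(theta_by_feature[j][r] for j in range(len(self.level_counts)))
            for r in range(R)
        )
        return GenerativeParams(pi, theta, z[self.w_slice].copy())

    def unconstrain(self, params: GenerativeParams) -> np.ndarray:
        if params.n_components != self.n_components or \
                params.level_counts != tuple(self.level_counts):
            raise ValueError("params do not match layout")
        z = np.empty(self.dim)
        z[self.pi_slice] = stick_breaking_inverse(params.mixture_weights)
        R = self.n_components
        for j, lj in enumerate(self.level_counts):
            theta_j = np.stack([params.component_categoricals[r][j] for r in range(R)])
            z[self.theta_slice(j)] = stick_breaking_inverse(theta_j).ravel()
        z[self.w_slice] = params.regression_weights
        return z

    # ---- prior in unconstrained space ----
    # uniform (Dirichlet(1)) on every simplex, pushed through the transform,
    # plus N(0, W_PRIOR_SCALE^2) on the regression weights
    def log_prior(self, z: np.ndarray) -> float:
        pi, v = stick_breaking_forward(z[self.pi_slice])
        R = self.n_components
        total = float(gammaln(R)) + float(stick_breaking_logdet(pi, v))
        for j, lj in enumerate(self.level_counts):
            u = z[self.theta_slice(j)].reshape(R, lj - 1)
            theta, v = stick_breaking_forward(u)
            total += R * float(gammaln(lj))
            total += float(stick_breaking_logdet(theta, v).sum())
        w = z[self.w_slice]
        total += float(np.sum(
            -0.5 * (w / W_PRIOR_SCALE) ** 2
            - np.log(W_PRIOR_SCALE) - 0.5 * np.log(2 * np.pi)
        ))
        return total

    def log_prior_grad(self, z: np.ndarray) -> np.ndarray:
        g = np.empty(self.dim)
        _, v = stick_breaking_forward(z[self.pi_slice])
        g[self.pi_slice] = stick_breaking_logdet_grad(v)
        R = self.n_components
        for j, lj in enumerate(self.level_counts):
            u = z[self.theta_slice(j)].reshape(R, lj - 1)
            _, v = stick_breaking_forward(u)
            g[self.theta_slice(j)] = stick_breaking_logdet_grad(v).ravel()
        g[self.w_slice] = -z[self.w_slice] / W_PRIOR_SCALE**2
        return g


@dataclass
class MeanFieldPosterior:
    """Diagonal-Gaussian variational posterior over the unconstrained space."""

    layout: ParamLayout
    loc: np.ndarray
    log_scale: np.ndarray

    def __post_init__(self) -> None:
        self.loc = np.asarray(self.loc, dtype=float).ravel()
        self.log_scale = np.asarray(self.log_scale, dtype=float).ravel()
        if self.loc.shape != (self.layout.dim,) or \
                self.log_scale.shape != (self.layout.dim,):
            raise ValueError("posterior shape does not match layout")

    @classmethod
    def initial(cls, layout: ParamLayout, scale: float = 0.1
                ) -> "MeanFieldPosterior":
        return cls(layout, np.zeros(layout.dim),
                   np.full(layout.dim, np.log(scale)))

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def sample_unconstrained(self, rng: np.random.Generator
                             ) -> tuple[np.ndarray, np.ndarray]:
        """Reparameterized draw: returns (z, eps) with z = loc + scale * eps."""
        eps = rng.standard_normal(self.layout.dim)
        return self.loc + self.scale * eps, eps

    def log_q(self, z: np.ndarray) -> float:
        s = self.scale
        return float(np.sum(
            -0.5 * ((z - self.loc) / s) ** 2 - self.log_scale
            - 0.5 * np.log(2 * np.pi)
        ))

    def draw_params(self, rng: np.random.Generator) -> GenerativeParams:
        z, _ = self.sample_unconstrained(rng)
        return self.layout.constrain(z)

    def mean_params(self) -> GenerativeParams:
        return self.layout.constrain(self.loc.copy())

    def to_dict(self) -> dict:
        return {
            "n_components": self.layout.n_components,
            "level_counts": list(self.layout.level_counts),
            "loc": self.loc.tolist(),
            "log_scale": self.log_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MeanFieldPosterior":
        layout = ParamLayout(payload["n_components"],
                             tuple(payload["level_counts"]))
        return cls(layout, np.array(payload["loc"]),
                   np.array(payload["log_scale"]))
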