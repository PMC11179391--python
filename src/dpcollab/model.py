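"""The two-part probabilistic model: categorical-mixture features and a
Poisson-regression outcome.

Features follow a mixture of product-categoricals: a latent component
``r ~ Categorical(pi)`` is drawn, then each feature ``j`` independently follows
``Categorical(theta[r][j])``. The outcome follows a Poisson regression with log
link, ``y ~ Poisson(lambda)``, ``lambda = exp(w . x_enc)``; because the data
outcome is a binary test result, sampled counts are clipped to ``min(y, 1)``.
The same regression doubles as the downstream analysis model, whose point
prediction is the Poisson-pmf argmax over ``y in {0, 1}`` — equivalently
``1`` iff ``lambda > 1`` (ties at ``lambda == 1`` resolve to 0).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .datasets import TabularDataset

__all__ = [
    "GenerativeParams",
    "FeatureEncoding",
    "encode_features",
    "encode_dataset",
    "log_prob_features",
    "log_prob_outcome",
    "predict",
    "sample_synthetic",
    "sample_binary_outcomes",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters (pi, theta, w) of the generative model.

    ``mixture_weights`` is an R-simplex; ``component_categoricals[r][j]`` is the
    categorical simplex of feature ``j`` inside component ``r``;
    ``regression_weights`` has the encoded design length ``p``.
    """

    mixture_weights: np.ndarray
    component_categoricals: tuple[tuple[np.ndarray, ...], ...]
    regression_weights: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.mixture_weights, dtype=float).ravel()
        theta = tuple(
            tuple(np.asarray(t, dtype=float).ravel() for t in comp)
            for comp in self.component_categoricals
        )
        w = np.asarray(self.regression_weights, dtype=float).ravel()
        object.__setattr__(self, "mixture_weights", pi)
        object.__setattr__(self, "component_categoricals", theta)
        object.__setattr__(self, "regression_weights", w)
        if (pi < 0).any() or abs(pi.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("mixture_weights is not a probability simplex")
        if len(theta) != pi.size:
            raise ValueError("one categorical block per mixture component required")
        d = len(theta[0]) if theta else 0
        for comp in theta:
            if len(comp) != d:
                raise ValueError("all components must model the same d features")
            for t in comp:
                if (t < 0).any() or abs(t.sum() - 1.0) > _SIMPLEX_TOL:
                    raise ValueError("component categorical is not a simplex")

    @property
    def n_components(self) -> int:
        return self.mixture_weights.size

    @property
    def d(self) -> int:
        return len(self.component_categoricals[0])

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(t.size for t in self.component_categoricals[0])

    def feature_marginals(self) -> list[np.ndarray]:
        """Model marginal of each feature: sum_r pi_r theta[r][j]."""
        pi = self.mixture_weights
        return [
            sum(pi[r] * self.component_categoricals[r][j] for r in range(pi.size))
            for j in range(self.d)
        ]

    # plain-text round trip so fitted parameter sets can be reused as fixtures
    def to_json(self, path: str | Path) -> None:
        payload = {
            "mixture_weights": self.mixture_weights.tolist(),
            "component_categoricals": [
                [t.tolist() for t in comp] for comp in self.component_categoricals
            ],
            "regression_weights": self.regression_weights.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenerativeParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.array(payload["mixture_weights"]),
            tuple(tuple(np.array(t) for t in comp)
                  for comp in payload["component_categoricals"]),
            np.array(payload["regression_weights"]),
        )


@dataclass(frozen=True)
class FeatureEncoding:
    """Dummy (reference-level) coding with a leading intercept.

    Feature ``j`` with ``L_j`` levels contributes ``L_j - 1`` indicator columns,
    its reference level contributing none, so the encoded length is
    ``p = 1 + sum_j (L_j - 1)``. Full one-hot would make the Poisson MLE
    non-identifiable alongside the intercept.
    """

    level_counts: tuple[int, ...]
    reference_levels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        lc = tuple(int(l) for l in self.level_counts)
        object.__setattr__(self, "level_counts", lc)
        refs = self.reference_levels
        refs = tuple(0 for _ in lc) if refs is None else tuple(int(r) for r in refs)
        if len(refs) != len(lc) or any(not 0 <= r < l for r, l in zip(refs, lc)):
            raise ValueError("invalid reference levels")
        object.__setattr__(self, "reference_levels", refs)

    @property
    def d(self) -> int:
        return len(self.level_counts)

    @property
    def p(self) -> int:
        return 1 + sum(l - 1 for l in self.level_counts)

    def column_names(self) -> list[str]:
        names = ["intercept"]
        for j, (lj, ref) in enumerate(zip(self.level_counts, self.reference_levels)):
            names += [f"x{j + 1}[{l}]" for l in range(lj) if l != ref]
        return names


def encode_features(record: Sequence[int], enc: FeatureEncoding) -> np.ndarray:
    """Encode one record of category codes into the design vector."""
    return encode_dataset(np.asarray(record, dtype=np.int64)[None, :], enc)[0]


def encode_dataset(features: np.ndarray, enc: FeatureEncoding) -> np.ndarray:
    """Vectorized dummy encoding of an ``(n, d)`` code array into ``(n, p)``."""
    feats = np.asarray(features, dtype=np.int64)
    if feats.ndim != 2 or feats.shape[1] != enc.d:
        raise ValueError("feature array shape does not match encoding")
    n = feats.shape[0]
    out = np.zeros((n, enc.p), dtype=float)
    out[:, 0] = 1.0
    col = 1
    for j, (lj, ref) in enumerate(zip(enc.level_counts, enc.reference_levels)):
        codes = feats[:, j]
        if codes.size and (codes.min() < 0 or codes.max() >= lj):
            raise ValueError(f"feature {j} has out-of-range codes for the encoding")
        nonref = [l for l in range(lj) if l != ref]
        for k, level in enumerate(nonref):
            out[:, col + k] = codes == level
        col += lj - 1
    return out


def log_prob_features(record: Sequence[int], params: GenerativeParams) -> float:
    """Log mixture probability of one feature record, evaluated in log space."""
    x = np.asarray(record, dtype=np.int64).ravel()
    pi = params.mixture_weights
    with np.errstate(divide="ignore"):
        comp_logp = np.array([
            np.log(pi[r]) + sum(
                np.log(params.component_categoricals[r][j][x[j]])
                for j in range(params.d)
            )
            for r in range(params.n_components)
        ])
    if np.all(np.isneginf(comp_logp)):
        return -np.inf
    return float(logsumexp(comp_logp))


def log_prob_outcome(y: int, record: Sequence[int], w: np.ndarray,
                     enc: FeatureEncoding) -> float:
    """Poisson log-pmf of ``y`` at rate ``lambda = exp(w . encode(record))``."""
    if y < 0 or int(y) != y:
        raise ValueError("y must be a nonnegative integer")
    eta = float(encode_features(record, enc) @ np.asarray(w, dtype=float))
    return y * eta - math.exp(eta) - float(gammaln(y + 1))


def predict(record: Sequence[int], w: np.ndarray, enc: FeatureEncoding) -> int:
    """Poisson-pmf argmax over y in {0,1}: 1 iff lambda > 1 (tie -> 0)."""
    eta = float(encode_features(record, enc) @ np.asarray(w, dtype=float))
    return int(eta > 0.0)


def sample_binary_outcomes(design: np.ndarray, w: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw y ~ Poisson(exp(design . w)) and clip to {0,1}.

    The single code path shared by population generation and synthetic-data
    sampling, so both stages use the identical outcome mapping.
    """
    eta = np.clip(design @ np.asarray(w, dtype=float), -700, 30)
    lam = np.exp(eta)
    return np.minimum(rng.poisson(lam), 1).astype(np.int64)


def sample_synthetic(params: GenerativeParams, n: int, enc: FeatureEncoding,
                     seed: int | np.random.Generator) -> TabularDataset:
    """Draw ``n`` i.i.d. records from the generative model."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if tuple(params.level_counts) != tuple(enc.level_counts):
        raise ValueError("params and encoding disagree on level counts")
    R = params.n_components
    comps = rng.choice(R, size=n, p=params.mixture_weights)
    feats = np.empty((n, params.d), dtype=np.int64)
    for r in range(R):
        mask = comps == r
        m = int(mask.sum())
        if not m:
            continue
        for j in range(params.d):
            theta = params.component_categoricals[r][j]
            feats[mask, j] = rng.choice(theta.size, size=m, p=theta)
    design = encode_dataset(feats, enc) if n else np.zeros((0, enc.p))
    y = sample_binary_outcomes(design, params.regression_weights, rng)
    return TabularDataset(feats, y, params.level_counts)
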