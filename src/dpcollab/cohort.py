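"""Multi-center cohort simulation with known ground truth.

Generates a population from known generative parameters, partitions it into
heterogeneous centers (each center over- or under-represents feature categories,
so local distributions shift away from the population: Pr[x|m] != Pr[x]), and
provides the manipulations the experiments need: uniform subsampling, two-way
marginal skew injection, and per-center train/test splitting with a global
(union) test set.

The default configuration emulates a multi-center health cohort: five
categorical ethnic/socioeconomic-style features, a rare binary test-result
outcome (~13% positive) driven by a log-linear rate model, and a ~7% minority
category on the first feature that the skew experiment depletes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import TabularDataset, concat_datasets
from .model import FeatureEncoding, GenerativeParams, sample_synthetic
from .rng import stream

__all__ = [
    "CohortConfig",
    "default_true_params",
    "default_cohort_config",
    "generate_population",
    "partition_centers",
    "subsample_dataset",
    "inject_marginal_skew",
    "split_train_test",
    "MINORITY_FEATURE",
    "MINORITY_CATEGORY",
]

# feature/category the skew experiment targets: a ~7% minority group
MINORITY_FEATURE = 0
MINORITY_CATEGORY = 1

_DEFAULT_LEVELS = (5, 4, 3, 3, 2)
_BASE_MARGINALS = (
    np.array([0.80, 0.07, 0.05, 0.05, 0.03]),
    np.array([0.40, 0.30, 0.20, 0.10]),
    np.array([0.50, 0.30, 0.20]),
    np.array([0.34, 0.33, 0.33]),
    np.array([0.60, 0.40]),
)
# intercept -2 puts the base positive rate near exp(-2) ~ 0.135; the minority
# category carries an elevated rate so depleting its positive cell is informative
_TRUE_W = np.array([
    -2.0,
    0.8, 0.3, -0.3, 0.2,      # feature 1, levels 1..4 vs reference 0
    0.3, -0.2, 0.1,           # feature 2
    0.2, -0.1,                # feature 3
    -0.2, 0.1,                # feature 4
    0.25,                     # feature 5
])


def default_true_params(n_components: int = 4, concentration: float = 30.0,
                        seed: int = 20210315) -> GenerativeParams:
    """Ground-truth generative parameters for the simulated cohort.

    Component categoricals are Dirichlet perturbations of fixed base marginals,
    so the mixture average stays near the base while individual components
    differ (genuine latent structure for the fitted mixture to find).
    """
    rng = np.random.default_rng(seed)
    theta = tuple(
        tuple(rng.dirichlet(concentration * base) for base in _BASE_MARGINALS)
        for _ in range(n_components)
    )
    pi = rng.dirichlet(np.full(n_components, 5.0))
    return GenerativeParams(pi, theta, _TRUE_W.copy())


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for one simulated cohort."""

    n_population: int = 20000
    level_counts: tuple[int, ...] = _DEFAULT_LEVELS
    true_params: GenerativeParams = field(default_factory=default_true_params)
    n_centers: int = 8
    tilt_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_population < 0:
            raise ValueError("n_population must be nonnegative")
        if self.n_centers < 1:
            raise ValueError("need at least one center")
        if self.tilt_strength < 0:
            raise ValueError("tilt_strength must be nonnegative")
        if tuple(self.true_params.level_counts) != tuple(self.level_counts):
            raise ValueError("true_params do not match level_counts")

    @property
    def encoding(self) -> FeatureEncoding:
        return FeatureEncoding(self.level_counts)


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    return replace(CohortConfig(seed=seed), **overrides)


def generate_population(config: CohortConfig) -> TabularDataset:
    """Draw the ground-truth population i.i.d. from the true generative model."""
    rng = stream(config.seed, "population")
    return sample_synthetic(config.true_params, config.n_population,
                            config.encoding, rng)


def partition_centers(pop: TabularDataset, n_centers: int, tilt_strength: float,
                      seed: int) -> list[TabularDataset]:
    """Split the population into ``M`` disjoint, non-uniformly sampled centers.

    Each center draws a log-affinity vector over the first feature's categories
    from ``N(0, tilt_strength^2)``; a record with first-feature code ``c`` is
    assigned to center ``m`` with probability proportional to
    ``exp(affinity[m, c])``. The affinity matrix is balanced (Sinkhorn-style,
    against the empirical category distribution) so every center's *expected
    size* is ``n / M`` while its category composition still shifts — local
    distributions move away from the population without starving any center.
    ``tilt_strength = 0`` reduces to uniform multinomial assignment.
    """
    if n_centers < 1:
        raise ValueError("need at least one center")
    if n_centers > pop.n:
        raise ValueError(f"cannot split {pop.n} records into {n_centers} centers")
    rng = stream(seed, "partition")
    n_cat = pop.level_counts[0]
    cat_freq = np.bincount(pop.features[:, 0], minlength=n_cat) / max(pop.n, 1)
    B = np.exp(tilt_strength * rng.standard_normal((n_centers, n_cat)))
    for _ in range(200):
        B /= B.sum(axis=0, keepdims=True)             # columns: P(center | cat)
        row = B @ cat_freq                            # expected share per center
        B /= np.maximum(row, 1e-12)[:, None] * n_centers
    B /= B.sum(axis=0, keepdims=True)
    probs = B[:, pop.features[:, 0]]                  # (M, n)
    u = rng.random(pop.n)
    assignment = (np.cumsum(probs, axis=0) < u).sum(axis=0)
    return [pop.take(np.flatnonzero(assignment == m)).with_center(m)
            for m in range(n_centers)]


def subsample_dataset(ds: TabularDataset, fraction: float, seed: int
                      ) -> TabularDataset:
    """Uniform sample without replacement of ``floor(fraction * n)`` records."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return ds
    keep = int(np.floor(fraction * ds.n))
    rng = stream(seed, "subsample")
    idx = np.sort(rng.choice(ds.n, size=keep, replace=False))
    return ds.take(idx)


def inject_marginal_skew(ds: TabularDataset, feature: int, category: int,
                         outcome_value: int, keep_fraction: float, seed: int
                         ) -> TabularDataset:
    """Deplete one cell of the (feature, outcome) two-way marginal.

    Records with ``feature == category`` and ``outcome == outcome_value`` are
    subsampled to ``round(keep_fraction * cell_count)`` (round half up, so small
    cells keep at least one record down to 10%); every other record is kept.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    in_cell = (ds.features[:, feature] == category) & (ds.outcome == outcome_value)
    cell_idx = np.flatnonzero(in_cell)
    if cell_idx.size == 0:
        warnings.warn("skew target cell is empty; dataset returned unchanged",
                      stacklevel=2)
        return ds
    if keep_fraction == 1.0:
        return ds
    keep = int(np.floor(keep_fraction * cell_idx.size + 0.5))
    rng = stream(seed, "skew")
    kept_cell = rng.choice(cell_idx, size=keep, replace=False)
    idx = np.sort(np.concatenate([np.flatnonzero(~in_cell), kept_cell]))
    return ds.take(idx)


def split_train_test(centers: list[TabularDataset], ratio: float, seed: int
                     ) -> tuple[list[TabularDataset], TabularDataset]:
    """Per-center uniform train/test split; global test = union of local tests.

    ``ratio`` is the training fraction (0.8 gives the 80/20 design); each
    center's training size is ``floor(ratio * n_m)``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    trains, tests = [], []
    for m, ds in enumerate(centers):
        if ds.n == 0:
            raise ValueError(f"center {m} is empty")
        rng = stream(seed, f"split-center-{m}")
        perm = rng.permutation(ds.n)
        n_train = int(np.floor(ratio * ds.n))
        trains.append(ds.take(np.sort(perm[:n_train])))
        tests.append(ds.take(np.sort(perm[n_train:])))
    return trains, concat_datasets(tests)
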