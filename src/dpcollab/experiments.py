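"""End-to-end experiment designs on simulated multi-center cohorts.

Four designs, all sharing one pipeline (simulate cohort -> per-center 80/20
split -> subsample training data -> fit a DP generative model per center ->
release K synthetic replicates each -> fit the downstream Poisson regression
on K combined sets -> Rubin-combine -> Monte-Carlo log-likelihood samples on
the global test set):

* combined vs local: every center's local-only model against its model trained
  with all other centers' synthetic data, plus the privacy-agnostic pooled-data
  baseline;
* incremental: synthetic data from other centers added one by one in random
  orders;
* size sweep: the combined-vs-local design at several training-set fractions;
* skew: an artificial population-matched party whose (minority category,
  positive outcome) two-way cell is depleted, evaluated on the minority
  subgroup of held-out data.

Results are long-format pandas DataFrames (one row per log-likelihood sample),
reproducible bit-for-bit from (config, master seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .accountant import PrivacyParams, calibrate_noise
from .analysis import (FitResult, fit_poisson_regression, ranked_welch_test,
                       rubins_rules, sample_loglik_distribution)
from .cohort import (MINORITY_CATEGORY, MINORITY_FEATURE, CohortConfig,
                     generate_population, inject_marginal_skew,
                     partition_centers, split_train_test, subsample_dataset)
from .datasets import TabularDataset, concat_datasets
from .dpvi import OptimizerConfig, fit_dpvi
from .release import ReleaseBundle, assemble_combined_sets, release_synthetic_sets
from .rng import child_seed
from .transforms import MeanFieldPosterior, ParamLayout

__all__ = [
    "ExperimentConfig",
    "run_combined_vs_local",
    "run_incremental",
    "run_size_sweep",
    "run_skew_experiment",
    "summarize_significance",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol constants for one experiment campaign.

    Defaults follow the reference protocol: K = 100 synthetic replicates per
    party, 100 log-likelihood samples, 10 repeats, 100 order permutations,
    privacy target (epsilon, delta) = (1, 1e-6), 80/20 train/test split, 10%
    training subsample, size-sweep grid {10, 20, 50, 100}% and skew
    keep-fraction grid {10, 25, 50, 75}%.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    epsilon: float = 1.0
    delta: float = 1e-6
    clip_norm: float = 2.0
    iterations: int = 8000
    batch_target: float = 25.0  # q is chosen so q * n ~ batch_target
    n_mixture_components: int = 16
    k_replicates: int = 100
    n_loglik_samples: int = 100
    n_repeats: int = 10
    n_permutations: int = 100
    subsample_fraction: float = 0.1
    size_sweep: tuple[float, ...] = (0.10, 0.20, 0.50, 1.00)
    skew_fractions: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75)
    skew_feature: int = MINORITY_FEATURE
    skew_category: int = MINORITY_CATEGORY
    skew_outcome: int = 1
    train_ratio: float = 0.8
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_replicates, self.n_loglik_samples, self.n_repeats,
               self.n_permutations) < 1:
            raise ValueError("all protocol counts must be >= 1")
        for f in (self.subsample_fraction, *self.size_sweep, *self.skew_fractions):
            if not 0 < f <= 1:
                raise ValueError("fractions must lie in (0, 1]")

    @property
    def layout(self) -> ParamLayout:
        return ParamLayout(self.n_mixture_components, self.cohort.level_counts)

    def privacy_for(self, n: int) -> PrivacyParams:
        q = round(min(1.0, self.batch_target / max(n, 1)), 2)
        pp = PrivacyParams(self.epsilon, self.delta, self.clip_norm, None,
                           max(q, 0.01), self.iterations)
        return pp.calibrated()


# ---------------------------------------------------------------- pipeline --

def _prepare(cfg: ExperimentConfig, fraction: float
             ) -> tuple[list[TabularDataset], TabularDataset]:
    """Cohort -> centers -> per-center split -> subsampled training sets.

    The cohort and its split are functions of the cohort seed only, so repeats
    (which reseed inference and sampling) reuse the same split.
    """
    cohort = replace(cfg.cohort, seed=child_seed(cfg.seed, "cohort"))
    pop = generate_population(cohort)
    centers = partition_centers(pop, cohort.n_centers, cohort.tilt_strength,
                                child_seed(cfg.seed, "centers"))
    trains, global_test = split_train_test(centers, cfg.train_ratio,
                                           child_seed(cfg.seed, "split"))
    trains = [
        subsample_dataset(t, fraction, child_seed(cfg.seed, f"subsample-{m}"))
        for m, t in enumerate(trains)
    ]
    return trains, global_test


_RELEASE_MEMO: dict[tuple, dict[int, ReleaseBundle]] = {}


def _trains_checksum(trains: Sequence[TabularDataset]) -> int:
    import zlib
    crc = 0
    for t in trains:
        crc = zlib.crc32(t.features.tobytes(), crc)
        crc = zlib.crc32(t.outcome.tobytes(), crc)
    return crc


def _fit_and_release(trains: Sequence[TabularDataset], cfg: ExperimentConfig,
                     repeat: int) -> dict[int, ReleaseBundle]:
    """One repeat's DPVI fits and K-replicate releases for every center.

    Memoized on (protocol constants, repeat, training-data checksum): the
    released bundles are a pure function of those inputs, so experiment designs
    sharing a cohort (combined / incremental / skew) reuse the same releases —
    exactly as parties publishing once would.
    """
    memo_key = (cfg.seed, cfg.epsilon, cfg.delta, cfg.clip_norm,
                cfg.iterations, cfg.batch_target, cfg.n_mixture_components,
                cfg.k_replicates, cfg.optimizer.step_size, repeat,
                _trains_checksum(trains))
    if memo_key in _RELEASE_MEMO:
        return _RELEASE_MEMO[memo_key]
    rseed = child_seed(cfg.seed, f"repeat-{repeat}")
    bundles: dict[int, ReleaseBundle] = {}
    for m, tr in enumerate(trains):
        pp = cfg.privacy_for(tr.n)
        post = fit_dpvi(tr, cfg.layout, pp, cfg.optimizer,
                        seed=child_seed(rseed, f"dpvi-{m}"))
        bundles[m] = release_synthetic_sets(
            post, cfg.k_replicates, tr.n,
            seed=child_seed(rseed, f"release-{m}"), party=m,
            realized_epsilon=pp.realized_epsilon())
    _RELEASE_MEMO[memo_key] = bundles
    return bundles


def _rubin_from_sets(sets: Iterable[TabularDataset], enc) -> tuple:
    """Fit every combined set and Rubin-combine the converged fits.

    Small combined sets (e.g. the first step of incremental sharing) can
    separate — a category level with no positive outcomes drives its
    coefficient toward -infinity. When fewer than two fits strictly converge,
    all finite fits are combined instead: their extreme coefficients and huge
    standard errors then show up honestly as a wild log-likelihood spread,
    rather than aborting the experiment.
    """
    fits = [fit_poisson_regression(cs, enc) for cs in sets]
    good = [f for f in fits if f.converged]
    if len(good) < 2:
        good = [replace_fit_converged(f) for f in fits
                if np.all(np.isfinite(f.w_hat)) and np.all(np.isfinite(f.v_hat))
                and np.all(f.v_hat >= 0)]
    if len(good) < 2:
        raise RuntimeError("fewer than two usable replicate fits")
    return rubins_rules(good), len(fits) - len(good)


def replace_fit_converged(f: FitResult) -> FitResult:
    return FitResult(f.w_hat, f.v_hat, True, f.iterations, f.dropped_columns)


def _sample_rows(est, test, enc, cfg, seed, **labels) -> list[dict]:
    ll = sample_loglik_distribution(est, test, enc, cfg.n_loglik_samples,
                                    seed=seed, normalize=True)
    return [dict(labels, sample=i, loglik=float(v))
            for i, v in enumerate(ll.values)]


# ------------------------------------------------------------- experiments --

def run_combined_vs_local(cfg: ExperimentConfig, fraction: float | None = None
                          ) -> pd.DataFrame:
    """Per-center local-only vs all-synthetic-combined, plus pooled baseline."""
    fraction = cfg.subsample_fraction if fraction is None else fraction
    trains, global_test = _prepare(cfg, fraction)
    enc = cfg.cohort.encoding
    pooled_train = concat_datasets(trains)
    rows: list[dict] = []
    for rep in range(cfg.n_repeats):
        rseed = child_seed(cfg.seed, f"repeat-{rep}")
        bundles = _fit_and_release(trains, cfg, rep)
        pooled_fit = fit_poisson_regression(pooled_train, enc)
        rows += _sample_rows(pooled_fit, global_test, enc, cfg,
                             child_seed(rseed, "ll-pooled"),
                             experiment="combined_vs_local", center=-1,
                             condition="pooled", repeat=rep, fraction=fraction)
        for m, tr in enumerate(trains):
            local_fit = fit_poisson_regression(tr, enc)
            rows += _sample_rows(local_fit, global_test, enc, cfg,
                                 child_seed(rseed, f"ll-local-{m}"),
                                 experiment="combined_vs_local", center=m,
                                 condition="local", repeat=rep,
                                 fraction=fraction)
            est, _ = _rubin_from_sets(
                assemble_combined_sets(tr, bundles, cfg.k_replicates,
                                       own_party=m), enc)
            rows += _sample_rows(est, global_test, enc, cfg,
                                 child_seed(rseed, f"ll-combined-{m}"),
                                 experiment="combined_vs_local", center=m,
                                 condition="combined", repeat=rep,
                                 fraction=fraction)
    return pd.DataFrame(rows)


def run_incremental(cfg: ExperimentConfig) -> pd.DataFrame:
    """Add other centers' synthetic data one by one in random orders.

    Step 0 is the local-only model; step s the Rubin-combined model using the
    first s parties of the permuted order (replicate-aligned: the k-th combined
    set takes replicate k from every included party).
    """
    trains, global_test = _prepare(cfg, cfg.subsample_fraction)
    enc = cfg.cohort.encoding
    M = len(trains)
    rows: list[dict] = []
    for rep in range(cfg.n_repeats):
        rseed = child_seed(cfg.seed, f"repeat-{rep}")
        bundles = _fit_and_release(trains, cfg, rep)
        for m, tr in enumerate(trains):
            local_fit = fit_poisson_regression(tr, enc)
            others = [pid for pid in sorted(bundles) if pid != m]
            perm_rng = np.random.default_rng(
                child_seed(rseed, f"orders-{m}"))
            for perm in range(cfg.n_permutations):
                order = perm_rng.permutation(others)
                rows += _sample_rows(
                    local_fit, global_test, enc, cfg,
                    child_seed(rseed, f"ll-inc-{m}-{perm}-0"),
                    experiment="incremental", center=m, condition="step",
                    repeat=rep, permutation=perm, step=0)
                for s in range(1, M):
                    subset = {pid: bundles[pid] for pid in order[:s]}
                    est, _ = _rubin_from_sets(
                        assemble_combined_sets(tr, subset, cfg.k_replicates,
                                               own_party=m), enc)
                    rows += _sample_rows(
                        est, global_test, enc, cfg,
                        child_seed(rseed, f"ll-inc-{m}-{perm}-{s}"),
                        experiment="incremental", center=m, condition="step",
                        repeat=rep, permutation=perm, step=s)
    return pd.DataFrame(rows)


def run_size_sweep(cfg: ExperimentConfig, focal_center: int | None = None
                   ) -> pd.DataFrame:
    """Combined-vs-local at each training-set fraction; results tabulated for
    one focal center (defaults to the largest, echoing the largest-site view)."""
    frames = []
    for frac in cfg.size_sweep:
        df = run_combined_vs_local(cfg, fraction=frac)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if focal_center is None:
        trains, _ = _prepare(cfg, 1.0)
        focal_center = int(np.argmax([t.n for t in trains]))
    out = out[(out["center"] == focal_center) | (out["condition"] == "pooled")]
    return out.assign(experiment="size_sweep").reset_index(drop=True)


def run_skew_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Artificial population-matched party with a depleted two-way marginal.

    The party is built from half the global test set (so its data matches the
    population); the (skew_feature == skew_category, outcome == skew_outcome)
    cell is subsampled to each keep fraction. Local-only and combined models
    are evaluated on the minority-category subgroup of the *other* half of the
    test set, which stays disjoint from the party's data.
    """
    trains, global_test = _prepare(cfg, cfg.subsample_fraction)
    enc = cfg.cohort.encoding
    half_rng = np.random.default_rng(child_seed(cfg.seed, "skew-half"))
    perm = half_rng.permutation(global_test.n)
    n_half = global_test.n // 2
    party_data = global_test.take(np.sort(perm[:n_half]))
    eval_half = global_test.take(np.sort(perm[n_half:]))
    subgroup = eval_half.take(np.flatnonzero(
        eval_half.features[:, cfg.skew_feature] == cfg.skew_category))
    if subgroup.n == 0:
        raise ValueError("minority subgroup empty in the evaluation half")
    new_party = max(len(trains), 1 + max(range(len(trains)), default=0))
    rows: list[dict] = []
    for rep in range(cfg.n_repeats):
        rseed = child_seed(cfg.seed, f"repeat-{rep}")
        bundles = _fit_and_release(trains, cfg, rep)
        for keep in cfg.skew_fractions:
            skewed = inject_marginal_skew(
                party_data, cfg.skew_feature, cfg.skew_category,
                cfg.skew_outcome, keep,
                seed=child_seed(cfg.seed, f"skew-{keep}"))
            local_fit = fit_poisson_regression(skewed, enc)
            rows += _sample_rows(local_fit, subgroup, enc, cfg,
                                 child_seed(rseed, f"ll-skl-{keep}"),
                                 experiment="skew", center=new_party,
                                 condition="local", repeat=rep,
                                 keep_fraction=keep)
            est, _ = _rubin_from_sets(
                assemble_combined_sets(skewed, bundles, cfg.k_replicates,
                                       own_party=new_party), enc)
            rows += _sample_rows(est, subgroup, enc, cfg,
                                 child_seed(rseed, f"ll-skc-{keep}"),
                                 experiment="skew", center=new_party,
                                 condition="combined", repeat=rep,
                                 keep_fraction=keep)
    return pd.DataFrame(rows)


# ------------------------------------------------------------ significance --

def summarize_significance(table: pd.DataFrame, condition_a: str,
                           condition_b: str, sides: str = "one",
                           by: Sequence[str] = ("center",)) -> pd.DataFrame:
    """Ranked Welch test of condition_a vs condition_b within each group.

    Pools all log-likelihood samples of each condition (across repeats and, if
    present, permutations), mirroring the n_local = repeats x samples,
    n_combined = repeats x permutations x samples group sizes of the protocol.
    """
    need = {"condition", "loglik"} | set(by)
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"result table lacks columns: {sorted(missing)}")
    rows = []
    for keys, grp in table.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        a = grp.loc[grp["condition"] == condition_a, "loglik"].to_numpy()
        b = grp.loc[grp["condition"] == condition_b, "loglik"].to_numpy()
        if a.size == 0 or b.size == 0:
            raise ValueError(
                f"condition missing in group {dict(zip(by, keys))}")
        stat, p = ranked_welch_test(a, b, sides=sides)
        rows.append(dict(zip(by, keys),
                         comparison=f"{condition_a} vs {condition_b}",
                         sides=sides, statistic=stat, p=p,
                         n_a=a.size, n_b=b.size))
    return pd.DataFrame(rows)
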