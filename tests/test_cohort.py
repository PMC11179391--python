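"""Cohort simulation: population law, center partition, subsampling, skew."""

import math

import numpy as np
import pytest
from scipy.stats import chi2, chi2_contingency

from dpcollab.cohort import (CohortConfig, default_true_params,
                             generate_population, inject_marginal_skew,
                             partition_centers, split_train_test,
                             subsample_dataset)
from dpcollab.datasets import TabularDataset
from dpcollab.model import GenerativeParams


def _single_cell_config(n: int, intercept: float = 0.0) -> CohortConfig:
    params = GenerativeParams(np.array([1.0]), ((np.array([1.0]),),),
                              np.array([intercept]))
    return CohortConfig(n_population=n, level_counts=(1,), true_params=params,
                        n_centers=1, tilt_strength=0.0, seed=42)


class TestGeneratePopulation:
    def test_unit_rate_outcome_frequency(self):
        # lambda = 1 everywhere; P(min(Poisson(1), 1) = 1) = 1 - e^-1
        pop = generate_population(_single_cell_config(100000))
        assert pop.outcome.mean() == pytest.approx(1 - math.exp(-1), abs=0.01)

    def test_empty_population(self):
        pop = generate_population(_single_cell_config(0))
        assert pop.n == 0

    def test_default_schema_has_five_features(self):
        cfg = CohortConfig(n_population=100, seed=1,
                           true_params=default_true_params(n_components=16))
        pop = generate_population(cfg)
        assert pop.d == 5
        assert cfg.true_params.n_components == 16

    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_population=300, seed=5)
        a, b = generate_population(cfg), generate_population(cfg)
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.outcome, b.outcome)


@pytest.fixture(scope="module")
def pop():
    return generate_population(CohortConfig(n_population=10000, seed=3))


class TestPartitionCenters:

    def test_single_center_identity(self, pop):
        (only,) = partition_centers(pop, 1, 0.0, seed=1)
        np.testing.assert_array_equal(only.features, pop.features)

    def test_partition_conserves_records(self, pop):
        centers = partition_centers(pop, 4, 2.0, seed=1)
        assert sum(c.n for c in centers) == pop.n
        # disjointness: per-center index recovery via record multiset
        all_rows = np.concatenate([c.features for c in centers])
        assert all_rows.shape == pop.features.shape

    def test_more_centers_than_records_rejected(self, pop):
        with pytest.raises(ValueError):
            partition_centers(pop.take(np.arange(3)), 5, 0.0, seed=0)

    def test_tilt_zero_marginals_match_population(self, pop):
        centers = partition_centers(pop, 4, 0.0, seed=7)
        for c in centers:
            tv = 0.5 * np.abs(c.feature_marginal(0)
                              - pop.feature_marginal(0)).sum()
            assert tv < 0.05

    def test_tilt_induces_feature_center_dependence(self, pop):
        centers = partition_centers(pop, 4, 2.0, seed=11)
        n_cat = pop.level_counts[0]
        table = np.stack([
            np.bincount(c.features[:, 0], minlength=n_cat) for c in centers
        ])
        table = table[:, table.sum(axis=0) > 0]
        stat = chi2_contingency(table)[0]
        dof = (table.shape[0] - 1) * (table.shape[1] - 1)
        assert stat > chi2.ppf(0.99, dof)


class TestSubsample:
    @pytest.fixture
    def ds(self):
        return generate_population(CohortConfig(n_population=10, seed=2))

    def test_identity_at_full_fraction(self, ds):
        assert subsample_dataset(ds, 1.0, seed=1) is ds

    def test_floor_rule(self, ds):
        assert subsample_dataset(ds, 0.25, seed=1).n == 2  # floor(2.5)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, ds, bad):
        with pytest.raises(ValueError):
            subsample_dataset(ds, bad, seed=1)

    @pytest.mark.parametrize("fraction", [0.10, 0.20, 0.50, 1.00])
    def test_size_sweep_grid_values_accepted(self, fraction):
        big = generate_population(CohortConfig(n_population=1000, seed=2))
        out = subsample_dataset(big, fraction, seed=3)
        assert out.n == int(np.floor(fraction * big.n))


class TestInjectSkew:
    @pytest.fixture
    def ds(self):
        # constructed fixture: 40 records in the target cell, 60 outside
        feats = np.zeros((100, 2), dtype=int)
        feats[:40, 0] = 1
        outcome = np.zeros(100, dtype=int)
        outcome[:40] = 1
        outcome[60:] = 1  # cell (feature0==1, y==1): rows 0..39
        return TabularDataset(feats, outcome, (2, 2))

    def test_identity_at_full_keep(self, ds):
        assert inject_marginal_skew(ds, 0, 1, 1, 1.0, seed=1) is ds

    def test_exact_cell_arithmetic(self, ds):
        out = inject_marginal_skew(ds, 0, 1, 1, 0.25, seed=1)
        in_cell = (out.features[:, 0] == 1) & (out.outcome == 1)
        assert in_cell.sum() == 10          # round(0.25 * 40)
        assert out.n == 70                  # complement of 60 untouched

    def test_other_cells_unchanged(self, ds):
        out = inject_marginal_skew(ds, 0, 1, 1, 0.10, seed=1)
        for feat_val in (0, 1):
            for y_val in (0, 1):
                if (feat_val, y_val) == (1, 1):
                    continue
                before = ((ds.features[:, 0] == feat_val)
                          & (ds.outcome == y_val)).sum()
                after = ((out.features[:, 0] == feat_val)
                         & (out.outcome == y_val)).sum()
                assert before == after

    def test_round_half_up_keeps_small_cells_alive(self, ds):
        small = ds.take(np.arange(36, 100))  # only 4 records in the cell
        out = inject_marginal_skew(small, 0, 1, 1, 0.10, seed=1)
        in_cell = (out.features[:, 0] == 1) & (out.outcome == 1)
        assert in_cell.sum() == 0  # round(0.4) = 0: rounds to nearest
        out = inject_marginal_skew(small, 0, 1, 1, 0.15, seed=1)
        in_cell = (out.features[:, 0] == 1) & (out.outcome == 1)
        assert in_cell.sum() == 1  # round(0.6) = 1

    def test_empty_cell_warns_and_returns_unchanged(self, ds):
        no_cell = ds.take(np.arange(40, 100))
        clean = no_cell.take(np.flatnonzero(
            ~((no_cell.features[:, 0] == 1) & (no_cell.outcome == 1))))
        with pytest.warns(UserWarning):
            out = inject_marginal_skew(clean, 0, 1, 1, 0.5, seed=1)
        assert out is clean


class TestSplitTrainTest:
    def test_eighty_twenty_split_sizes(self):
        ds = generate_population(CohortConfig(n_population=100, seed=4))
        trains, global_test = split_train_test([ds], 0.8, seed=1)
        assert trains[0].n == 80 and global_test.n == 20

    def test_global_test_is_union_of_local_tests(self):
        pop = generate_population(CohortConfig(n_population=1000, seed=4))
        centers = partition_centers(pop, 3, 1.0, seed=2)
        trains, global_test = split_train_test(centers, 0.8, seed=1)
        expected = sum(c.n - int(np.floor(0.8 * c.n)) for c in centers)
        assert global_test.n == expected
        assert sum(t.n for t in trains) + global_test.n == pop.n

    def test_split_reproducible(self):
        pop = generate_population(CohortConfig(n_population=500, seed=4))
        centers = partition_centers(pop, 2, 0.5, seed=2)
        t1, g1 = split_train_test(centers, 0.8, seed=9)
        t2, g2 = split_train_test(centers, 0.8, seed=9)
        np.testing.assert_array_equal(g1.features, g2.features)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.features, b.features)

    def test_empty_center_rejected(self):
        empty = TabularDataset(np.zeros((0, 1), dtype=int),
                               np.zeros(0, dtype=int), (1,))
        with pytest.raises(ValueError):
            split_train_test([empty], 0.8, seed=0)
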