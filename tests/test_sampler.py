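from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from dpsample import (
    DataTable,
    RunConfig,
    compare_distributions,
    largest_remainder_quotas,
    opdis_downsample,
    run_trial,
    select_relevant_features_pca,
    stratified_sample_indices,
)


class TestStratifiedSampling:
    def test_largest_remainder_quotas(self):
        np.testing.assert_array_equal(
            largest_remainder_quotas(np.array([60, 10, 30]), 10), [6, 1, 3]
        )

    def test_quotas_always_sum_to_size(self, rng):
        for _ in range(50):
            counts = rng.integers(1, 40, size=rng.integers(1, 6))
            size = int(rng.integers(1, counts.sum()))
            q = largest_remainder_quotas(counts, size)
            assert q.sum() == size and np.all(q >= 0) and np.all(q <= counts)

    def test_single_class_uniform_draw(self):
        idx = stratified_sample_indices(np.zeros(10), 9, seed=3)
        assert len(idx) == 9 and len(set(idx)) == 9

    def test_seed_determinism(self):
        labels = np.repeat([0, 1, 2], [60, 10, 30])
        a = stratified_sample_indices(labels, 10, seed=5)
        b = stratified_sample_indices(labels, 10, seed=5)
        c = stratified_sample_indices(labels, 10, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_class_proportions_preserved(self):
        labels = np.repeat([0, 1, 2], [60, 10, 30])
        idx = stratified_sample_indices(labels, 10, seed=1)
        sampled = labels[idx]
        assert [np.sum(sampled == c) for c in (0, 1, 2)] == [6, 1, 3]

    def test_size_bounds_enforced(self):
        with pytest.raises(ValueError):
            stratified_sample_indices(np.zeros(5), 5, seed=0)

    def test_uniform_inclusion_frequency(self):
        # every instance of a class has inclusion probability quota/count
        labels = np.repeat([0, 1], [20, 20])
        counts = np.zeros(40)
        n_draws = 500
        for seed in range(n_draws):
            counts[stratified_sample_indices(labels, 4, seed)] += 1
        p = 2 / 20
        sd = np.sqrt(n_draws * p * (1 - p))
        z = np.abs(counts - n_draws * p) / sd
        # Bonferroni-style simultaneous bound over 40 instances
        assert z.max() < stats.norm.ppf(1 - 0.01 / (2 * 40))


class TestRunTrial:
    def test_single_trial_reduces_to_stratified_draw(self, two_class_toy):
        cfg = RunConfig(size=4, seed=10, n_trials=1, max_workers=1)
        tr = run_trial(two_class_toy, cfg, 1)
        expected = stratified_sample_indices(two_class_toy.labels, 4, seed=11)
        np.testing.assert_array_equal(tr.selected_indices, expected)
        assert tr.trial_seed == 11

    def test_reproducible_and_consistent(self, iris_table):
        cfg = RunConfig(size=15, seed=0, n_trials=5, max_workers=1)
        a = run_trial(iris_table, cfg, 3)
        b = run_trial(iris_table, cfg, 3)
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)
        np.testing.assert_array_equal(a.per_variable_distance, b.per_variable_distance)
        assert len(a.per_variable_distance) == 4
        assert a.max_distance == a.per_variable_distance.max()


def _exhaustive_minmax(table, metric):
    """Brute-force min-max distance over all class-proportional subsets."""
    cls0 = np.flatnonzero(table.labels == 0)
    cls1 = np.flatnonzero(table.labels == 1)
    best = np.inf
    for a in combinations(cls0, 2):
        for b in combinations(cls1, 2):
            idx = np.sort(np.array(a + b))
            d = compare_distributions(
                table.values[idx, 0], table.values[:, 0], metric
            )
            best = min(best, d)
    return best


class TestOpdisDownsample:
    def test_matches_exhaustive_enumeration(self, two_class_toy):
        # 36 class-proportional subsets; enough trials to cover them all
        cfg = RunConfig(size=4, seed=0, n_trials=2000, metric_id="ad", max_workers=1)
        res = opdis_downsample(two_class_toy, cfg)
        assert res.winner.max_distance == pytest.approx(
            _exhaustive_minmax(two_class_toy, "ad"), abs=1e-12
        )

    def test_single_trial_is_plain_stratified_sampling(self, two_class_toy):
        cfg = RunConfig(size=4, seed=7, n_trials=1, max_workers=1)
        res = opdis_downsample(two_class_toy, cfg)
        expected = stratified_sample_indices(two_class_toy.labels, 4, seed=8)
        np.testing.assert_array_equal(
            np.flatnonzero(np.isin(np.arange(8), res.sample.row_ids)), expected
        )

    def test_partition_and_proportions(self, iris_table):
        cfg = RunConfig(size=15, seed=1, n_trials=20, max_workers=1)
        res = opdis_downsample(iris_table, cfg)
        assert res.sample.n == 15 and res.removed.n == 135
        assert sorted(np.concatenate([res.sample.row_ids, res.removed.row_ids])) \
            == list(range(150))
        assert [np.sum(res.sample.labels == c) for c in (0, 1, 2)] == [5, 5, 5]

    def test_prefix_monotonicity(self, iris_table):
        # min over a superset of the same seeded trials can only improve
        base = dict(size=15, seed=0, metric_id="ad", max_workers=1)
        d10 = opdis_downsample(iris_table, RunConfig(n_trials=10, **base))
        d100 = opdis_downsample(iris_table, RunConfig(n_trials=100, **base))
        assert d100.winner.max_distance <= d10.winner.max_distance

    def test_worker_count_does_not_change_result(self, iris_table):
        a = opdis_downsample(
            iris_table, RunConfig(size=15, seed=2, n_trials=40, job_size=10,
                                  max_workers=1))
        b = opdis_downsample(
            iris_table, RunConfig(size=15, seed=2, n_trials=40, job_size=10,
                                  max_workers=4))
        assert a.winner.trial_seed == b.winner.trial_seed
        assert a.winner.max_distance == b.winner.max_distance
        np.testing.assert_array_equal(a.sample.row_ids, b.sample.row_ids)

    def test_unlabeled_data_treated_as_one_class(self, rng):
        data = DataTable(values=rng.normal(size=(30, 2)))
        res = opdis_downsample(data, RunConfig(size=6, n_trials=5, max_workers=1))
        assert res.sample.n == 6


class TestPcaFeatureSelection:
    def test_signal_variable_singled_out(self, rng):
        # one high-variance signal + 9 tiny-variance noise variables
        X = np.concatenate(
            [rng.normal(0, 10, size=(200, 1)), rng.normal(0, 0.01, size=(200, 9))],
            axis=1,
        )
        data = DataTable(values=X)
        assert select_relevant_features_pca(data) == ("V1",)

    def test_output_contained_in_feature_set(self, rng):
        data = DataTable(values=rng.normal(size=(100, 2)))
        assert set(select_relevant_features_pca(data)) <= set(data.feature_names)

    def test_all_constant_data_falls_back_to_all_variables(self):
        data = DataTable(values=np.ones((20, 3)), labels=np.zeros(20))
        assert select_relevant_features_pca(data) == ()
        res = opdis_downsample(
            data, RunConfig(size=5, n_trials=2, pca_importance=True, max_workers=1)
        )
        assert res.variables_assessed == data.feature_names

    def test_pca_importance_restricts_assessed_variables(self, rng):
        X = np.concatenate(
            [rng.normal(0, 10, size=(100, 1)), rng.normal(0, 0.01, size=(100, 4))],
            axis=1,
        )
        data = DataTable(values=X, labels=rng.integers(0, 2, 100))
        res = opdis_downsample(
            data, RunConfig(size=10, n_trials=3, pca_importance=True, max_workers=1)
        )
        assert res.variables_assessed == ("V1",)
        assert len(res.winner.per_variable_distance) == 1
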