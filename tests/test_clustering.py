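import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

import dfcstates as d
from dfcstates.clustering import elbow_point


def three_clouds(n_per=100, sep=10.0, seed=0):
    """Three 2-D Gaussian clouds separated by ``sep`` standard deviations."""
    rng = np.random.default_rng(seed)
    centres = np.array([[0.0, 0.0], [sep, 0.0], [0.0, sep]])
    X = np.vstack([c + rng.normal(size=(n_per, 2)) for c in centres])
    labels = np.repeat(np.arange(3), n_per)
    return X, labels


class TestKmeansL1:
    def test_k1_centroid_is_coordinatewise_median(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(51, 7))
        model = d.kmeans_l1(X, 1, n_init=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], np.median(X, axis=0))

    def test_perfect_separation_zero_cost(self):
        points = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.repeat(points, 10, axis=0)
        model = d.kmeans_l1(X, 3, n_init=5, seed=1)
        assert model.cost == pytest.approx(0.0)
        got = {tuple(c) for c in model.centroids}
        assert got == {tuple(p) for p in points}

    def test_recovers_separated_clouds_exactly(self):
        X, truth = three_clouds(seed=2)
        model = d.kmeans_l1(X, 3, n_init=10, seed=2)
        assert adjusted_rand_score(truth, model.labels) == 1.0
        # labels equal brute-force nearest-centroid assignment
        brute = cdist(X, model.centroids, metric="cityblock").argmin(axis=1)
        np.testing.assert_array_equal(model.labels, brute)

    def test_objective_monotone_over_iterations(self):
        X, _ = three_clouds(n_per=60, sep=3.0, seed=3)
        model = d.kmeans_l1(X, 4, n_init=3, seed=3)
        assert np.all(np.diff(model.cost_history) <= 1e-9)

    def test_restarts_never_hurt(self):
        X, _ = three_clouds(n_per=40, sep=4.0, seed=4)
        best10 = d.kmeans_l1(X, 3, n_init=10, seed=4).cost
        best1 = d.kmeans_l1(X, 3, n_init=1, seed=4).cost
        assert best10 <= best1 + 1e-12

    def test_seeded_determinism(self):
        X, _ = three_clouds(seed=5)
        a = d.kmeans_l1(X, 3, n_init=5, seed=11)
        b = d.kmeans_l1(X, 3, n_init=5, seed=11)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.cost == b.cost

    def test_mean_update_switch(self):
        X, truth = three_clouds(seed=6)
        model = d.kmeans_l1(X, 3, n_init=5, seed=6, update="mean")
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            d.kmeans_l1(np.zeros((2, 3)), 5)

    def test_non_finite_rejected(self):
        X = np.zeros((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            d.kmeans_l1(X, 2)


class TestElbowRatio:
    def test_zero_radius_clusters(self):
        points = np.array([[0.0, 0.0], [5.0, 5.0]])
        X = np.repeat(points, 5, axis=0)
        labels = np.repeat([0, 1], 5)
        assert d.elbow_ratio(X, labels, points) == pytest.approx(0.0)

    def test_ratio_by_construction(self):
        # every point at L1 distance 1 from its centroid; centroids 10 apart
        centroids = np.array([[0.0, 0.0], [10.0, 0.0]])
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [11.0, 0.0], [9.0, 0.0]])
        labels = np.array([0, 0, 1, 1])
        assert d.elbow_ratio(X, labels, centroids) == pytest.approx(0.1)

    def test_k1_undefined(self):
        with pytest.raises(ValueError):
            d.elbow_ratio(np.zeros((4, 2)), np.zeros(4, dtype=int), np.zeros((1, 2)))

    def test_smaller_at_true_k_on_clouds(self):
        wins = 0
        for seed in range(20):
            X, _ = three_clouds(n_per=50, seed=seed)
            m2 = d.kmeans_l1(X, 2, n_init=5, seed=seed)
            m3 = d.kmeans_l1(X, 3, n_init=5, seed=seed)
            r2 = d.elbow_ratio(X, m2.labels, m2.centroids)
            r3 = d.elbow_ratio(X, m3.labels, m3.centroids)
            wins += r3 < r2
        assert wins >= 15  # clear majority across seeds


class TestSelectK:
    def test_worked_curve_example(self):
        k, flat = elbow_point([2, 3, 4, 5], [1.0, 0.2, 0.18, 0.17])
        assert k == 3 and not flat

    def test_three_clouds_select_three(self):
        X, _ = three_clouds(n_per=80, seed=7)
        scan = d.select_k(X, (2, 6), n_init=5, seed=7)
        assert scan.best_k == 3
        assert set(scan.cost_curve) == set(scan.ratio_curve) == {2, 3, 4, 5, 6}

    def test_single_cloud_warns_and_returns_smallest(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((400, 50))
        with pytest.warns(UserWarning, match="elbow"):
            scan = d.select_k(X, (2, 8), n_init=5, seed=0)
        assert scan.best_k == 2 and scan.flat

    def test_range_validation(self):
        X = np.random.default_rng(9).normal(size=(20, 2))
        with pytest.raises(ValueError):
            d.select_k(X, (1, 5))
        with pytest.raises(ValueError):
            d.select_k(X, (2, 25))


class TestOrderStates:
    def test_sorts_by_centroid_mean(self):
        model = d.StateModel(
            k=3,
            centroids=np.array([[0.7, 0.7], [0.1, 0.1], [0.4, 0.4]]),
            cost=0.0,
            labels=np.zeros(3, dtype=int),
            n_iter=1,
            n_init=1,
            seed=0,
        )
        ordered = d.order_states(model)
        # raw 1 (mean .1) -> rank 0, raw 2 (.4) -> rank 1, raw 0 (.7) -> rank 2
        np.testing.assert_array_equal(ordered.order, [2, 0, 1])

    def test_already_ascending_is_identity(self):
        model = d.StateModel(
            k=3,
            centroids=np.array([[0.1], [0.4], [0.7]]),
            cost=0.0,
            labels=np.zeros(3, dtype=int),
            n_iter=1,
            n_init=1,
            seed=0,
        )
        np.testing.assert_array_equal(d.order_states(model).order, [0, 1, 2])

    def test_tie_breaks_by_raw_index(self):
        model = d.StateModel(
            k=2,
            centroids=np.array([[0.5], [0.5]]),
            cost=0.0,
            labels=np.zeros(2, dtype=int),
            n_iter=1,
            n_init=1,
            seed=0,
        )
        np.testing.assert_array_equal(d.order_states(model).order, [0, 1])


class TestAssignWindows:
    @pytest.fixture()
    def ordered_model(self):
        model = d.StateModel(
            k=3,
            centroids=np.array([[4.0, 4.0], [0.0, 0.0], [2.0, 2.0]]),
            cost=0.0,
            labels=np.zeros(3, dtype=int),
            n_iter=1,
            n_init=1,
            seed=0,
        )
        return d.order_states(model)

    def test_centroid_maps_to_own_label(self, ordered_model):
        # raw order (4,0,2) -> ranks (2,0,1)
        labels = d.assign_windows(ordered_model, ordered_model.centroids)
        np.testing.assert_array_equal(labels, [2, 0, 1])

    def test_tie_goes_to_lower_ordered_label(self, ordered_model):
        # (1,1) is equidistant from centroids (0,0) [rank 0] and (2,2) [rank 1]
        labels = d.assign_windows(ordered_model, np.array([[1.0, 1.0]]))
        assert labels[0] == 0

    def test_matches_brute_force(self, ordered_model):
        rng = np.random.default_rng(10)
        X = rng.uniform(-1, 5, size=(50, 2))
        labels = d.assign_windows(ordered_model, X)
        rank_to_raw = np.argsort(ordered_model.order)
        brute = cdist(X, ordered_model.centroids[rank_to_raw], "cityblock").argmin(axis=1)
        np.testing.assert_array_equal(labels, brute)

    def test_dimension_mismatch_rejected(self, ordered_model):
        with pytest.raises(ValueError):
            d.assign_windows(ordered_model, np.zeros((3, 5)))


class TestFilterIncompleteSubjects:
    def test_subject_with_all_states_kept(self):
        kept, excl = d.filter_incomplete_subjects({"a": np.array([0, 1, 2, 1])}, 3)
        assert kept == ["a"] and excl == {}

    def test_subject_missing_a_state_excluded(self):
        kept, excl = d.filter_incomplete_subjects({"a": np.array([0, 2, 2])}, 3)
        assert kept == [] and excl == {"a": [0, 2]}

    def test_cohort_accounting(self):
        rng = np.random.default_rng(11)
        assignments = {}
        for i in range(150):
            if i < 34:  # only two of the three states
                assignments[f"s{i}"] = rng.integers(0, 2, size=215)
            else:
                labels = rng.integers(0, 3, size=215)
                labels[:3] = [0, 1, 2]
                assignments[f"s{i}"] = labels
        kept, excl = d.filter_incomplete_subjects(assignments, 3)
        assert len(kept) == 116 and len(excl) == 34
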