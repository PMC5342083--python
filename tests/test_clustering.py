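import numpy as np
import pytest
from sklearn.cluster import KMeans as SkKMeans
from sklearn.metrics import adjusted_rand_score

from agecurve import (
    ValidationError,
    abs_correlation_distance,
    clusters_from_labels,
    detect_age_position,
    find_conjunctions,
    kmeans_trends,
    label_inclinations,
    merge_redundant_clusters,
    standardize_trajectories,
)


GRID = np.arange(40.0, 81.0)


def hinge(grid, c, delta, baseline=0.0):
    hi = grid[-1]
    return baseline + np.where(grid <= c, 0.0, delta * (grid - c) / (hi - c))


class TestStandardize:
    def test_simple_example(self):
        np.testing.assert_allclose(
            standardize_trajectories(np.array([[1.0, 2.0, 3.0]])), [[-1.0, 0.0, 1.0]]
        )

    def test_constant_becomes_zero_and_idempotent(self):
        out = standardize_trajectories(np.full((2, 4), 3.3))
        np.testing.assert_allclose(out, 0.0)
        rng = np.random.default_rng(0)
        t = rng.normal(size=(5, 10))
        once = standardize_trajectories(t)
        np.testing.assert_allclose(standardize_trajectories(once), once, atol=1e-12)


class TestAbsCorrelationDistance:
    def test_mirror_and_self_distance_zero(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=12)
        d = abs_correlation_distance(np.vstack([t, -t, t]), np.vstack([t]))
        np.testing.assert_allclose(d[:, 0], 0.0, atol=1e-12)

    def test_range_zero_one(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(20, 15))
        d = abs_correlation_distance(A, A)
        assert d.min() >= -1e-12 and d.max() <= 1.0 + 1e-12


class TestKmeansTrends:
    def _two_shape_cohort(self, n_per=25, noise=0.05, seed=3):
        rng = np.random.default_rng(seed)
        up = hinge(GRID, 60, 1.0)
        down = -up
        traj = np.vstack(
            [up + rng.normal(0, noise, GRID.size) for _ in range(n_per)]
            + [down + rng.normal(0, noise, GRID.size) for _ in range(n_per)]
        )
        labels_true = np.array([0] * n_per + [1] * n_per)
        return standardize_trajectories(traj), labels_true

    def test_euclidean_separates_planted_shapes(self):
        traj, truth = self._two_shape_cohort()
        labels, centroids, _ = kmeans_trends(traj, 2, metric="euclidean", seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_euclidean_agrees_with_sklearn_on_separated_data(self):
        traj, truth = self._two_shape_cohort()
        labels, _, _ = kmeans_trends(traj, 2, metric="euclidean", seed=0)
        sk = SkKMeans(n_clusters=2, n_init=5, random_state=0).fit_predict(traj)
        assert adjusted_rand_score(labels, sk) == 1.0

    def test_abscorr_unites_mirrored_trends(self):
        rng = np.random.default_rng(4)
        t = np.sin(np.linspace(0, 3, GRID.size)) + rng.normal(0, 0.01, GRID.size)
        other = np.cos(np.linspace(0, 9, GRID.size))
        traj = np.vstack([t, -t, other])
        labels, _, _ = kmeans_trends(traj, 2, metric="abscorr", seed=0)
        assert labels[0] == labels[1]
        assert labels[2] != labels[0]

    def test_k_one_groups_everything(self):
        rng = np.random.default_rng(5)
        labels, _, _ = kmeans_trends(rng.normal(size=(7, 10)), 1, seed=0)
        assert set(labels) == {0}

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            kmeans_trends(np.random.default_rng(0).normal(size=(3, 5)), 4)

    def test_constant_trajectory_rejected_under_abscorr(self):
        traj = np.vstack([np.zeros(6), np.arange(6.0)])
        with pytest.raises(ValidationError, match="row 0"):
            kmeans_trends(traj, 2, metric="abscorr")

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        traj = rng.normal(size=(40, 20))
        out1 = kmeans_trends(traj, 5, seed=9)
        out2 = kmeans_trends(traj, 5, seed=9)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])


class TestMergeAndLabel:
    def _clusters(self, centroid_rows, sizes):
        traj = np.repeat(centroid_rows, sizes, axis=0)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        return clusters_from_labels(labels, traj), traj

    def test_identical_centroids_merged(self):
        base = np.linspace(0, 1, 10)
        clusters, traj = self._clusters(np.vstack([base, base]), [3, 2])
        merged = merge_redundant_clusters(clusters, traj, 0.9)
        assert len(merged) == 1 and merged[0].size == 5

    def test_opposite_trends_never_merged(self):
        base = np.linspace(0, 1, 10)
        noisy_mirror = -base + 0.01 * np.sin(np.arange(10))
        clusters, traj = self._clusters(np.vstack([base, noisy_mirror]), [3, 3])
        merged = merge_redundant_clusters(clusters, traj, 0.9)
        assert len(merged) == 2

    def test_singletons_dropped_others_intact(self):
        a = np.linspace(0, 1, 10)
        b = np.cos(np.linspace(0, 6, 10))
        clusters, traj = self._clusters(np.vstack([a, b]), [4, 1])
        merged = merge_redundant_clusters(clusters, traj, 0.99)
        assert len(merged) == 1 and merged[0].size == 4

    def test_inclination_labels(self):
        rising = np.linspace(-1, 1, 8)
        clusters, traj = self._clusters(np.vstack([rising, -rising]), [2, 2])
        labeled = label_inclinations(clusters)
        assert [c.inclination for c in labeled] == ["positive", "negative"]


class TestFindConjunctions:
    def test_crossing_lines_meet_at_midpoint(self):
        grid = np.arange(40.0, 81.0)
        diff = 2.0 * (grid - 60.0)
        crossings = find_conjunctions(diff, grid)
        assert len(crossings) == 1
        assert crossings[0][0] == pytest.approx(60.0)

    def test_interpolated_crossing(self):
        grid = np.array([0.0, 1.0])
        crossings = find_conjunctions(np.array([-1.0, 3.0]), grid)
        assert crossings[0][0] == pytest.approx(0.25)

    def test_divergence_after_zero_run(self):
        grid = np.arange(40.0, 81.0)
        diff = np.where(grid <= 65.0, 0.0, grid - 65.0)
        crossings = find_conjunctions(diff, grid)
        assert len(crossings) == 1
        assert crossings[0][0] == pytest.approx(65.0)

    def test_no_crossing_reported_empty(self):
        grid = np.arange(5.0)
        assert find_conjunctions(np.ones(5), grid) == []


class TestDetectAgePosition:
    def test_centered_opposite_lines_cross_at_grid_midpoint(self):
        grid = np.arange(40.0, 81.0)
        rng = np.random.default_rng(7)
        slopes = rng.uniform(0.5, 2.0, 10)
        traj = np.vstack(
            [s * (grid - 60.0) for s in slopes[:5]]
            + [-s * (grid - 60.0) for s in slopes[5:]]
        )
        pos = detect_age_position(traj, grid, k=3, seed=0)
        assert pos is not None
        assert pos.age == pytest.approx(60.0)
        assert pos.decade == 7

    def test_shared_baseline_hinges_conjoin_exactly_at_hinge(self):
        # uncentered opposite hinges share their pre-change plateau; the
        # conjunction (divergence) point is exactly the planted hinge age
        grid = np.arange(46.0, 90.0)
        up = 5.0 + np.where(grid <= 65, 0.0, 0.6 * (grid - 65) / (grid[-1] - 65))
        down = 10.0 - up
        traj = np.vstack([up, up, 10.0 - up, 10.0 - up])
        # give the detector the raw (uncentered) trajectories
        pos = detect_age_position(traj - traj.mean(), grid, k=2, seed=0)
        assert pos is not None
        assert pos.age == pytest.approx(65.0)

    def test_sign_invariance(self):
        grid = np.arange(40.0, 81.0)
        rng = np.random.default_rng(8)
        traj = np.vstack(
            [hinge(grid, 60, d) - hinge(grid, 60, d).mean() for d in rng.uniform(0.5, 1.5, 12)]
        )
        traj[::2] *= -1.0
        base = detect_age_position(traj, grid, k=3, seed=1)
        flipped = traj.copy()
        flipped[[1, 4, 7]] *= -1.0
        alt = detect_age_position(flipped, grid, k=3, seed=1)
        assert base is not None and alt is not None
        assert base.age == pytest.approx(alt.age, abs=1e-2)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(9)
        slopes = rng.uniform(0.5, 2.0, 8)
        for shift in (0.0, 7.0):
            grid = np.arange(40.0, 81.0) + shift
            mid = 60.0 + shift
            traj = np.vstack(
                [s * (grid - mid) for s in slopes[:4]]
                + [-s * (grid - mid) for s in slopes[4:]]
            )
            pos = detect_age_position(traj, grid, k=2, seed=0)
            assert pos.age == pytest.approx(mid)

    def test_single_inclination_yields_none(self):
        grid = np.arange(40.0, 81.0)
        traj = np.vstack([s * (grid - 60.0) for s in (0.5, 1.0, 1.5)])
        # all mutually positively correlated: one sign group only
        assert detect_age_position(traj, grid, k=2, seed=0) is None

    def test_quadratic_vertex_method(self):
        grid = np.arange(40.0, 81.0)
        para = ((grid - 62.0) / 20.0) ** 2
        traj = np.vstack([para - para.mean(), -(para - para.mean())] * 3)
        pos = detect_age_position(traj, grid, k=2, seed=0, method="quadratic-vertex")
        assert pos is not None
        assert pos.method == "quadratic-vertex"
        assert pos.age == pytest.approx(62.0, abs=1e-6)
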