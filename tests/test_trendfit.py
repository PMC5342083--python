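import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from agecurve import (
    AnalysisConfig,
    ValidationError,
    age_association_test,
    bh_adjust,
    filter_probes,
    fit_dataset,
    fit_quadratic,
    fold_change,
    sample_weights,
    simulate_dataset,
    smooth_trajectory,
    tabulate_directions,
    volcano_table,
)
from agecurve.synthetic import CohortSpec


def brute_bh(p):
    """Textbook step-up BH, coded independently of the package path."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFitQuadratic:
    def test_exact_model_recovered(self):
        ages = np.arange(40.0, 81.0)
        y = 2.0 + 0.1 * ages + 0.01 * ages**2
        w = np.linspace(0.2, 2.0, ages.size)
        a, b, g, resid = fit_quadratic(y, ages, weights=w)
        np.testing.assert_allclose([a, b, g], [2.0, 0.1, 0.01], atol=1e-8)
        np.testing.assert_allclose(resid, 0, atol=1e-8)

    def test_constant_y(self):
        ages = np.array([50.0, 55.0, 60.0, 65.0, 70.0])
        a, b, g, _ = fit_quadratic(np.full(5, 3.25), ages)
        np.testing.assert_allclose([a, b, g], [3.25, 0.0, 0.0], atol=1e-9)

    def test_four_points_against_normal_equations(self):
        ages = np.array([40.0, 50.0, 60.0, 70.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        w = np.array([1.0, 1.0, 1.0, 10.0])
        X = np.column_stack([np.ones(4), ages, ages**2])
        expected = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        a, b, g, _ = fit_quadratic(y, ages, weights=w)
        np.testing.assert_allclose([a, b, g], expected, rtol=1e-8)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_statsmodels_wls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        ages = rng.uniform(30, 90, n)
        while np.unique(ages).size < 3:
            ages = rng.uniform(30, 90, n)
        y = rng.normal(7, 1, n)
        w = rng.uniform(0.1, 3.0, n)
        X = sm.add_constant(np.column_stack([ages, ages**2]))
        oracle = sm.WLS(y, X, weights=w).fit().params
        a, b, g, _ = fit_quadratic(y, ages, weights=w)
        np.testing.assert_allclose([a, b, g], oracle, rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize(
        "y,ages",
        [
            (np.ones(4), np.array([50.0, 50.0, 60.0, 60.0])),  # 2 distinct ages
            (np.ones(3), np.array([50.0, 60.0, 70.0])),        # too few samples
            (np.array([1.0, np.nan, 2.0, 3.0, 4.0]), np.arange(50.0, 55.0)),
        ],
    )
    def test_invalid_inputs_rejected(self, y, ages):
        with pytest.raises(ValidationError):
            fit_quadratic(y, ages)


class TestSmoothTrajectory:
    def test_pure_square(self):
        assert smooth_trajectory(0, 0, 1, [3.0])[0] == 9.0

    def test_arithmetic_example(self):
        assert smooth_trajectory(2, 0.1, 0.01, [50.0])[0] == pytest.approx(32.0)

    def test_affine_when_gamma_zero(self):
        traj = smooth_trajectory(1.0, 2.0, 0.0, np.arange(40.0, 50.0))
        assert np.allclose(np.diff(traj, 2), 0.0)


class TestAgeAssociationTest:
    def test_noiseless_quadratic_gives_tiny_p(self):
        ages = np.linspace(40, 80, 50)
        y = 1.0 + 0.02 * ages + 0.003 * ages**2
        assert age_association_test(y, ages) < 1e-12

    def test_constant_y_gives_p_one(self):
        ages = np.linspace(40, 80, 20)
        assert age_association_test(np.full(20, 5.0), ages) == pytest.approx(1.0)

    def test_unweighted_null_pvalues_uniform(self):
        rng = np.random.default_rng(42)
        n, n_probes = 50, 1000
        ages = rng.uniform(40, 90, n)
        # direct null matrix; the simulator is exercised elsewhere
        Y = rng.normal(size=(n_probes, n))
        ps = np.array([age_association_test(Y[i], ages) for i in range(200)])
        ks = scipy.stats.kstest(ps, "uniform").statistic
        assert ks < 0.1  # 200 draws; crit(5%) ~ 0.096

    def test_weight_rescaling_leaves_p_unchanged(self):
        rng = np.random.default_rng(8)
        ages = rng.uniform(40, 90, 60)
        y = rng.normal(size=60) + 0.01 * ages
        w = 1.0 / np.maximum(1, rng.integers(1, 20, 60))
        p1 = age_association_test(y, ages, weights=w)
        p2 = age_association_test(y, ages, weights=17.3 * w)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            age_association_test(np.ones(4), np.arange(4.0) + 50)


class TestBHAdjust:
    def test_displayed_examples(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([0.005, 0.04]), [0.01, 0.04])
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_and_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 50))
        q = bh_adjust(p)
        np.testing.assert_allclose(q, brute_bh(p), atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


class TestFoldChange:
    def test_rising_endpoints(self):
        traj = np.array([7.0, 7.1, 7.263])
        fc, direction = fold_change(traj)
        assert direction == 1
        assert fc == pytest.approx(2**0.263, rel=1e-12)
        assert fc == pytest.approx(1.20, abs=0.005)

    def test_flat_trajectory(self):
        fc, direction = fold_change(np.full(5, 3.0))
        assert (fc, direction) == (1.0, 0)

    def test_falling_one_log2_unit(self):
        fc, direction = fold_change(np.array([8.0, 7.5, 7.0]))
        assert (fc, direction) == (-2.0, -1)

    def test_amplitude_mode_sees_symmetric_excursion(self):
        grid = np.linspace(40, 80, 41)
        traj = ((grid - 60) / 20) ** 2  # symmetric parabola, equal endpoints
        fc_end, d_end = fold_change(traj, mode="endpoints")
        fc_amp, _ = fold_change(traj, mode="amplitude")
        assert fc_end == pytest.approx(1.0)
        assert d_end == 0
        assert fc_amp == pytest.approx(2.0)


class TestFilterAndTabulate:
    def test_joint_filter_with_boundary_fc(self):
        table = pd.DataFrame(
            {
                "qvalue": [0.01, 0.01, 0.2, 0.04],
                "fold_change": [1.5, 1.1, 2.0, -1.2],
                "direction": [1, 1, 1, -1],
            },
            index=pd.Index(["a", "b", "c", "d"], name="probe_id"),
        )
        kept, summary = filter_probes(table, 0.05, 1.2)
        assert list(kept.index) == ["a", "d"]
        assert summary == {"n_total": 4, "n_pass_fdr": 3, "n_pass_fc": 3, "n_pass_both": 2}

    def test_empty_input(self):
        table = pd.DataFrame(columns=["qvalue", "fold_change", "direction"])
        kept, summary = filter_probes(table, 0.05, 1.2)
        assert len(kept) == 0 and summary["n_total"] == 0

    def test_tabulate_directions(self):
        table = pd.DataFrame({"direction": [1, 1, -1]})
        assert tabulate_directions(table) == {
            "positive": 2, "negative": 1, "zero": 0, "total": 3,
        }
        assert tabulate_directions(pd.DataFrame({"direction": []}))["total"] == 0

    def test_volcano_partition(self):
        table = pd.DataFrame(
            {
                "pvalue": [1e-6, 1e-6, 0.5],
                "qvalue": [0.01, 0.01, 0.9],
                "fold_change": [1.5, 1.05, 1.4],
            },
            index=pd.Index(["a", "b", "c"], name="probe_id"),
        )
        v = volcano_table(table)
        assert list(v["category"]) == ["fdr_fc", "fdr", "ns"]


class TestFitDataset:
    def test_agrees_with_single_probe_path(self):
        spec = CohortSpec(n_samples=80, n_probes=20, seed=4)
        ds, _ = simulate_dataset(spec, noise_sd=0.4)
        sw = sample_weights(ds.ages)
        res = fit_dataset(ds, weights=sw, config=AnalysisConfig(random_seed=4))
        for i in (0, 7, 19):
            a, b, g, _ = fit_quadratic(ds.values[i], ds.ages, weights=sw)
            row = res.table.iloc[i]
            np.testing.assert_allclose(
                [row["alpha"], row["beta"], row["gamma"]], [a, b, g], rtol=1e-9
            )

    def test_smoothed_rows_are_exact_quadratics(self):
        spec = CohortSpec(n_samples=60, n_probes=10, seed=5)
        ds, _ = simulate_dataset(spec, noise_sd=0.2)
        res = fit_dataset(ds)
        second_diff = np.diff(res.smoothed, n=2, axis=1)
        # second differences of a quadratic on a unit grid are constant
        assert np.allclose(second_diff, second_diff[:, :1], atol=1e-9)

    def test_qvalues_never_below_pvalues(self):
        spec = CohortSpec(n_samples=60, n_probes=50, seed=6)
        ds, _ = simulate_dataset(spec, noise_sd=0.5)
        res = fit_dataset(ds)
        assert (res.table["qvalue"] >= res.table["pvalue"] - 1e-12).all()
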