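import numpy as np
import pytest

from flowpops.anomaly import (
    build_gdataset,
    default_gamma,
    default_omega,
    delta_distance,
    detect_anomalies,
    local_density,
    pool_and_cluster,
    run_anomaly_pipeline,
    standardize,
)
from flowpops.data_io import FlowSample
from flowpops.mcl_merge import PopulationAssignment
from flowpops.synthetic import default_cohort_spec, gen_cohort

COLLINEAR = np.array([[0.0], [1.0], [2.0]])


def small_cohort(n_subjects=30, n_anomalous=0, seed=0, cells=100):
    spec = default_cohort_spec(n_subjects=n_subjects, n_anomalous=n_anomalous, seed=seed)
    spec.cells_per_subject = cells
    return gen_cohort(spec)


def make_assignment(labels):
    labels = np.asarray(labels)
    n = int(labels.max()) + 1
    return PopulationAssignment({i: i for i in range(n)}, labels, n)


class TestPoolAndCluster:
    def test_pooling_preserves_cells_and_provenance(self, rng):
        a = FlowSample("a", ["X", "Y"], rng.normal(size=(100, 2)), subject_id="a")
        b = FlowSample("b", ["X", "Y"], rng.normal(size=(100, 2)), subject_id="b")
        pooled, idx, _ = pool_and_cluster([a, b], seed=0)
        assert pooled.n_cells == 200
        np.testing.assert_array_equal(np.bincount(idx), [100, 100])

    def test_per_subject_cap_subsamples(self, rng):
        a = FlowSample("a", ["X"], rng.normal(size=(100, 1)))
        b = FlowSample("b", ["X"], rng.normal(size=(100, 1)))
        pooled, idx, _ = pool_and_cluster([a, b], per_subject_cap=50, seed=1)
        assert pooled.n_cells == 100
        np.testing.assert_array_equal(np.bincount(idx), [50, 50])

    def test_marker_mismatch_names_subject(self, rng):
        a = FlowSample("a", ["X", "Y"], rng.normal(size=(10, 2)))
        b = FlowSample("b", ["X", "Z"], rng.normal(size=(10, 2)), subject_id="odd-one")
        with pytest.raises(ValueError, match="odd-one"):
            pool_and_cluster([a, b], seed=0)


class TestBuildGdataset:
    def _tiny(self):
        # 2 subjects, 1 marker, 2 populations; hand-checkable
        values = np.array([[1.0], [2.0], [9.0], [4.0], [6.0], [5.0], [7.0]])
        pooled = FlowSample("pooled", ["X"], values)
        subject = np.array([0, 0, 0, 0, 1, 1, 1])
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        return pooled, subject, make_assignment(labels)

    def test_mfi_is_median_and_percentage_is_share(self):
        pooled, subject, asg = self._tiny()
        feats = build_gdataset(pooled, subject, asg)
        # subject 0, population 0: values {1,2,9} -> median 2; 3 of 4 cells -> 75%
        assert feats.features[0, 0] == 2.0
        assert feats.features[0, 1] == 75.0
        assert feats.features[0, 3] == 25.0

    def test_absent_subject_gets_pooled_mfi_and_zero_percent(self):
        values = np.array([[1.0], [3.0], [10.0], [20.0]])
        pooled = FlowSample("pooled", ["X"], values)
        subject = np.array([0, 0, 1, 1])
        labels = np.array([0, 0, 1, 1])  # subject 0 absent from population 1
        feats = build_gdataset(pooled, subject, make_assignment(labels))
        assert feats.features[0, 3] == 0.0  # percentage
        assert feats.features[0, 2] == 15.0  # pooled median of population 1

    def test_percentages_sum_to_100(self):
        pooled, subject, asg = self._tiny()
        feats = build_gdataset(pooled, subject, asg)
        pct = feats.features[:, feats.percentage_columns()]
        np.testing.assert_allclose(pct.sum(axis=1), 100.0, atol=1e-6)


class TestStandardize:
    def _wrap(self, x):
        from flowpops.anomaly import CohortFeatures

        x = np.asarray(x, dtype=float)
        return CohortFeatures(
            subject_ids=[f"s{i}" for i in range(x.shape[0])],
            features=np.asarray(x, dtype=float),
            marker_names=["X"],
            n_populations=x.shape[1] // 2,
        )

    def test_two_point_column_is_symmetric(self):
        z = standardize(self._wrap([[0.0, 1.0], [10.0, 1.0]]))
        col = z.features[:, 0]
        assert col[0] == -col[1] and col[1] > 0

    def test_constant_column_becomes_zero(self):
        z = standardize(self._wrap([[0.0, 1.0], [10.0, 1.0]]))
        np.testing.assert_array_equal(z.features[:, 1], 0.0)

    def test_columns_centered(self, rng):
        z = standardize(self._wrap(rng.normal(size=(20, 4))))
        np.testing.assert_allclose(z.features.mean(axis=0), 0.0, atol=1e-9)
        assert z.standardized


class TestLocalDensity:
    def test_omega_from_density_parameter(self):
        assert default_omega(0.15, 100) == 15
        assert default_omega(0.15, 3) == 1
        assert default_omega(0.9, 10) == 9  # capped at P-1

    def test_collinear_worked_example(self):
        rho, omega = local_density(COLLINEAR, omega=2)
        assert omega == 2
        np.testing.assert_allclose(rho, [0.4, 1.0, 0.4])

    def test_scaling_law(self, rng):
        x = rng.normal(size=(20, 3))
        rho1, _ = local_density(x, r=0.2)
        rho2, _ = local_density(3.0 * x, r=0.2)
        np.testing.assert_allclose(rho2, rho1 / 9.0, rtol=1e-12)

    def test_duplicate_points_get_sentinel(self):
        x = np.array([[0.0], [0.0], [5.0], [6.0]])
        rho, _ = local_density(x, omega=1)
        finite_max = rho[2:].max()
        assert rho[0] == rho[1] == 10 * max(finite_max, rho[0] / 10)
        assert np.isfinite(rho).all()


class TestDeltaDistance:
    def test_gamma_rarity_threshold(self):
        assert default_gamma(359) == 3
        assert default_gamma(99) == 1  # floored at 1

    def test_collinear_worked_example(self):
        rho = np.array([0.4, 1.0, 0.4])
        delta, psi = delta_distance(COLLINEAR, rho, gamma=1)
        # middle point is the global density peak: delta = max distance
        np.testing.assert_allclose(delta, [1.0, 1.0, 1.0])
        assert psi[1] == []
        assert psi[0] == [1] and psi[2] == [1]

    def test_gamma_one_reduces_to_classical_density_peak(self, rng):
        x = rng.normal(size=(25, 4))
        rho, _ = local_density(x, r=0.2)
        delta, _ = delta_distance(x, rho, gamma=1)
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        for i in range(25):
            higher = np.flatnonzero(rho > rho[i])
            expected = d[i].max() if higher.size == 0 else d[i, higher].min()
            assert delta[i] == pytest.approx(expected, rel=1e-12)

    def test_psi_neighbours_have_strictly_higher_density(self, rng):
        x = rng.normal(size=(40, 3))
        rho, _ = local_density(x, r=0.15)
        _, psi = delta_distance(x, rho, gamma=3)
        for i, members in enumerate(psi):
            assert all(rho[j] > rho[i] for j in members)
            assert len(members) <= 3


class TestDetectAnomalies:
    def test_single_extreme_value_flagged(self):
        rho = np.ones(5)
        delta = np.array([1.0, 1, 1, 1, 100.0])
        assert detect_anomalies(rho, delta) == {4}

    def test_equal_ratios_give_no_flags(self):
        assert detect_anomalies(np.ones(6), np.ones(6)) == set()

    def test_permutation_invariance(self, rng):
        rho = rng.uniform(0.5, 2.0, size=30)
        delta = rng.uniform(0.5, 2.0, size=30)
        delta[7] = 100.0
        base = detect_anomalies(rho, delta)
        perm = rng.permutation(30)
        flagged_perm = detect_anomalies(rho[perm], delta[perm])
        expected = {int(np.flatnonzero(perm == i)[0]) for i in base}
        assert flagged_perm == expected


class TestPipeline:
    def test_deterministic_given_seed(self):
        samples, _ = small_cohort(n_subjects=20, seed=4, cells=80)
        r1 = run_anomaly_pipeline(samples, seed=9)
        r2 = run_anomaly_pipeline(samples, seed=9)
        np.testing.assert_array_equal(r1.rho, r2.rho)
        np.testing.assert_array_equal(r1.delta, r2.delta)
        assert r1.flagged == r2.flagged
        assert r1.n_populations == r2.n_populations

    def test_recovers_template_population_count(self):
        samples, _ = small_cohort(n_subjects=30, seed=1, cells=150)
        report = run_anomaly_pipeline(samples, seed=1)
        assert report.n_populations == 3

    def test_injected_anomalies_attain_top_ratios_and_are_flagged(self):
        samples, truth = small_cohort(n_subjects=60, n_anomalous=2, seed=2, cells=150)
        report = run_anomaly_pipeline(samples, seed=2)
        top2 = set(np.argsort(report.ratios)[-2:].tolist())
        assert top2 == truth
        assert truth <= report.flagged

    @pytest.mark.parametrize("seed", [0, 1])
    def test_clean_cohort_flags_stay_at_fringe_level(self, seed):
        """Without injected anomalies the chi-square screen may flag a few
        fringe subjects (the test level is an uncorrected alpha=0.05), but it
        must not cascade: flags stay within a small fraction of the cohort."""
        samples, _ = small_cohort(n_subjects=50, n_anomalous=0, seed=seed, cells=100)
        report = run_anomaly_pipeline(samples, seed=seed)
        assert len(report.flagged) <= 5

    def test_requires_three_subjects(self, rng):
        a = FlowSample("a", ["X"], rng.normal(size=(10, 1)))
        with pytest.raises(ValueError):
            run_anomaly_pipeline([a, a], seed=0)
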