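import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from flowpops.data_io import FlowSample
from flowpops.fuzzy_cluster import (
    _memberships_from_distances,
    fcm_fit,
    hard_assign,
    mahalanobis,
    regularize_covariance,
)

from conftest import make_blobs


class TestMahalanobis:
    def test_identity_covariance_is_euclidean(self):
        assert mahalanobis([3, 4], [0, 0], np.eye(2)) == pytest.approx(5.0)

    def test_axis_aligned_closed_form(self):
        assert mahalanobis([2, 0], [0, 0], np.diag([4.0, 1.0])) == pytest.approx(1.0)

    def test_zero_at_center(self):
        assert mahalanobis([1.5, -2], [1.5, -2], np.diag([4.0, 1.0])) == 0.0

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError, match="symmetric"):
            mahalanobis([1, 0], [0, 0], np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_identity_matches_euclidean_on_random_pairs(self, rng):
        x = rng.normal(size=(1000, 4))
        mu = rng.normal(size=(1000, 4))
        eye = np.eye(4)
        d_m = np.array([mahalanobis(a, b, eye) for a, b in zip(x, mu)])
        d_e = np.linalg.norm(x - mu, axis=1)
        np.testing.assert_allclose(d_m, d_e, atol=1e-12)


class TestRegularizeCovariance:
    def test_well_conditioned_nearly_unchanged(self, rng):
        a = rng.normal(size=(200, 3))
        s = np.cov(a, rowvar=False)
        out = regularize_covariance(s, n_points=200)
        rel = np.linalg.norm(out - s) / np.linalg.norm(s)
        assert rel < 1e-5

    def test_rank_deficient_becomes_invertible(self):
        pts = np.array([[0.0, 0, 0], [1.0, 1, 1]])
        s = np.cov(pts, rowvar=False)
        out = regularize_covariance(s, n_points=2)
        np.linalg.cholesky(out)  # raises if not SPD

    def test_zero_matrix_becomes_scaled_identity(self):
        out = regularize_covariance(np.zeros((3, 3)), n_points=100)
        np.testing.assert_allclose(out, 1e-6 * np.eye(3))


class TestMembershipUpdate:
    def test_rows_sum_to_one(self, rng):
        d = rng.uniform(0.1, 5.0, size=(30, 4))
        u = _memberships_from_distances(d, m=2.0)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_distance_gets_full_membership(self):
        d = np.array([[0.0, 3.0], [2.0, 2.0]])
        u = _memberships_from_distances(d, m=2.0)
        np.testing.assert_allclose(u[0], [1.0, 0.0])
        np.testing.assert_allclose(u[1], [0.5, 0.5])

    def test_two_coincident_centers_split_equally(self):
        d = np.array([[0.0, 0.0, 1.0]])
        u = _memberships_from_distances(d, m=2.0)
        np.testing.assert_allclose(u[0], [0.5, 0.5, 0.0])


class TestFcmFit:
    def test_k1_returns_column_mean_and_unit_membership(self, small_sample):
        model = fcm_fit(small_sample, K=1)
        np.testing.assert_allclose(model.centers[0], small_sample.values.mean(axis=0))
        np.testing.assert_allclose(model.memberships, 1.0)

    @pytest.mark.parametrize("mode", ["euclidean", "mahalanobis"])
    def test_two_blobs_recovered_with_high_membership(self, two_blob_sample, mode):
        sample, labels = two_blob_sample
        model = fcm_fit(sample, K=2, distance_mode=mode, seed=0)
        u = model.memberships
        # map generator populations to fitted clusters via the centers
        order = np.argsort(model.centers[:, 0])
        gen_cluster = order[labels]  # label 0 -> low-x center
        own = u[np.arange(len(labels)), gen_cluster]
        assert np.mean(own > 0.9) > 0.99

    def test_membership_rows_sum_to_one_at_every_iteration(self, two_blob_sample):
        sample, _ = two_blob_sample
        for n_iter in (1, 2, 3, 5, 8):
            model = fcm_fit(sample, K=3, seed=1, max_iter=n_iter, tol=0.0)
            np.testing.assert_allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_euclidean_objective_non_increasing(self, rng):
        x = FlowSample("r", ["A", "B", "C"], rng.normal(size=(300, 3)))
        model = fcm_fit(x, K=4, distance_mode="euclidean", seed=5)
        trace = np.array(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * trace[:-1])

    def test_euclidean_mode_matches_reference_fcm(self, rng):
        """Same k-means++ init, standard FCM updates implemented independently."""
        x = rng.normal(size=(50, 2))
        x[25:] += 6.0
        sample = FlowSample("o", ["A", "B"], x)
        K, m, seed = 2, 2.0, 42

        centers, _ = kmeans_plusplus(x, n_clusters=K, random_state=seed)
        u = None
        for _ in range(200):
            d = np.maximum(cdist(x, centers), 1e-12)
            u_new = 1.0 / ((d[:, :, None] / d[:, None, :]) ** (2 / (m - 1))).sum(axis=2)
            w = u_new**m
            centers = (w.T @ x) / w.sum(axis=0)[:, None]
            if u is not None and np.abs(u_new - u).max() < 1e-7:
                break
            u = u_new

        model = fcm_fit(sample, K=K, m=m, distance_mode="euclidean", seed=seed,
                        tol=1e-7, max_iter=200)
        # clusters may come out in either order
        diff = min(
            np.abs(model.centers - centers).max(),
            np.abs(model.centers[::-1] - centers).max(),
        )
        assert diff < 1e-4

    def test_k_larger_than_n_rejected(self, small_sample):
        with pytest.raises(ValueError):
            fcm_fit(small_sample, K=1000)

    def test_covariances_positive_definite(self, two_blob_sample):
        model = fcm_fit(two_blob_sample[0], K=2, seed=0)
        for s in model.covariances:
            np.testing.assert_allclose(s, s.T, atol=1e-9)
            assert np.linalg.eigvalsh(s).min() > 0


class TestHardAssign:
    def test_argmax_and_tie_to_lowest_index(self, small_sample):
        model = fcm_fit(small_sample, K=1)
        model.memberships = np.array([[0.2, 0.7, 0.1], [0.5, 0.5, 0.0]])
        labels = hard_assign(model)
        np.testing.assert_array_equal(labels, [1, 0])

    def test_length_matches_cells(self, two_blob_sample):
        sample, _ = two_blob_sample
        model = fcm_fit(sample, K=2, seed=0)
        assert hard_assign(model).shape == (sample.n_cells,)
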