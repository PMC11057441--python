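"""The four one-class detectors: scores, thresholds, calibration."""

import warnings

import numpy as np
import pytest

from dtboundary import (
    KMeansDetector,
    KnnDetector,
    MogDetector,
    SvddDetector,
    load_model,
    make_detector,
    save_model,
)
from dtboundary._qp import random_feasible, solve_svdd_dual, svdd_dual_objective


def brute_knn_score(X_train, x, k):
    """Exhaustive-search oracle for the KNN distance-ratio score."""

    def kth_dist_and_point(p, exclude_self):
        d = np.linalg.norm(X_train - p, axis=1)
        order = np.argsort(d, kind="stable")
        if exclude_self and d[order[0]] == 0.0:
            order = order[1:]
        idx = order[k - 1]
        return d[idx], idx

    member = any(np.array_equal(row, x) for row in X_train)
    num, q_idx = kth_dist_and_point(x, member)
    den, _ = kth_dist_and_point(X_train[q_idx], True)
    if den == 0.0:
        return np.inf if num > 0 else 0.0
    return num / den


class TestKnn:
    def setup_method(self):
        self.model = KnnDetector(k=1).fit(np.array([[0.0], [1.0]]))

    def test_hand_geometry_inside(self):
        # x=0.4: nearest neighbor 0 at distance 0.4; its own NN distance 1
        assert self.model.score([0.4]) == pytest.approx(0.4)
        assert not self.model.classify([[0.4]])[0]  # accept at t=1

    def test_hand_geometry_outside(self):
        assert self.model.score([2.5]) == pytest.approx(1.5)
        assert self.model.classify([[2.5]])[0]

    def test_training_point_excludes_itself(self):
        # numerator uses the nearest *other* point
        assert self.model.score([0.0]) == pytest.approx(1.0)

    def test_native_threshold_is_acceptance_rule(self):
        assert self.model.threshold_ == 1.0

    def test_k_must_be_smaller_than_n(self):
        with pytest.raises(ValueError):
            KnnDetector(k=2).fit(np.array([[0.0], [1.0]]))

    @pytest.mark.parametrize("dim", [1, 2])
    def test_matches_exhaustive_search_oracle(self, dim):
        rng = np.random.default_rng(dim)
        for _ in range(50):
            n = int(rng.integers(5, 25))
            k = int(rng.integers(1, min(n - 1, 6)))
            X = rng.standard_normal((n, dim))
            queries = np.vstack([rng.standard_normal((3, dim)), X[:2]])
            model = KnnDetector(k=k).fit(X)
            got = model.score_samples(queries)
            expected = [brute_knn_score(X, q, k) for q in queries]
            np.testing.assert_allclose(got, expected, rtol=1e-10)


class TestMog:
    def test_single_component_matches_gaussian_closed_form(self, rng):
        X = rng.standard_normal((400, 1))
        model = MogDetector(n_components=1, seed=0).fit(X)
        mu = float(model.means_[0, 0])
        var = float(model.covariances_[0, 0, 0])
        expected = 1.0 / np.sqrt(2.0 * np.pi * var)
        assert model.density([[mu]])[0] == pytest.approx(expected, rel=1e-6)
        # with unit-variance data the peak density is near 1/sqrt(2*pi)
        assert model.density([[mu]])[0] == pytest.approx(0.39894, rel=0.1)

    def test_duplicated_training_set_gives_identical_density(self, rng):
        X = rng.standard_normal((150, 2))
        a = MogDetector(n_components=2, seed=1).fit(X)
        b = MogDetector(n_components=2, seed=1).fit(np.vstack([X, X]))
        q = rng.standard_normal((20, 2))
        np.testing.assert_allclose(a.density(q), b.density(q), rtol=1e-3)

    def test_density_integrates_to_one(self, rng):
        """Monte-Carlo integral over a wide box is ~1 (proper density)."""
        X = rng.standard_normal((300, 2))
        model = MogDetector(n_components=3, seed=2).fit(X)
        lo, hi = -8.0, 8.0
        samples = rng.uniform(lo, hi, size=(1_000_000, 2))
        integral = model.density(samples).mean() * (hi - lo) ** 2
        assert integral == pytest.approx(1.0, abs=0.02)

    def test_bit_reproducible_given_seed(self, rng):
        X = rng.standard_normal((120, 3))
        a = MogDetector(n_components=2, seed=5).fit(X)
        b = MogDetector(n_components=2, seed=5).fit(X)
        np.testing.assert_array_equal(a.train_scores_, b.train_scores_)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            MogDetector(n_components=5).fit(np.zeros((10, 3)))


class TestKMeans:
    def test_single_centroid_is_mean(self, rng):
        X = rng.standard_normal((100, 2))
        model = KMeansDetector(n_clusters=1, seed=0).fit(X)
        np.testing.assert_allclose(model.centroids_[0], X.mean(axis=0), atol=1e-8)
        assert model.score(X.mean(axis=0)) == pytest.approx(0.0, abs=1e-8)

    def test_two_separated_blobs_recovered(self, rng):
        blob1 = rng.normal(0.0, 0.1, size=(500, 2))
        blob2 = rng.normal(5.0, 0.1, size=(500, 2))
        model = KMeansDetector(n_clusters=2, seed=0).fit(np.vstack([blob1, blob2]))
        centers = model.centroids_[np.argsort(model.centroids_[:, 0])]
        assert np.linalg.norm(centers[0] - blob1.mean(axis=0)) < 0.05
        assert np.linalg.norm(centers[1] - blob2.mean(axis=0)) < 0.05

    def test_score_is_distance_to_nearest_centroid(self):
        model = KMeansDetector(n_clusters=2, seed=0)
        model.centroids_ = np.array([[0.0], [10.0]])
        assert model.score([4.0]) == pytest.approx(4.0)

    def test_reproducible_given_seed(self, rng):
        X = rng.standard_normal((200, 3))
        a = KMeansDetector(n_clusters=4, seed=9).fit(X)
        b = KMeansDetector(n_clusters=4, seed=9).fit(X)
        np.testing.assert_array_equal(a.centroids_, b.centroids_)


class TestSvdd:
    def test_single_point_zero_radius(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SvddDetector(C=1.0, sigma=1.0).fit(np.array([[0.5]]))
        assert model.alpha_[0] == pytest.approx(1.0)
        assert model.r_squared_ == pytest.approx(0.0, abs=1e-12)
        assert model.score([0.5]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sep,sigma", [(1.0, 1.0), (2.0, 1.5), (0.3, 0.7)])
    def test_two_point_closed_form(self, sep, sigma):
        # symmetric solution a = (1/2, 1/2), R^2 = (1 - kappa)/2
        model = SvddDetector(C=1.0, sigma=sigma).fit(np.array([[0.0], [sep]]))
        kappa = np.exp(-(sep ** 2) / sigma ** 2)
        np.testing.assert_allclose(model.alpha_, [0.5, 0.5], atol=1e-8)
        assert model.r_squared_ == pytest.approx(0.5 * (1.0 - kappa), abs=1e-8)

    def test_dual_dominates_random_feasible_points(self, rng):
        """QP oracle: no random feasible multiplier vector beats the SMO
        solution (up to 1e-6)."""
        for n in (5, 12, 20):
            X = rng.standard_normal((n, 3))
            model = SvddDetector(C=0.3, sigma=2.0).fit(X)
            K = model._kernel(X, X)
            best = svdd_dual_objective(model.alpha_, K)
            for a in random_feasible(n, 0.3, 2000, rng):
                assert best >= svdd_dual_objective(a, K) - 1e-6

    def test_multipliers_sum_to_one_in_box(self, rng):
        X = rng.standard_normal((60, 4))
        model = SvddDetector(C=0.05, sigma=1.0).fit(X)
        assert model.alpha_.sum() == pytest.approx(1.0, abs=1e-8)
        assert model.alpha_.min() >= -1e-12
        assert model.alpha_.max() <= 0.05 + 1e-12

    def test_score_plus_r2_bounded_by_kernel(self, rng):
        # squared kernel distance to the center lies in [0, 2] for RBF
        X = rng.standard_normal((40, 2))
        model = SvddDetector(C=1.0, sigma=1.0).fit(X)
        q = rng.standard_normal((200, 2)) * 3
        vals = model.score_samples(q) + model.r_squared_
        assert np.all(vals >= -1e-10) and np.all(vals <= 2.0 + 1e-10)

    def test_infeasible_C_rejected(self):
        with pytest.raises(ValueError):
            SvddDetector(C=0.05, sigma=1.0).fit(np.zeros((10, 1)))

    def test_solver_requires_feasible_C(self):
        with pytest.raises(ValueError):
            solve_svdd_dual(np.eye(4), C=0.1)


class TestCalibration:
    def test_one_in_ten_scores_above_threshold(self):
        model = KMeansDetector(n_clusters=1, seed=0)
        model.train_scores_ = np.arange(1.0, 11.0)
        model.calibrate(0.1)
        assert (model.train_scores_ > model.threshold_).sum() == 1

    def test_median_at_half(self):
        model = KMeansDetector(n_clusters=1, seed=0)
        model.train_scores_ = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        model.calibrate(0.5)
        assert model.threshold_ == pytest.approx(3.0)

    def test_training_rejection_near_theta(self, rng):
        X = rng.standard_normal((2000, 3))
        for model in (KnnDetector(5), KMeansDetector(8, seed=0)):
            model.fit(X).calibrate(0.1)
            rate = (model.train_scores_ > model.threshold_).mean()
            assert rate == pytest.approx(0.1, abs=0.01)

    def test_held_out_rejection_converges_to_theta(self, rng):
        """Fresh draws from the training distribution are rejected at ~theta."""
        X = rng.standard_normal((20_000, 2))
        model = KMeansDetector(10, seed=0).fit(X[:10_000]).calibrate(0.1)
        rate = model.classify(X[10_000:]).mean()
        assert rate == pytest.approx(0.1, abs=0.02)

    def test_boundary_score_accepts(self):
        model = KMeansDetector(n_clusters=1, seed=0)
        model.centroids_ = np.array([[0.0]])
        model.threshold_ = 2.0
        assert not model.classify([[2.0]])[0]  # score == t -> inside
        assert model.classify([[2.1]])[0]

    def test_theta_range_checked(self):
        model = KnnDetector(1).fit(np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError):
            model.calibrate(1.5)


class TestSerialization:
    @pytest.mark.parametrize("method,param", [
        ("knn", 2), ("mog", 2), ("kmeans", 3), ("svdd", 0.0),
    ])
    def test_roundtrip_preserves_scores(self, tmp_path, rng, method, param):
        X = rng.standard_normal((80, 2))
        model = make_detector(method, param, seed=0)
        model.fit(X).calibrate(0.1)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        q = rng.standard_normal((25, 2))
        np.testing.assert_allclose(
            loaded.score_samples(q), model.score_samples(q), rtol=1e-10
        )
        assert loaded.threshold_ == model.threshold_

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            make_detector("isolation_forest", 1)
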