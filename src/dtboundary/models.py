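"""Four one-class (novelty detection) models over a shared interface.

Each detector is trained on healthy-control data only and reduced to a
continuous anomaly score — higher means more anomalous — plus a threshold.
A point is classified *outside* (abnormal) iff score > threshold. Thresholds
are calibrated uniformly across methods to a target false rejection rate
theta: the threshold is the empirical (1 - theta) quantile of the training
scores, so a theta fraction of the training normals is deliberately placed
outside the boundary.

Methods
-------
KNN      distance-ratio score ||x - NN_k(x)|| / ||NN_k(x) - NN_k(NN_k(x))||,
         where NN_k(p) is the single k-th nearest training point (a training
         point excludes itself). The classical acceptance rule "accept iff
         ratio <= 1" is recovered at threshold 1 (the native default).
MoG      Gaussian mixture density fitted by EM; score = -log density.
KMEANS   k centroids from Lloyd's algorithm; score = distance to the
         nearest centroid.
SVDD     support vector data description: minimum hypersphere around the
         data in RBF feature space, K(x, y) = exp(-||x-y||^2 / sigma^2);
         score = squared kernel distance to the center minus R^2, so the
         native threshold is 0.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from ._qp import solve_svdd_dual

METHODS = ("knn", "mog", "kmeans", "svdd")

SERIALIZATION_VERSION = 1


class NoveltyDetector:
    """Base class: fit on normal data, score, calibrate, classify."""

    method: str = ""

    def __init__(self) -> None:
        self.threshold_: float | None = None
        self.theta_: float | None = None
        self.train_scores_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "NoveltyDetector":
        raise NotImplementedError

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Anomaly score per row; higher = more anomalous."""
        raise NotImplementedError

    def score(self, x: np.ndarray) -> float:
        return float(self.score_samples(np.atleast_2d(x))[0])

    def calibrate(self, theta: float) -> "NoveltyDetector":
        """Set the threshold to the (1 - theta) quantile of training scores.

        theta is the target false rejection rate: the fraction of training
        normals placed outside the boundary (within 1/n_train).
        """
        if not 0 < theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.train_scores_ is None:
            raise RuntimeError("fit the model before calibrating")
        finite = self.train_scores_[np.isfinite(self.train_scores_)]
        self.threshold_ = float(np.quantile(finite, 1.0 - theta, method="linear"))
        self.theta_ = float(theta)
        return self

    def classify(self, X: np.ndarray) -> np.ndarray:
        """Boolean per row: True = outside (abnormal). Boundary accepts:
        score == threshold is inside."""
        if self.threshold_ is None:
            raise RuntimeError("no threshold set; call calibrate() first")
        return self.score_samples(np.atleast_2d(X)) > self.threshold_

    def _check_fitted(self) -> None:
        if self.train_scores_ is None:
            raise RuntimeError("model is not fitted")


class KnnDetector(NoveltyDetector):
    """k-th-nearest-neighbor distance-ratio detector."""

    method = "knn"

    def __init__(self, k: int = 1) -> None:
        super().__init__()
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = int(k)

    def fit(self, X: np.ndarray) -> "KnnDetector":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.k >= X.shape[0]:
            raise ValueError(f"k={self.k} must be < n_train={X.shape[0]}")
        self.X_train_ = X
        self._nn = NearestNeighbors(n_neighbors=min(self.k + 2, X.shape[0]))
        self._nn.fit(X)
        # k-th NN distance of each training point, self excluded
        d, idx = self._nn.kneighbors(X)
        self._train_knn_dist = d[:, self.k]
        self._train_knn_idx = idx[:, self.k]
        self.train_scores_ = self.score_samples(X)
        self.threshold_ = 1.0  # native acceptance rule: ratio <= 1
        return self

    def _kth_neighbor(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distance to, and index of, the k-th nearest training point;
        a query coinciding with a training point skips itself (one
        zero-distance hit)."""
        d, idx = self._nn.kneighbors(X)
        is_member = d[:, 0] == 0.0
        col = np.where(is_member, self.k, self.k - 1)
        rows = np.arange(X.shape[0])
        return d[rows, col], idx[rows, col]

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "X_train_"):
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        num, nn_idx = self._kth_neighbor(X)
        den = self._train_knn_dist[nn_idx]
        out = np.empty(X.shape[0])
        zero = den == 0.0
        out[~zero] = num[~zero] / den[~zero]
        out[zero] = np.where(num[zero] > 0, np.inf, 0.0)
        return out


class MogDetector(NoveltyDetector):
    """Gaussian-mixture density detector; score = -log P_MoG(x).

    The density is sum_j a_j N(x; mu_j, Sigma_j) with sum a_j = 1 and full
    covariances, fitted by EM with a ridge of 1e-6 * trace(cov)/d added to
    each covariance diagonal for conditioning.
    """

    method = "mog"

    def __init__(self, n_components: int = 2, seed: int = 0,
                 max_iter: int = 500, tol: float = 1e-7) -> None:
        super().__init__()
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = int(n_components)
        self.seed = int(seed)
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: np.ndarray) -> "MogDetector":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, d = X.shape
        if n <= self.n_components * (d + 1):
            raise ValueError(
                f"n_train={n} too small for N={self.n_components} components in "
                f"{d} dimensions (need n > N*(d+1))"
            )
        self.X_train_ = X
        tr = np.trace(np.atleast_2d(np.cov(X, rowvar=False)))
        reg = max(1e-6 * tr / d, 1e-12)
        self._gmm = GaussianMixture(
            n_components=self.n_components,
            covariance_type="full",
            reg_covar=reg,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._gmm.fit(X)
        if not self._gmm.converged_:
            warnings.warn("EM did not converge; using best iterate", stacklevel=2)
        self.train_scores_ = self.score_samples(X)
        return self

    @property
    def weights_(self) -> np.ndarray:
        return self._gmm.weights_

    @property
    def means_(self) -> np.ndarray:
        return self._gmm.means_

    @property
    def covariances_(self) -> np.ndarray:
        return self._gmm.covariances_

    def density(self, X: np.ndarray) -> np.ndarray:
        """Mixture probability density per row."""
        return np.exp(self._gmm.score_samples(np.atleast_2d(X)))

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return -self._gmm.score_samples(np.atleast_2d(np.asarray(X, dtype=float)))


class KMeansDetector(NoveltyDetector):
    """k-means prototype detector; score = Euclidean distance to the
    nearest centroid. Lloyd iterations from k-means++, best of 10 restarts."""

    method = "kmeans"

    def __init__(self, n_clusters: int = 5, seed: int = 0) -> None:
        super().__init__()
        if n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        self.n_clusters = int(n_clusters)
        self.seed = int(seed)

    def fit(self, X: np.ndarray) -> "KMeansDetector":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.n_clusters > X.shape[0]:
            raise ValueError("n_clusters must be <= n_train")
        self.X_train_ = X
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=10,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km.fit(X)
        self.centroids_ = km.cluster_centers_
        self.train_scores_ = self.score_samples(X)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = (
            (X ** 2).sum(axis=1)[:, None]
            - 2.0 * X @ self.centroids_.T
            + (self.centroids_ ** 2).sum(axis=1)[None, :]
        )
        return np.sqrt(np.clip(d2.min(axis=1), 0.0, None))


class SvddDetector(NoveltyDetector):
    """Support vector data description with an RBF kernel.

    The dual  max  sum_i a_i K_ii - a'Ka  s.t.  sum a = 1, 0 <= a_i <= C
    is solved by pairwise coordinate (SMO) updates. The squared radius is
    R^2 = 1 - 2 sum_i a_i K(x_i, x_s) + sum_ij a_i a_j K(x_i, x_j) averaged
    over the unbounded support vectors x_s (0 < a_s < C); with no unbounded
    SV the multiplier max is used with a warning. score(x) is the squared
    kernel distance of x to the sphere center minus R^2; the native
    threshold is therefore 0, but it may be re-calibrated like any other
    method.
    """

    method = "svdd"

    #: tolerance band for "unbounded" support vectors
    EPS_SV = 1e-7

    def __init__(self, C: float = 1.0, sigma: float = 1.0) -> None:
        super().__init__()
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.C = float(C)
        self.sigma = float(sigma)

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        d2 = (
            (A ** 2).sum(axis=1)[:, None]
            - 2.0 * A @ B.T
            + (B ** 2).sum(axis=1)[None, :]
        )
        return np.exp(-np.clip(d2, 0.0, None) / self.sigma ** 2)

    def fit(self, X: np.ndarray) -> "SvddDetector":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if self.C < 1.0 / n:
            raise ValueError(f"C={self.C} must be >= 1/n_train = {1.0 / n}")
        self.X_train_ = X
        K = self._kernel(X, X)
        self.alpha_ = solve_svdd_dual(K, self.C)
        self._aKa = float(self.alpha_ @ K @ self.alpha_)

        sv = (self.alpha_ > self.EPS_SV) & (self.alpha_ < self.C - self.EPS_SV)
        if not sv.any():
            warnings.warn(
                "no unbounded support vector; using max-multiplier point",
                stacklevel=2,
            )
            sv = self.alpha_ == self.alpha_.max()
        # R^2 = 1 - 2 K(X, x_s)'a + a'Ka, averaged over unbounded SVs
        r2 = 1.0 - 2.0 * (K[sv] @ self.alpha_) + self._aKa
        self.r_squared_ = float(r2.mean())
        self.train_scores_ = self.score_samples(X)
        self.threshold_ = 0.0  # native rule: outside the sphere
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Kx = self._kernel(X, self.X_train_)
        return 1.0 - 2.0 * Kx @ self.alpha_ + self._aKa - self.r_squared_


def make_detector(method: str, param: float, seed: int = 0,
                  C: float = 1.0, sigma_as_exponent: bool = True) -> NoveltyDetector:
    """Construct a detector from its method name and scalar hyperparameter.

    param means: k (knn), number of components (mog), number of centroids
    (kmeans), or the kernel-width grid value g for SVDD — interpreted as a
    base-10 exponent (sigma = 10^g) unless ``sigma_as_exponent`` is False.
    """
    method = method.lower()
    if method == "knn":
        return KnnDetector(k=int(param))
    if method == "mog":
        return MogDetector(n_components=int(param), seed=seed)
    if method == "kmeans":
        return KMeansDetector(n_clusters=int(param), seed=seed)
    if method == "svdd":
        sigma = float(10.0 ** param) if sigma_as_exponent else float(param)
        return SvddDetector(C=C, sigma=sigma)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def default_grid(method: str, desk_scale: bool = True) -> list[float]:
    """Hyperparameter grids: k 1..40 (KNN), N 1..15 (MoG), k 1..150
    (KMEANS), kernel exponent g in -1.5..1.5 (SVDD; step 0.05 at desk scale,
    0.01 for the fine grid)."""
    method = method.lower()
    if method == "knn":
        return list(range(1, 41))
    if method == "mog":
        return list(range(1, 16))
    if method == "kmeans":
        return list(range(1, 151))
    if method == "svdd":
        step = 0.05 if desk_scale else 0.01
        return [round(g, 4) for g in np.arange(-1.5, 1.5 + step / 2, step)]
    raise ValueError(f"unknown method {method!r}")


def save_model(model: NoveltyDetector, path: str | Path) -> None:
    """Serialize a fitted detector to a versioned JSON document."""
    doc: dict = {
        "version": SERIALIZATION_VERSION,
        "method": model.method,
        "threshold": model.threshold_,
        "theta": model.theta_,
        "train_scores": np.asarray(model.train_scores_).tolist(),
    }
    if isinstance(model, KnnDetector):
        doc["params"] = {"k": model.k}
        doc["X_train"] = model.X_train_.tolist()
    elif isinstance(model, MogDetector):
        doc["params"] = {"n_components": model.n_components, "seed": model.seed}
        doc["weights"] = model.weights_.tolist()
        doc["means"] = model.means_.tolist()
        doc["covariances"] = model.covariances_.tolist()
    elif isinstance(model, KMeansDetector):
        doc["params"] = {"n_clusters": model.n_clusters, "seed": model.seed}
        doc["centroids"] = model.centroids_.tolist()
    elif isinstance(model, SvddDetector):
        doc["params"] = {"C": model.C, "sigma": model.sigma}
        doc["X_train"] = model.X_train_.tolist()
        doc["alpha"] = model.alpha_.tolist()
        doc["r_squared"] = model.r_squared_
    else:  # pragma: no cover
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> NoveltyDetector:
    """Load a detector serialized by :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported serialization version {doc.get('version')}")
    method = doc["method"]
    if method == "knn":
        model = KnnDetector(**doc["params"])
        model.fit(np.asarray(doc["X_train"]))
    elif method == "mog":
        model = MogDetector(**doc["params"])
        gmm = GaussianMixture(
            n_components=model.n_components, covariance_type="full"
        )
        gmm.weights_ = np.asarray(doc["weights"])
        gmm.means_ = np.asarray(doc["means"])
        gmm.covariances_ = np.asarray(doc["covariances"])
        gmm.precisions_cholesky_ = _precisions_cholesky(gmm.covariances_)
        model._gmm = gmm
    elif method == "kmeans":
        model = KMeansDetector(**doc["params"])
        model.centroids_ = np.asarray(doc["centroids"])
    elif method == "svdd":
        model = SvddDetector(**doc["params"])
        model.X_train_ = np.asarray(doc["X_train"])
        model.alpha_ = np.asarray(doc["alpha"])
        K = model._kernel(model.X_train_, model.X_train_)
        model._aKa = float(model.alpha_ @ K @ model.alpha_)
        model.r_squared_ = float(doc["r_squared"])
    else:
        raise ValueError(f"unknown method {method!r}")
    model.train_scores_ = np.asarray(doc["train_scores"])
    model.threshold_ = doc["threshold"]
    model.theta_ = doc["theta"]
    return model


def _precisions_cholesky(covariances: np.ndarray) -> np.ndarray:
    from scipy import linalg

    out = np.empty_like(covariances)
    for j, cov in enumerate(covariances):
        chol = linalg.cholesky(cov, lower=True)
        out[j] = linalg.solve_triangular(
            chol, np.eye(cov.shape[0]), lower=True
        ).T
    return out
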