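"""Decision-boundary approximation and the signed distance-to-boundary score.

The decision boundary of a calibrated detector is the level set
{x : score(x) = threshold}. Because the score is trained on healthy
controls only, this level set closes around the healthy region, and the
signed Euclidean distance of a subject to the nearest boundary point —
negative inside, positive outside — reads as a continuous severity axis:
the further outside, the more severe the deviation from the healthy
pattern.

The boundary is represented as a point cloud obtained by root-finding
along quasi-uniform random rays from an interior anchor, which works in
any dimension and handles disconnected components (each test point is
judged against the component its nearest boundary point belongs to).
Outward unit normals come from central-difference gradients of the score.

A quartile-based severity scale built on reference DtB values maps the
score onto clinically readable HC / MCI / AD bands and a 0-10 axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .models import KnnDetector, NoveltyDetector

logger = logging.getLogger(__name__)

#: finite-difference step for normals, per normalized-unit axis; the KNN
#: score is only piecewise smooth, so its normals use a coarser step that
#: implicitly smooths over score facets.
GRAD_STEP = 1e-4
GRAD_STEP_KNN = 0.05


@dataclass
class Boundary:
    """Point-cloud approximation of a detector's decision boundary."""

    model: NoveltyDetector
    threshold: float
    points: np.ndarray   # (m, d)
    normals: np.ndarray  # (m, d), unit length, toward increasing score
    tol: float

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class DtBResult:
    """Signed distance to boundary per evaluated subject."""

    dtb: np.ndarray            # signed distance; negative inside
    nearest_index: np.ndarray  # index of the nearest boundary point
    side: np.ndarray           # "inside" | "outside"


def training_medoid(X: np.ndarray) -> np.ndarray:
    """The training point minimizing total distance to all others."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X[cdist(X, X).sum(axis=1).argmin()]


def _score_gradient(model: NoveltyDetector, Y: np.ndarray, h: float) -> np.ndarray:
    """Central-difference gradient of the score at each row of Y."""
    m, d = Y.shape
    grad = np.empty((m, d))
    for j in range(d):
        step = np.zeros(d)
        step[j] = h
        grad[:, j] = (
            model.score_samples(Y + step) - model.score_samples(Y - step)
        ) / (2.0 * h)
    return grad


def build_boundary(
    model: NoveltyDetector,
    anchor: np.ndarray | None = None,
    m: int = 2048,
    tol: float = 1e-6,
    seed: int = 0,
    s_max: float | None = None,
    X_train: np.ndarray | None = None,
    grad_step: float | None = None,
) -> Boundary:
    """Approximate the level set score(x) = threshold by ray root-finding.

    For ``m`` quasi-uniform random directions from an interior anchor
    (default: the training-data medoid), bisection locates the crossing of
    the score through the threshold along each ray within ``[0, s_max]``
    (default 10x the training-data radius around the anchor). Rays that
    never cross are dropped and logged; fewer than m/2 surviving rays is an
    error (the boundary is not closed enough around the anchor).
    """
    if model.threshold_ is None:
        raise RuntimeError("model has no threshold; calibrate it first")
    t = float(model.threshold_)

    if X_train is None:
        X_train = getattr(model, "X_train_", None)
    if anchor is None:
        if X_train is None:
            raise ValueError("anchor required when the model stores no training data")
        anchor = training_medoid(X_train)
    anchor = np.asarray(anchor, dtype=float).ravel()
    d = anchor.shape[0]
    if model.score(anchor) >= t:
        raise ValueError("anchor is not strictly inside the boundary")
    if s_max is None:
        if X_train is None:
            raise ValueError("s_max required when the model stores no training data")
        radius = float(np.linalg.norm(X_train - anchor, axis=1).max())
        s_max = 10.0 * max(radius, 1e-12)

    rng = np.random.default_rng(seed)
    U = rng.standard_normal((m, d))
    U /= np.linalg.norm(U, axis=1, keepdims=True)

    f = lambda S: model.score_samples(anchor[None, :] + S[:, None] * U) - t

    hi = np.full(m, float(s_max))
    crosses = f(hi) > 0
    if crosses.sum() < (m + 1) // 2:
        raise ValueError(
            f"only {int(crosses.sum())}/{m} rays cross the boundary within s_max; "
            "boundary not closed enough around the anchor"
        )
    dropped = int(m - crosses.sum())
    if dropped:
        logger.info("dropping %d/%d rays that never cross the threshold", dropped, m)
    U = U[crosses]
    lo = np.zeros(U.shape[0])
    hi = np.full(U.shape[0], float(s_max))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        outside = f(mid) > 0
        hi = np.where(outside, mid, hi)
        lo = np.where(outside, lo, mid)
        if np.all(hi - lo < 4.0 * np.finfo(float).eps * s_max):
            break
    mid = 0.5 * (lo + hi)
    ok = np.abs(f(mid)) <= tol
    if ok.sum() < (m + 1) // 2:
        raise ValueError(
            f"only {int(ok.sum())}/{m} rays reached |score - t| <= tol; "
            "score too discontinuous for this tolerance"
        )
    if not ok.all():
        logger.info("dropping %d rays that missed the score tolerance",
                    int((~ok).sum()))
    Y = anchor[None, :] + mid[ok, None] * U[ok]

    h = grad_step if grad_step is not None else (
        GRAD_STEP_KNN if isinstance(model, KnnDetector) else GRAD_STEP
    )
    grad = _score_gradient(model, Y, h)
    norms = np.linalg.norm(grad, axis=1)
    degenerate = norms <= 0
    if degenerate.any():
        # fall back to the outward ray direction where the gradient vanishes
        grad[degenerate] = U[ok][degenerate]
        norms[degenerate] = 1.0
    N = grad / norms[:, None]
    return Boundary(model=model, threshold=t, points=Y, normals=N, tol=tol)


def dtb(boundary: Boundary, X: np.ndarray) -> DtBResult:
    """Signed distance of each row of X to the boundary point cloud.

    The nearest boundary point y* is found by Euclidean distance (ties by
    lowest index); the sign comes from the dot product of the outward
    normal at y* with the vector from y* to x — negative dot product means
    the subject lies inside (healthy side). A subject exactly on a boundary
    point has DtB = 0 on the inside; a zero dot product defers to the score
    rule score(x) > threshold.
    """
    if boundary.n_points == 0:
        raise ValueError("empty boundary")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = cdist(X, boundary.points)
    nearest = D.argmin(axis=1)  # argmin takes the lowest index on ties
    dist = D[np.arange(X.shape[0]), nearest]
    diff = X - boundary.points[nearest]
    dot = (boundary.normals[nearest] * diff).sum(axis=1)

    inside = dot < 0
    on_fence = dot == 0
    if on_fence.any():
        outside_score = (
            boundary.model.score_samples(X[on_fence]) > boundary.threshold
        )
        inside[on_fence] = ~outside_score
    signed = np.where(inside, -dist, dist)
    side = np.where(inside, "inside", "outside").astype(object)
    return DtBResult(dtb=signed, nearest_index=nearest, side=side)


@dataclass
class SeverityScale:
    """Quartile-based severity bands on the DtB axis, normalized to 0-10.

    Cut points come from reference DtB values of labelled subjects:
    Q1/Q3 of the HC distribution, Q1 of AD, and an upper end at
    Q3_AD + 1.5 * IQR_AD (the boxplot outlier fence). Subjects below the
    AD first quartile read as HC-like, [Q1_AD, Q3_HC) as the MCI band
    (overlapping the HC range — flagged), and [Q3_HC, upper] as AD-like.
    """

    q1_hc: float | None
    q3_hc: float | None
    q1_ad: float | None
    upper: float | None
    lower: float
    bands_present: tuple[str, ...]

    def classify(self, dtb_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Band label per value plus a boolean HC/MCI-overlap flag."""
        v = np.atleast_1d(np.asarray(dtb_values, dtype=float))
        bands = np.full(v.shape, "HC", dtype=object)
        overlap = np.zeros(v.shape, dtype=bool)
        if self.q1_ad is not None and self.q3_hc is not None:
            mci = (v >= self.q1_ad) & (v < self.q3_hc)
            bands[mci] = "MCI"
            overlap[mci] = True  # MCI band sits inside the HC range
            bands[v >= self.q3_hc] = "AD"
        elif self.q3_hc is not None:
            bands[v >= self.q3_hc] = "AD"
        return bands, overlap

    def severity(self, dtb_values: np.ndarray) -> np.ndarray:
        """Affine map of [lower, upper] onto [0, 10], clipped."""
        if self.upper is None:
            raise ValueError("scale has no upper cut (AD absent from reference)")
        v = np.atleast_1d(np.asarray(dtb_values, dtype=float))
        out = 10.0 * (v - self.lower) / (self.upper - self.lower)
        return np.clip(out, 0.0, 10.0)


def severity_scale(
    dtb_values: np.ndarray, labels: np.ndarray
) -> SeverityScale:
    """Build the quartile severity scale from reference DtB values.

    Requires at least 4 subjects per class present; a class absent from
    the reference omits its band with a warning. All-equal reference
    values give no usable axis and raise.
    """
    v = np.asarray(dtb_values, dtype=float)
    labels = np.asarray(labels)
    if np.ptp(v) == 0:
        raise ValueError("all reference DtB values are equal; degenerate scale")

    def quart(cls: str) -> tuple[float, float] | None:
        mask = labels == cls
        if not mask.any():
            warnings.warn(f"class {cls} absent; its band is omitted", stacklevel=2)
            return None
        if mask.sum() < 4:
            raise ValueError(f"need >= 4 reference subjects of class {cls}")
        q1, q3 = np.quantile(v[mask], [0.25, 0.75], method="linear")
        return float(q1), float(q3)

    hc = quart("HC")
    ad = quart("AD")
    present = tuple(
        c for c, q in (("HC", hc), ("AD", ad)) if q is not None
    )
    q1_hc, q3_hc = hc if hc else (None, None)
    q1_ad, q3_ad = ad if ad else (None, None)
    upper = None
    if ad:
        upper = q3_ad + 1.5 * (q3_ad - q1_ad)
    cuts = [c for c in (q1_hc, q3_hc, q1_ad) if c is not None]
    lower = float(min(cuts)) if cuts else float(v.min())
    if upper is not None and upper <= lower:
        raise ValueError("degenerate scale: upper cut does not exceed lower cut")
    return SeverityScale(
        q1_hc=q1_hc, q3_hc=q3_hc, q1_ad=q1_ad,
        upper=upper, lower=lower, bands_present=present,
    )
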