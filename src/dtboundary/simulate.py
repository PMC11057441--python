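"""Synthetic cohort generator emulating dementia-screening tabular data.

Real cohorts of this kind are access-restricted, so the generator emulates
their statistical structure: a majority healthy-control class whose
informative (cognitive-assessment-like) features follow a Gaussian mixture,
impaired classes shifted along a single fixed direction — MCI by Delta
standard deviations and AD by 2*Delta, with equal covariance, producing the
characteristic HC/MCI overlap — plus many class-independent noise features,
and class imbalance. CDR is assigned 0 / 0.5 / 1 by class. Defaults echo a
600/260/160 HC/MCI/AD imbalance with 4 informative and 29 noise features
and Delta = 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort

#: fixed affine rescaling of the informative features so they resemble
#: bounded clinical instruments (e.g. a 0-30 cognitive screen) instead of
#: unit-variance z-scores; recycled when d_informative > 4.
_CFA_SCALE = (4.0, 3.0, 2.5, 5.0)
_CFA_OFFSET = (24.0, 10.0, 8.0, 50.0)

#: modality tags cycled across the noise features.
_NOISE_MODALITIES = ("BLO_ApoE", "MH_DEM", "IMG", "other")


@dataclass
class CohortSpec:
    """Stated world of the generator; see the module docstring."""

    n_hc: int = 600
    n_mci: int = 260
    n_ad: int = 160
    d_informative: int = 4
    d_noise: int = 29
    delta: float = 1.5
    hc_components: int = 2
    noise: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_mci, self.n_ad) <= 0:
            raise ValueError("class counts must be positive")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.d_informative < 1:
            raise ValueError("need at least one informative feature")


def generate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Draw a cohort from the stated world; deterministic given spec.seed."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    di = spec.d_informative

    # unit shift direction shared by both impaired classes
    u = np.ones(di) / np.sqrt(di)
    # mixture component centers spread along an axis orthogonal to the
    # shift (or along u itself when di == 1)
    if di > 1:
        v = np.zeros(di)
        v[0], v[1] = 1.0, -1.0
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
    else:
        v = u.copy()
    centers = np.linspace(-1.0, 1.0, spec.hc_components)[:, None] * v[None, :]

    def draw(n: int, shift: float) -> np.ndarray:
        comp = rng.integers(spec.hc_components, size=n)
        return centers[comp] + shift * u[None, :] + rng.standard_normal((n, di))

    Z = np.vstack(
        [
            draw(spec.n_hc, 0.0),
            draw(spec.n_mci, spec.delta),
            draw(spec.n_ad, 2.0 * spec.delta),
        ]
    )
    scale = np.array([_CFA_SCALE[j % len(_CFA_SCALE)] for j in range(di)])
    offset = np.array([_CFA_OFFSET[j % len(_CFA_OFFSET)] for j in range(di)])
    X_inf = Z * scale + offset

    n_total = spec.n_hc + spec.n_mci + spec.n_ad
    if spec.noise == "uniform":
        X_noise = rng.uniform(0.0, 1.0, size=(n_total, spec.d_noise))
    elif spec.noise == "normal":
        X_noise = rng.standard_normal((n_total, spec.d_noise))
    else:
        raise ValueError(f"unknown noise distribution {spec.noise!r}")

    labels = np.array(
        ["HC"] * spec.n_hc + ["MCI"] * spec.n_mci + ["AD"] * spec.n_ad,
        dtype=object,
    )
    cdr = np.where(labels == "HC", 0.0, np.where(labels == "MCI", 0.5, 1.0))

    inf_names = [f"cfa_{j + 1:02d}" for j in range(di)]
    noise_names = [f"noise_{j + 1:02d}" for j in range(spec.d_noise)]
    modalities = {n: "CFA" for n in inf_names}
    modalities.update(
        {
            n: _NOISE_MODALITIES[j % len(_NOISE_MODALITIES)]
            for j, n in enumerate(noise_names)
        }
    )
    X = np.hstack([X_inf, X_noise]) if spec.d_noise else X_inf
    return Cohort(
        X=X,
        labels=labels,
        feature_names=inf_names + noise_names,
        modalities=modalities,
        cdr=cdr,
    )


def write_cohort(cohort: Cohort, csv_path: str | Path,
                 schema_path: str | Path) -> None:
    """Write the CSV + schema pair that :func:`dtboundary.cohort.load_cohort`
    reads back."""
    df = pd.DataFrame(cohort.X, columns=cohort.feature_names)
    if cohort.cdr is not None:
        df["CDR"] = cohort.cdr
    else:
        df["label"] = cohort.labels
    df.to_csv(csv_path, index=False, float_format="%.10g")
    schema: dict = {"features": dict(cohort.modalities)}
    if cohort.cdr is not None:
        schema["cdr_column"] = "CDR"
    else:
        schema["label_column"] = "label"
    Path(schema_path).write_text(yaml.safe_dump(schema, sort_keys=False))


def unit_circle_points(n: int = 360, radius: float = 1.0) -> np.ndarray:
    """n points evenly spaced on a circle: the analytic boundary fixture
    (a 1-centroid k-means model thresholded at t = radius has exactly the
    circle of that radius as its level set)."""
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def two_point_svdd_set(separation: float = 1.0) -> np.ndarray:
    """Two 1D points at distance ``separation``: the closed-form SVDD
    fixture with kernel value kappa = exp(-separation^2 / sigma^2)."""
    return np.array([[0.0], [float(separation)]])


def knn_1d_set() -> np.ndarray:
    """The two-point 1D training set {0, 1} used for hand-geometry KNN
    checks."""
    return np.array([[0.0], [1.0]])


def generate_worked_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the analytic fixtures (unit circle, two-point SVDD set, 1D KNN
    set) as CSV files and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixtures = {
        "unit_circle": pd.DataFrame(unit_circle_points(), columns=["x", "y"]),
        "svdd_two_point": pd.DataFrame(two_point_svdd_set(), columns=["x"]),
        "knn_1d": pd.DataFrame(knn_1d_set(), columns=["x"]),
    }
    paths = {}
    for name, df in fixtures.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
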