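"""Cohort ingestion, label derivation, normalization and fold construction.

A cohort is one row per subject-visit: numeric feature columns tagged with a
modality (cognitive/functional assessments, imaging volumes, blood panel and
ApoE, medical history and demographics), plus a Clinical Dementia Rating (CDR)
column from which the three-way class label (HC / MCI / AD) is derived.
Repeat visits are treated as independent rows; rows with any missing value in
the selected columns are dropped (complete-case rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

CLASSES = ("HC", "MCI", "AD")
MODALITIES = ("CFA", "IMG", "MH_DEM", "BLO_ApoE", "other")

#: CDR levels accepted by :func:`cdr_to_class`.
VALID_CDR = (0.0, 0.5, 1.0, 2.0, 3.0)


def cdr_to_class(cdr: float) -> str:
    """Map a Clinical Dementia Rating to a class label.

    CDR 0 is healthy control (HC), 0.5 is mild cognitive impairment (MCI),
    and 1/2/3 (mild/moderate/severe dementia) are merged into a single AD
    category because severe ratings are rare in practice.
    """
    if not any(np.isclose(cdr, v) for v in VALID_CDR):
        raise ValueError(f"invalid CDR value {cdr!r}; expected one of {VALID_CDR}")
    if np.isclose(cdr, 0.0):
        return "HC"
    if np.isclose(cdr, 0.5):
        return "MCI"
    return "AD"


@dataclass
class Cohort:
    """Subjects-by-features matrix with class labels and feature metadata.

    Attributes
    ----------
    X : (n_subjects, n_features) float array
    labels : (n_subjects,) array of ``"HC" | "MCI" | "AD"``
    feature_names : list of str
    modalities : mapping feature name -> modality tag
    cdr : optional (n_subjects,) float array of raw CDR scores
    """

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    modalities: dict[str, str]
    cdr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X rows and labels length differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("X columns and feature_names length differ")
        unknown = set(self.labels) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        missing = [f for f in self.feature_names if f not in self.modalities]
        if missing:
            raise ValueError(f"features without a modality tag: {missing}")
        bad = {f: m for f, m in self.modalities.items() if m not in MODALITIES}
        if bad:
            raise ValueError(f"unknown modality tags: {bad}")
        if np.isnan(self.X).any():
            raise ValueError("Cohort contains missing values (complete-case rule)")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def subset_features(self, names: Sequence[str]) -> "Cohort":
        """Restrict to the given feature columns (order preserved as given)."""
        idx = [self.feature_names.index(n) for n in names]
        return replace(
            self,
            X=self.X[:, idx],
            feature_names=list(names),
            modalities={n: self.modalities[n] for n in names},
        )

    def subset_modalities(self, tags: Sequence[str]) -> "Cohort":
        """Restrict to features whose modality tag is in ``tags``."""
        names = [f for f in self.feature_names if self.modalities[f] in set(tags)]
        if not names:
            raise ValueError(f"no features carry modality tags {list(tags)}")
        return self.subset_features(names)

    def subset_rows(self, index: np.ndarray) -> "Cohort":
        return replace(
            self,
            X=self.X[index],
            labels=self.labels[index],
            cdr=None if self.cdr is None else self.cdr[index],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.labels
        if self.cdr is not None:
            df["CDR"] = self.cdr
        return df


def read_schema(path: str | Path) -> dict:
    """Read a YAML/JSON schema mapping columns to roles and modalities.

    Expected keys: ``features`` (mapping column name -> modality tag) and one
    of ``cdr_column`` (labels derived via :func:`cdr_to_class`) or
    ``label_column`` (column already holding HC/MCI/AD strings).
    """
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, dict) or "features" not in schema:
        raise ValueError("schema must be a mapping with a 'features' key")
    if "cdr_column" not in schema and "label_column" not in schema:
        raise ValueError("schema must name a 'cdr_column' or 'label_column'")
    return schema


def load_cohort(path: str | Path, schema: Mapping | str | Path) -> Cohort:
    """Load a cohort from CSV using a column-role schema.

    Rows with any missing value among the selected columns are dropped and
    logged, one line per row. Raises if the schema references an absent
    column or no complete rows remain.
    """
    if not isinstance(schema, Mapping):
        schema = read_schema(schema)
    df = pd.read_csv(path)

    feature_map: dict[str, str] = dict(schema["features"])
    label_col = schema.get("label_column")
    cdr_col = schema.get("cdr_column")
    needed = list(feature_map) + [c for c in (label_col, cdr_col) if c]
    absent = [c for c in needed if c not in df.columns]
    if absent:
        raise ValueError(f"schema references absent column(s): {absent}")

    complete = df[needed].notna().all(axis=1)
    for i in df.index[~complete]:
        blank = [c for c in needed if pd.isna(df.at[i, c])]
        logger.info("dropping row %d: missing value in %s", i, blank)
    df = df.loc[complete]
    if df.empty:
        raise ValueError("no complete rows after applying the complete-case rule")

    cdr = None
    if cdr_col is not None:
        cdr = df[cdr_col].to_numpy(dtype=float)
        labels = np.array([cdr_to_class(v) for v in cdr], dtype=object)
    else:
        labels = df[label_col].astype(str).to_numpy(dtype=object)

    X = df[list(feature_map)].to_numpy(dtype=float)
    return Cohort(
        X=X,
        labels=labels,
        feature_names=list(feature_map),
        modalities=feature_map,
        cdr=cdr,
    )


@dataclass
class NormalizationParams:
    """Per-feature min/max observed on the fitting split."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.maximum < self.minimum):
            raise ValueError("max < min for some feature")


def fit_minmax(X_fit: np.ndarray) -> NormalizationParams:
    """Learn per-feature min/max on the fitting (training) split only."""
    X_fit = np.asarray(X_fit, dtype=float)
    return NormalizationParams(X_fit.min(axis=0), X_fit.max(axis=0))


def apply_minmax(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """Map each feature's fitted min->0 and max->1; clip new data to [0, 1].

    Constant features (max == min) map to 0 everywhere.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != params.minimum.shape[0]:
        raise ValueError(
            f"feature count mismatch: params for {params.minimum.shape[0]}, "
            f"data has {X.shape[1]}"
        )
    span = params.maximum - params.minimum
    out = np.zeros_like(X, dtype=float)
    ok = span > 0
    out[:, ok] = (X[:, ok] - params.minimum[ok]) / span[ok]
    return np.clip(out, 0.0, 1.0)


def stratified_kfold(
    labels: Sequence, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split, deterministic given ``seed``.

    Returns a list of (train_indices, test_indices); the test folds
    partition the index set with per-class proportions preserved to within
    one subject. Raises if any class has fewer than ``k`` members.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; need >= k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]
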