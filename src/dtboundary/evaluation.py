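"""Detection metrics and the nested 5x5 cross-validation protocol.

The outer loop estimates generalization: each of five stratified folds
holds out 20% of every class as a test set. Inside each development set
the inner loop tunes the single method hyperparameter on the healthy
controls alone — train on four fifths of the development HC, validate on
the held-out HC fifth plus *all* development non-HC — choosing the value
with the best mean inner-validation AUC. The model is then refit on all
development HC with the chosen value, its threshold calibrated to the
target false rejection rate, and evaluated on the untouched outer test
fold. Non-HC subjects never enter training; normalization (and optional
feature selection) are fitted inside the development set only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold

from .cohort import Cohort, apply_minmax, fit_minmax, stratified_kfold
from .features import AggregationConfig, select_features
from .models import NoveltyDetector, make_detector


def sensitivity(pred_outside: np.ndarray, truth: np.ndarray,
                positive_class: str) -> float:
    """Fraction of subjects of ``positive_class`` detected (classified
    outside the boundary)."""
    truth = np.asarray(truth)
    mask = truth == positive_class
    if not mask.any():
        raise ValueError(f"no subjects of class {positive_class!r}")
    return float(np.asarray(pred_outside)[mask].mean())


def specificity(pred_outside: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of healthy controls correctly classified inside."""
    truth = np.asarray(truth)
    mask = truth == "HC"
    if not mask.any():
        raise ValueError("no HC subjects")
    return float((~np.asarray(pred_outside, dtype=bool)[mask]).mean())


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUC: probability that a random abnormal subject outscores
    a random normal one, ties counting one half.

    ``truth`` may be boolean (True = abnormal) or HC/MCI/AD labels, in
    which case MCI and AD pool into the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if truth.dtype.kind == "b":
        positive = truth
    else:
        positive = np.isin(truth, ("MCI", "AD"))
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both normal and abnormal subjects")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float(
        (ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    """Mean and normal-approximation 95% CI over folds, clipped to [0, 1].

    A single fold gives no spread; the CI is returned as NaN with a warning.
    """
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    if values.size < 2:
        warnings.warn("single fold: CI undefined", stacklevel=2)
        return mean, float("nan"), float("nan")
    half = 1.96 * values.std(ddof=1) / np.sqrt(values.size)
    return mean, max(mean - half, 0.0), min(mean + half, 1.0)


@dataclass
class FoldResult:
    chosen_param: float
    specificity: float
    sensitivity_mci: float | None
    sensitivity_ad: float | None
    auc: float
    selected_features: list[str] | None = None


@dataclass
class CVReport:
    """Per-outer-fold results plus aggregate mean and 95% CI."""

    method: str
    theta: float
    folds: list[FoldResult] = field(default_factory=list)

    def _column(self, attr: str) -> np.ndarray:
        vals = [getattr(f, attr) for f in self.folds]
        return np.array([v for v in vals if v is not None], dtype=float)

    def aggregate(self) -> dict[str, tuple[float, float, float]]:
        out = {}
        for key in ("auc", "specificity", "sensitivity_mci", "sensitivity_ad"):
            vals = self._column(key)
            if vals.size:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    out[key] = mean_ci(vals)
        return out

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "theta": self.theta,
            "folds": [
                {
                    "chosen_param": f.chosen_param,
                    "specificity": f.specificity,
                    "sensitivity_mci": f.sensitivity_mci,
                    "sensitivity_ad": f.sensitivity_ad,
                    "auc": f.auc,
                    "selected_features": f.selected_features,
                }
                for f in self.folds
            ],
            "aggregate": {k: list(v) for k, v in self.aggregate().items()},
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_table(self) -> str:
        """Human-readable summary mirroring the standard report columns:
        AUC (95% CI), specificity for HC, sensitivity for MCI and AD."""
        agg = self.aggregate()
        lines = [
            f"method: {self.method}   false rejection rate: {self.theta}",
            f"{'fold':>4} {'param':>8} {'AUC':>8} {'spec(HC)':>9} "
            f"{'sens(MCI)':>10} {'sens(AD)':>9}",
        ]
        for i, f in enumerate(self.folds):
            smci = "---" if f.sensitivity_mci is None else f"{f.sensitivity_mci:.4f}"
            sad = "---" if f.sensitivity_ad is None else f"{f.sensitivity_ad:.4f}"
            lines.append(
                f"{i:>4} {f.chosen_param:>8g} {f.auc:>8.4f} "
                f"{f.specificity:>9.4f} {smci:>10} {sad:>9}"
            )
        label = {
            "auc": "AUC",
            "specificity": "specificity (HC)",
            "sensitivity_mci": "sensitivity (MCI)",
            "sensitivity_ad": "sensitivity (AD)",
        }
        lines.append("aggregate (mean, 95% CI):")
        for key, (m, lo, hi) in agg.items():
            lines.append(f"  {label[key]:<18} {m:.4f} ({lo:.4f}-{hi:.4f})")
        return "\n".join(lines)


def _fit_calibrated(
    method: str, param: float, X_hc: np.ndarray, theta: float | None,
    seed: int, sigma_as_exponent: bool, C: float,
) -> NoveltyDetector:
    model = make_detector(
        method, param, seed=seed, C=C, sigma_as_exponent=sigma_as_exponent
    )
    model.fit(X_hc)
    if theta is not None:
        model.calibrate(theta)
    return model


def nested_cv(
    cohort: Cohort,
    method: str,
    grid: list[float],
    theta: float = 0.1,
    seed: int = 0,
    n_outer: int = 5,
    n_inner: int = 5,
    feature_selection: AggregationConfig | None = None,
    sigma_as_exponent: bool = True,
    svdd_C: float = 1.0,
) -> CVReport:
    """Run the nested cross-validation protocol and return a CVReport.

    ``grid`` is the candidate list for the method's hyperparameter;
    ``feature_selection`` (optional) runs the filter-ensemble selection
    inside each development set. Deterministic given ``seed``.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    n_hc = int((cohort.labels == "HC").sum())
    if n_hc < n_outer * n_inner:
        raise ValueError(
            f"{n_hc} HC subjects cannot support {n_outer}x{n_inner} splitting"
        )

    report = CVReport(method=method.lower(), theta=theta)
    outer = stratified_kfold(cohort.labels, n_outer, seed)
    for fold_i, (dev_idx, test_idx) in enumerate(outer):
        dev = cohort.subset_rows(dev_idx)
        test = cohort.subset_rows(test_idx)

        selected = None
        if feature_selection is not None:
            selected = select_features(dev, feature_selection)
            dev = dev.subset_features(selected)
            test = test.subset_features(selected)

        hc_mask = dev.labels == "HC"
        X_hc = dev.X[hc_mask]
        X_abn = dev.X[~hc_mask]

        # inner loop: tune on development HC folds + all development non-HC
        inner = KFold(n_splits=n_inner, shuffle=True, random_state=seed + fold_i)
        inner_auc = np.zeros(len(grid))
        for tr_idx, val_idx in inner.split(X_hc):
            norm = fit_minmax(X_hc[tr_idx])
            X_tr = apply_minmax(norm, X_hc[tr_idx])
            X_val = np.vstack(
                [apply_minmax(norm, X_hc[val_idx]), apply_minmax(norm, X_abn)]
            )
            y_val = np.concatenate(
                [np.zeros(len(val_idx), bool), np.ones(len(X_abn), bool)]
            )
            for gi, param in enumerate(grid):
                model = _fit_calibrated(
                    method, param, X_tr, None, seed, sigma_as_exponent, svdd_C
                )
                scores = model.score_samples(X_val)
                # guard KNN's infinite scores: AUC is rank-based, keep finite order
                scores = np.nan_to_num(scores, posinf=np.finfo(float).max)
                inner_auc[gi] += roc_auc(scores, y_val)
        chosen = grid[int(np.argmax(inner_auc))]  # first best on ties

        # refit on all development HC with the chosen value, test untouched
        norm = fit_minmax(X_hc)
        model = _fit_calibrated(
            method, chosen, apply_minmax(norm, X_hc), theta, seed,
            sigma_as_exponent, svdd_C,
        )
        X_test = apply_minmax(norm, test.X)
        scores = np.nan_to_num(
            model.score_samples(X_test), posinf=np.finfo(float).max
        )
        outside = scores > model.threshold_

        def _sens(cls: str) -> float | None:
            return (
                sensitivity(outside, test.labels, cls)
                if (test.labels == cls).any()
                else None
            )

        report.folds.append(
            FoldResult(
                chosen_param=chosen,
                specificity=specificity(outside, test.labels),
                sensitivity_mci=_sens("MCI"),
                sensitivity_ad=_sens("AD"),
                auc=roc_auc(scores, test.labels),
                selected_features=selected,
            )
        )
    return report
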