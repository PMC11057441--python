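"""Filter-ensemble feature selection against the CDR-derived class label.

Three univariate filters — information gain ratio (IGR), absolute Pearson
correlation, and the Pearson chi-square statistic — each produce a full
ranking of the candidate features. A Cross-Entropy Monte Carlo search then
aggregates the three rankings into a single ordered top-K list (K = 10 by
default) by approximately minimizing the mean weighted Spearman footrule
distance to the inputs. Using several filters in parallel avoids committing
to the bias of any single criterion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, apply_minmax, fit_minmax

#: numeric encoding of the class label used by the Pearson filter:
#: the CDR value that defines each class.
CLASS_NUMERIC = {"HC": 0.0, "MCI": 0.5, "AD": 1.0}


@dataclass
class RankedList:
    """An ordered feature ranking (most important first) with scores."""

    names: list[str]
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate names in ranking")
        if set(self.names) != set(self.scores):
            raise ValueError("names and scores cover different features")

    def rank_of(self, name: str) -> int:
        """1-based position of ``name``."""
        return self.names.index(name) + 1


def _sort_desc(names: list[str], scores: np.ndarray) -> RankedList:
    # stable sort: ties keep input feature order
    order = np.argsort(-scores, kind="stable")
    return RankedList(
        names=[names[i] for i in order],
        scores={n: float(s) for n, s in zip(names, scores)},
    )


def discretize_equal_frequency(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning into labels ``0..n_bins-1``.

    Items are assigned positionally after a stable sort (ties resolved by
    value order then original index), so bin populations differ by at most
    one when values are distinct. Fewer than two distinct values collapse to
    a single bin with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if np.unique(values).size < 2:
        warnings.warn("fewer than 2 distinct values; single bin", stacklevel=2)
        return np.zeros(n, dtype=int)
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, dtype=int)
    # first (n % n_bins) bins get one extra item, mirroring np.array_split
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    start = 0
    for b, size in enumerate(sizes):
        bins[order[start : start + size]] = b
        start += size
    return bins


def _entropy(labels: np.ndarray) -> float:
    """Shannon entropy (base 2) of a discrete vector."""
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def igr_rank(X: np.ndarray, y: np.ndarray, n_bins: int = 10,
             names: list[str] | None = None) -> RankedList:
    """Rank features by information gain ratio against the class label.

    score_j = (H(y) - H(y | x_j)) / H(x_j) with x_j discretized by equal
    frequency; a constant feature (H(x_j) = 0) scores 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("class label is constant")
    names = names or [f"f{j}" for j in range(X.shape[1])]
    hy = _entropy(y)
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            xb = discretize_equal_frequency(X[:, j], n_bins)
        hx = _entropy(xb)
        if hx == 0.0:
            continue
        h_cond = 0.0
        for b in np.unique(xb):
            mask = xb == b
            h_cond += mask.mean() * _entropy(y[mask])
        scores[j] = (hy - h_cond) / hx
    return _sort_desc(names, scores)


def pearson_rank(X: np.ndarray, y: np.ndarray,
                 names: list[str] | None = None) -> RankedList:
    """Rank features by |Pearson r| against the numeric CDR encoding.

    The label is encoded by its defining CDR value (HC=0, MCI=0.5, AD=1);
    zero-variance features score 0 by convention.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = names or [f"f{j}" for j in range(X.shape[1])]
    y_num = np.array([CLASS_NUMERIC.get(v, v) for v in y], dtype=float)
    yc = y_num - y_num.mean()
    sy = np.sqrt((yc ** 2).sum())
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    scores = np.zeros(X.shape[1])
    ok = (sx > 0) & (sy > 0)
    scores[ok] = np.abs(Xc[:, ok].T @ yc) / (sx[ok] * sy)
    return _sort_desc(names, scores)


def chisq_rank(X: np.ndarray, y: np.ndarray, n_bins: int = 10,
               names: list[str] | None = None) -> RankedList:
    """Rank features by the Pearson chi-square statistic of the
    discretized-feature x class contingency table.

    Cells with zero expected count contribute 0 (with a warning), so
    degenerate tables stay finite.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    names = names or [f"f{j}" for j in range(X.shape[1])]
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            xb = discretize_equal_frequency(X[:, j], n_bins)
        table = pd.crosstab(xb, y).to_numpy(dtype=float)
        scores[j] = chi_square_statistic(table)
    return _sort_desc(names, scores)


def chi_square_statistic(observed: np.ndarray) -> float:
    """Sum of (O-E)^2/E over cells; zero-expected cells contribute 0."""
    observed = np.asarray(observed, dtype=float)
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    if np.any(expected == 0):
        warnings.warn("zero expected cell(s); contributing 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return float(contrib.sum())


@dataclass
class AggregationConfig:
    """Parameters of the Cross-Entropy Monte Carlo rank aggregation.

    ``n_samples`` defaults to 10x the universe size when left ``None``.
    ``rho`` is the elite fraction retained per iteration, ``w`` the weight
    of the empirical elite frequencies in the probability-matrix update,
    and ``window`` the number of iterations the incumbent best objective
    must stay unchanged before stopping.
    """

    top_size: int = 10
    n_samples: int | None = None
    rho: float = 0.1
    w: float = 0.25
    max_iter: int = 200
    window: int = 15
    seed: int = 0
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.top_size < 1:
            raise ValueError("top_size must be >= 1")
        if not (0 < self.rho < 1 and 0 < self.w < 1):
            raise ValueError("rho and w must lie in (0, 1)")


def _footrule_tables(
    lists: list[RankedList], universe: list[str], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-list truncated ranks and min-max-normalized weights, as arrays
    indexed [list, item]."""
    n_lists, n_items = len(lists), len(universe)
    ranks = np.empty((n_lists, n_items))
    weights = np.empty((n_lists, n_items))
    for li, rl in enumerate(lists):
        s = np.array([rl.scores[it] for it in universe])
        span = s.max() - s.min()
        weights[li] = (s - s.min()) / span if span > 0 else 1.0
        ranks[li] = [min(rl.rank_of(it), k + 1) for it in universe]
    return ranks, weights


def _objective(
    cand_idx: np.ndarray, ranks: np.ndarray, weights: np.ndarray, k: int
) -> float:
    """Mean weighted footrule distance of one candidate top-k index list."""
    n_items = ranks.shape[1]
    cand_rank = np.full(n_items, k + 1.0)
    cand_rank[cand_idx] = np.arange(1, k + 1)
    return float((weights * np.abs(cand_rank[None, :] - ranks)).sum(axis=1).mean())


def footrule_objective(
    candidate: list[str], lists: list[RankedList], universe: list[str] | None = None
) -> float:
    """Mean weighted Spearman footrule distance of an ordered top-k list to
    the input rankings (items absent from a truncated list rank k+1)."""
    universe = universe or lists[0].names
    k = len(candidate)
    ranks, weights = _footrule_tables(lists, list(universe), k)
    idx = np.array([list(universe).index(c) for c in candidate])
    return _objective(idx, ranks, weights, k)


def ce_rank_aggregate(
    lists: list[RankedList], cfg: AggregationConfig
) -> tuple[list[str], float]:
    """Aggregate several rankings into one ordered top-K list.

    Cross-Entropy Monte Carlo search: an item-by-position probability matrix
    is sampled to produce candidate lists; the best ``rho`` fraction per
    iteration re-estimates the matrix via a convex update with weight ``w``.
    Deterministic given ``cfg.seed``. Returns (ordered names, objective of
    the best list found).
    """
    if len(lists) < 2:
        raise ValueError("need at least 2 rankings to aggregate")
    universe = list(lists[0].names)
    for rl in lists[1:]:
        if set(rl.names) != set(universe):
            raise ValueError("rankings cover different feature universes")
    universe = sorted(universe)  # canonical item order, independent of inputs
    n_items = len(universe)
    k = min(cfg.top_size, n_items)
    n_samples = cfg.n_samples or 10 * n_items
    n_elite = max(1, int(round(cfg.rho * n_samples)))
    rng = np.random.default_rng(cfg.seed)

    ranks, weights = _footrule_tables(lists, universe, k)
    P = np.full((n_items, k), 1.0 / n_items)

    best_idx: np.ndarray | None = None
    best_obj = np.inf
    stall = 0
    for _ in range(cfg.max_iter):
        samples = np.empty((n_samples, k), dtype=int)
        objs = np.empty(n_samples)
        for s in range(n_samples):
            avail = np.ones(n_items, dtype=bool)
            pick = np.empty(k, dtype=int)
            for pos in range(k):
                p = P[:, pos] * avail
                tot = p.sum()
                p = p / tot if tot > 0 else avail / avail.sum()
                pick[pos] = rng.choice(n_items, p=p)
                avail[pick[pos]] = False
            samples[s] = pick
            objs[s] = _objective(pick, ranks, weights, k)
        elite = samples[np.argsort(objs, kind="stable")[:n_elite]]
        it_best = objs.min()
        if it_best < best_obj - 1e-12:
            best_obj = it_best
            best_idx = samples[int(np.argmin(objs))].copy()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.window:
                break
        freq = np.zeros_like(P)
        for pos in range(k):
            counts = np.bincount(elite[:, pos], minlength=n_items)
            freq[:, pos] = counts / n_elite
        P = (1 - cfg.w) * P + cfg.w * freq

    assert best_idx is not None
    return [universe[i] for i in best_idx], best_obj


def brute_force_aggregate(
    lists: list[RankedList], k: int | None = None
) -> tuple[list[str], float]:
    """Exhaustive footrule minimization over all k-permutations.

    Oracle-grade reference for small universes (factorial cost).
    """
    universe = sorted(lists[0].names)
    k = k or len(universe)
    ranks, weights = _footrule_tables(lists, universe, k)
    best: tuple[float, tuple[int, ...]] | None = None
    for perm in itertools.permutations(range(len(universe)), k):
        obj = _objective(np.array(perm), ranks, weights, k)
        if best is None or obj < best[0] - 1e-12:
            best = (obj, perm)
    assert best is not None
    return [universe[i] for i in best[1]], best[0]


def rank_table(cohort: Cohort, n_bins: int = 10) -> pd.DataFrame:
    """Run the three filters on a min-max-normalized cohort; one row per
    feature with each filter's score and rank."""
    params = fit_minmax(cohort.X)
    Xn = apply_minmax(params, cohort.X)
    names = cohort.feature_names
    filters = {
        "igr": igr_rank(Xn, cohort.labels, n_bins, names),
        "pearson": pearson_rank(Xn, cohort.labels, names),
        "chisq": chisq_rank(Xn, cohort.labels, n_bins, names),
    }
    df = pd.DataFrame(index=names)
    for fname, rl in filters.items():
        df[f"{fname}_score"] = [rl.scores[n] for n in names]
        df[f"{fname}_rank"] = [rl.rank_of(n) for n in names]
    return df


def select_features(
    cohort: Cohort, cfg: AggregationConfig | None = None
) -> list[str]:
    """Full selection pipeline: normalize, run the three filters, aggregate,
    return the top ``min(cfg.top_size, n_features)`` feature names."""
    cfg = cfg or AggregationConfig()
    params = fit_minmax(cohort.X)
    Xn = apply_minmax(params, cohort.X)
    names = cohort.feature_names
    lists = [
        igr_rank(Xn, cohort.labels, cfg.n_bins, names),
        pearson_rank(Xn, cohort.labels, names),
        chisq_rank(Xn, cohort.labels, cfg.n_bins, names),
    ]
    top, _ = ce_rank_aggregate(lists, cfg)
    return top
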