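"""SMO-style solver for the SVDD dual quadratic program.

Solves  max_a  sum_i a_i K_ii - a' K a   s.t.  sum a = 1, 0 <= a_i <= C,
equivalently  min_a  a' K a - sum_i a_i K_ii  over the capped simplex.
Pairwise (maximal-violating-pair) coordinate updates preserve the equality
constraint exactly; each step is O(n) thanks to an incrementally maintained
gradient. K must be symmetric positive semidefinite.
"""

from __future__ import annotations

import numpy as np


def solve_svdd_dual(
    K: np.ndarray,
    C: float,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Return the optimal multipliers ``a`` of the SVDD dual.

    Parameters
    ----------
    K : (n, n) kernel matrix.
    C : box constraint; must satisfy C >= 1/n for feasibility.
    tol : KKT violation tolerance on the gradient gap.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n):
        raise ValueError("K must be square")
    if C < 1.0 / n:
        raise ValueError(f"C={C} infeasible: need C >= 1/n = {1.0 / n}")

    a = np.full(n, 1.0 / n)
    diag = np.diag(K).copy()
    Ka = K @ a
    # gradient of the minimized objective a'Ka - sum a_i K_ii
    grad = 2.0 * Ka - diag

    for _ in range(max_iter):
        up_ok = a < C - 1e-14       # can receive mass
        down_ok = a > 1e-14         # can give mass
        i = int(np.argmin(np.where(up_ok, grad, np.inf)))
        j = int(np.argmax(np.where(down_ok, grad, -np.inf)))
        gap = grad[j] - grad[i]
        if gap <= tol:
            break
        curv = diag[i] + diag[j] - 2.0 * K[i, j]
        delta = gap / (2.0 * curv) if curv > 1e-14 else np.inf
        delta = min(delta, C - a[i], a[j])
        if delta <= 0:
            break
        a[i] += delta
        a[j] -= delta
        step = delta * (K[:, i] - K[:, j])
        Ka += step
        grad += 2.0 * step
    return a


def svdd_dual_objective(a: np.ndarray, K: np.ndarray) -> float:
    """Dual objective (maximized form): sum_i a_i K_ii - a' K a."""
    a = np.asarray(a, dtype=float)
    return float(a @ np.diag(K) - a @ K @ a)


def random_feasible(
    n: int, C: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` random points of the capped simplex {sum=1, 0<=a<=C}.

    Dirichlet draws followed by clipping-and-redistribution; used as a
    brute-force comparison set for the QP solution.
    """
    out = np.empty((size, n))
    for s in range(size):
        a = rng.dirichlet(np.ones(n))
        # push mass exceeding C back onto unsaturated coordinates
        for _ in range(n):
            excess = np.clip(a - C, 0.0, None)
            if excess.sum() <= 1e-15:
                break
            a = np.minimum(a, C)
            room = a < C
            a[room] += excess.sum() * (a[room] + 1e-12) / (a[room] + 1e-12).sum()
        out[s] = np.minimum(a, C)
    return out
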