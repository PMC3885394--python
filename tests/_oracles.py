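"""Independent reference solvers used only by the tests.

The hierarchical problems are convex once the interaction entries are
split into positive and negative parts: the l1 terms become linear and the
row-budget constraints become linear inequalities, so a general-purpose
NLP solver (SLSQP with analytic structure-free objectives) can minimize
the exact same objective the package's proximal-gradient solver declares.
These routines are deliberately naive and independent of the package's
solution path.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def onerow_oracle(b_plus, b_minus, T_row, lam, t):
    """Minimize the ONEROW objective with SLSQP on the split formulation.

    Variables [bp, bm, a_1..a_m, b_1..b_m] >= 0 with Theta = a - b and the
    linear constraint sum(a+b) <= bp + bm.  Returns the optimal objective.
    """
    T_row = np.asarray(T_row, dtype=float)
    m = len(T_row)

    def obj(v):
        bp, bm = v[0], v[1]
        a = v[2 : 2 + m]
        b = v[2 + m :]
        th = a - b
        return (
            (1.0 / (2 * t))
            * ((bp - b_plus) ** 2 + (bm - b_minus) ** 2 + np.sum((th - T_row) ** 2))
            + lam * (bp + bm)
            + 0.5 * lam * np.sum(a + b)
        )

    A = np.zeros(2 + 2 * m)
    A[0] = A[1] = -1.0
    A[2:] = 1.0
    res = minimize(
        obj,
        np.full(2 + 2 * m, 0.1),
        bounds=[(0, None)] * (2 + 2 * m),
        constraints=[LinearConstraint(A, -np.inf, 0.0)],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    return float(res.fun)


def weak_hier_oracle(problem, lam):
    """Minimize the full weak-hierarchical-lasso objective with SLSQP.

    Same split trick per off-diagonal Theta entry; row constraints are the
    p linear inequalities sum_offdiag(a+b) <= bp_j + bm_j.  Returns the
    optimal objective value.  Only viable for tiny p.
    """
    X = problem.X_norm
    Z = problem.design.Z
    y = problem.table.y
    n, p = X.shape
    pairs = problem.design.pair_index
    q = len(pairs)
    off = [(j, k) for j in range(p) for k in range(p) if j != k]
    m = len(off)
    nv = 1 + 2 * p + 2 * m
    colmap = {}
    for c, (j, k) in enumerate(pairs):
        colmap[(j, k)] = c
        colmap[(k, j)] = c
    offc = np.array([colmap[o] for o in off])

    def obj(v):
        b0 = v[0]
        bp = v[1 : 1 + p]
        bm = v[1 + p : 1 + 2 * p]
        a = v[1 + 2 * p : 1 + 2 * p + m]
        b = v[1 + 2 * p + m :]
        th = a - b
        w = np.zeros(q)
        np.add.at(w, offc, th / 2.0)
        eta = b0 + X @ (bp - bm) + Z @ w
        if problem.loss == "logistic":
            L = float(np.sum(np.logaddexp(0.0, eta) - y * eta) / n)
        else:
            L = float(0.5 * np.sum((eta - y) ** 2) / n)
        return L + lam * (bp.sum() + bm.sum()) + 0.5 * lam * np.sum(a + b)

    A = np.zeros((p, nv))
    for r, (j, k) in enumerate(off):
        A[j, 1 + 2 * p + r] = 1.0
        A[j, 1 + 2 * p + m + r] = 1.0
    for j in range(p):
        A[j, 1 + j] = -1.0
        A[j, 1 + p + j] = -1.0
    res = minimize(
        obj,
        np.full(nv, 0.01),
        bounds=[(None, None)] + [(0, None)] * (nv - 1),
        constraints=[LinearConstraint(A, -np.inf, 0.0)],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 2000},
    )
    return float(res.fun)


def lambda_max_bisect(problem, fit_fn, lo_ratio=1e-3, iters=30):
    """Brute-force the smallest penalty giving an all-zero fit by bisection
    on whether a fit at the candidate penalty is entirely zero."""
    from whlfs.solver import lambda_max

    guess = lambda_max(problem)

    def is_zero(lam):
        fit = fit_fn(problem, lam)
        return (
            np.abs(fit.beta).max() < 1e-9 and np.abs(fit.Theta).max() < 1e-9
        )

    lo, hi = guess * lo_ratio, guess * 3.0
    assert not is_zero(lo) and is_zero(hi)
    for _ in range(iters):
        mid = np.sqrt(lo * hi)
        if is_zero(mid):
            hi = mid
        else:
            lo = mid
    return hi
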