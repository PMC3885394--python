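"""Weak hierarchical lasso solver (accelerated proximal gradient + ONEROW prox).

The model couples main effects and pairwise interactions through per-row
budget constraints.  With the main-effect vector split into nonnegative
parts beta = beta_plus - beta_minus and an interaction matrix Theta
(zero diagonal, NOT constrained to be symmetric), the problem is

    minimize   L(beta0, beta, Theta)
               + lam * sum_j (beta_plus_j + beta_minus_j)
               + (lam/2) * sum_j ||Theta_j||_1
    subject to beta_plus >= 0, beta_minus >= 0,
               ||Theta_j||_1 <= beta_plus_j + beta_minus_j   for every row j,

where L is the mean logistic negative log-likelihood (or half mean squared
error) of the linear predictor

    eta_i = beta0 + x_i' beta + sum_{j<k} ((Theta_jk + Theta_kj)/2) z_i,(jk)

built from the normalized main columns and normalized product columns.
The row constraints enforce weak hierarchy: an interaction in row j can be
nonzero only if feature j (or, via row k, feature k) carries a main-effect
budget.  Dropping the row constraints and keeping a uniform l1 penalty
gives the All-Pair Lasso baseline.

Each proximal step decomposes into p independent per-row subproblems
(ONEROW): soft-threshold the row of Theta and the two main-effect parts,
with the constraint handled through its scalar Lagrange multiplier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .data import (
    FeatureTable,
    InteractionDesign,
    NormalizationParams,
    apply_normalization,
    build_interaction_design,
    interaction_columns_for,
    normalize_columns,
)

logger = logging.getLogger(__name__)

Loss = Literal["logistic", "squared"]


@dataclass
class HierLassoProblem:
    """A feature table with its normalized design, ready for fitting."""

    table: FeatureTable
    loss: Loss
    X_norm: np.ndarray
    x_params: NormalizationParams
    design: InteractionDesign

    @property
    def n(self) -> int:
        return self.X_norm.shape[0]

    @property
    def p(self) -> int:
        return self.X_norm.shape[1]

    @property
    def kept_names(self) -> list[str]:
        return self.x_params.kept_names


@dataclass
class HierLassoFit:
    """Solution of the weak hierarchical lasso (or the All-Pair relaxation).

    ``beta_plus``/``beta_minus`` are the nonnegative parts of the
    main-effect vector; ``Theta`` is the p x p interaction matrix with zero
    diagonal.  The effective weight of unordered pair (j, k) in the model
    is ``(Theta[j, k] + Theta[k, j]) / 2``.
    """

    beta0: float
    beta_plus: np.ndarray
    beta_minus: np.ndarray
    Theta: np.ndarray
    lam: float
    loss: Loss
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def beta(self) -> np.ndarray:
        return self.beta_plus - self.beta_minus

    def pair_weights(self, pair_index: Sequence[tuple[int, int]]) -> np.ndarray:
        ju = np.fromiter((j for j, _ in pair_index), dtype=int)
        ku = np.fromiter((k for _, k in pair_index), dtype=int)
        return 0.5 * (self.Theta[ju, ku] + self.Theta[ku, ju])

    def check_invariants(self, atol: float = 1e-8) -> None:
        if np.any(self.beta_plus < 0) or np.any(self.beta_minus < 0):
            raise AssertionError("negative split coefficients")
        if np.any(np.diag(self.Theta) != 0):
            raise AssertionError("nonzero Theta diagonal")
        budget = self.beta_plus + self.beta_minus
        rows = np.abs(self.Theta).sum(axis=1)
        if np.any(rows > budget + atol):
            raise AssertionError("weak hierarchy violated beyond tolerance")

    def to_json(self, threshold: float = 1e-12) -> str:
        names = self.feature_names or [f"f{j}" for j in range(len(self.beta_plus))]
        beta = self.beta
        mains = {
            names[j]: float(beta[j])
            for j in range(len(beta))
            if abs(beta[j]) > threshold
        }
        p = len(names)
        pairs = {}
        for j in range(p):
            for k in range(j + 1, p):
                w = 0.5 * (self.Theta[j, k] + self.Theta[k, j])
                if abs(w) > threshold:
                    pairs[f"{names[j]}×{names[k]}"] = float(w)
        return json.dumps(
            {
                "lambda": float(self.lam),
                "loss": self.loss,
                "intercept": float(self.beta0),
                "main_effects": mains,
                "interactions": pairs,
                "converged": bool(self.converged),
                "n_iter": int(self.n_iter),
            },
            indent=2,
        )


def make_problem(table: FeatureTable, loss: Loss = "logistic") -> HierLassoProblem:
    """Normalize a feature table and build its interaction design."""
    if loss not in ("logistic", "squared"):
        raise ValueError(f"unknown loss {loss!r}")
    table.require_both_classes()
    X_norm, x_params = normalize_columns(table.X, table.feature_names)
    design = build_interaction_design(X_norm, x_params.kept_names)
    return HierLassoProblem(
        table=table, loss=loss, X_norm=X_norm, x_params=x_params, design=design
    )


# ---------------------------------------------------------------------------
# smooth loss


def _eta(problem: HierLassoProblem, beta0, beta, w) -> np.ndarray:
    return beta0 + problem.X_norm @ beta + problem.design.Z @ w


def _smooth_value(problem: HierLassoProblem, eta: np.ndarray) -> float:
    y = problem.table.y
    n = len(y)
    if problem.loss == "logistic":
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) / n)
    return float(0.5 * np.sum((eta - y) ** 2) / n)


def _smooth_grad_eta(problem: HierLassoProblem, eta: np.ndarray) -> np.ndarray:
    y = problem.table.y
    n = len(y)
    if problem.loss == "logistic":
        from scipy.special import expit

        return (expit(eta) - y) / n
    return (eta - y) / n


def _pair_arrays(problem: HierLassoProblem):
    pairs = problem.design.pair_index
    ju = np.fromiter((j for j, _ in pairs), dtype=int)
    ku = np.fromiter((k for _, k in pairs), dtype=int)
    return ju, ku


def loss_value_grad(
    problem: HierLassoProblem,
    beta0: float,
    beta: np.ndarray,
    Theta: np.ndarray,
) -> tuple[float, tuple[float, np.ndarray, np.ndarray]]:
    """Smooth loss and its exact gradient over (beta0, beta, Theta).

    Logistic: mean negative log-likelihood of y given eta.  Squared:
    half mean squared residual of eta against y.
    """
    beta = np.asarray(beta, dtype=float)
    Theta = np.asarray(Theta, dtype=float)
    if not (
        np.isfinite(beta0) and np.all(np.isfinite(beta)) and np.all(np.isfinite(Theta))
    ):
        raise ValueError("non-finite parameters")
    ju, ku = _pair_arrays(problem)
    w = 0.5 * (Theta[ju, ku] + Theta[ku, ju])
    eta = _eta(problem, beta0, beta, w)
    value = _smooth_value(problem, eta)
    u = _smooth_grad_eta(problem, eta)
    g0 = float(u.sum())
    gbeta = problem.X_norm.T @ u
    gz = problem.design.Z.T @ u
    gTheta = np.zeros_like(Theta)
    gTheta[ju, ku] = 0.5 * gz
    gTheta[ku, ju] = 0.5 * gz
    return value, (g0, gbeta, gTheta)


def _penalty(lam: float, bp, bm, Theta) -> float:
    return float(lam * (bp.sum() + bm.sum()) + 0.5 * lam * np.abs(Theta).sum())


# ---------------------------------------------------------------------------
# ONEROW prox


def _soft(x, thr):
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def onerow_prox(
    b_plus: float, b_minus: float, T_row: np.ndarray, lam: float, t: float
) -> tuple[float, float, np.ndarray]:
    """Exact prox of one row's penalty-plus-constraint block.

    Minimizes ``(1/2t)[(bp - b_plus)^2 + (bm - b_minus)^2 + ||Th - T_row||^2]
    + lam (bp + bm) + (lam/2) ||Th||_1`` over ``bp, bm >= 0`` and
    ``||Th||_1 <= bp + bm``.

    Solved through the constraint's scalar Lagrange multiplier alpha >= 0:
    Theta is soft-thresholded at ``t (lam/2 + alpha)`` and the main parts
    are ``max(0, b± - t (lam - alpha))``; the constraint slack is piecewise
    linear and non-increasing in alpha, so its root is found by safeguarded
    bisection (alpha = 0 when the constraint is already slack).
    """
    if not (np.isfinite(b_plus) and np.isfinite(b_minus)) or not np.all(
        np.isfinite(T_row)
    ):
        raise ValueError("non-finite prox inputs")
    if lam < 0 or t <= 0:
        raise ValueError("need lam >= 0 and t > 0")
    T_row = np.asarray(T_row, dtype=float)

    def point(alpha):
        th = _soft(T_row, t * (0.5 * lam + alpha))
        bp = max(0.0, b_plus - t * (lam - alpha))
        bm = max(0.0, b_minus - t * (lam - alpha))
        return bp, bm, th

    def slack(alpha):
        bp, bm, th = point(alpha)
        return np.abs(th).sum() - bp - bm

    if slack(0.0) <= 1e-15:
        return point(0.0)
    hi = max(np.max(np.abs(T_row)) / t - 0.5 * lam, 0.0) + 1e-12
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if slack(mid) > 0:
            lo = mid
        else:
            hi = mid
    # upper endpoint guarantees feasibility of the returned point
    return point(hi)


def _prox_all_rows(Bp, Bm, T, lam, t):
    """Vectorized ONEROW over all p rows (T is p x p with zero diagonal).

    The constraint slack g(alpha) is piecewise linear and non-increasing in
    the row's Lagrange multiplier, with kinks where a Theta entry is
    thresholded away or a main-effect part activates; the root is found
    exactly by sorting each active row's kink points and interpolating on
    the bracketing linear segment.
    """
    thr = t * 0.5 * lam
    Th = _soft(T, thr)
    shift = t * lam
    bp = np.maximum(0.0, Bp - shift)
    bm = np.maximum(0.0, Bm - shift)
    g0 = np.abs(Th).sum(axis=1) - bp - bm
    active = g0 > 1e-15
    if not np.any(active):
        return bp, bm, Th
    rows = np.where(active)[0]
    Ta = T[rows]
    bpa = Bp[rows]
    bma = Bm[rows]
    absT = np.abs(Ta)
    m = len(rows)
    # g(alpha) = t * sum_i max(A_i - alpha, 0) - max(0, Bp0 + t*alpha)
    #                                         - max(0, Bm0 + t*alpha)
    A = absT / t - 0.5 * lam  # (m, p) Theta-entry kink positions
    Bp0 = bpa - shift
    Bm0 = bma - shift
    kinks = np.concatenate(
        [A, (-Bp0 / t)[:, None], (-Bm0 / t)[:, None]], axis=1
    )
    kinks = np.maximum(kinks, 0.0)
    kinks.sort(axis=1)
    # evaluate g at every kink (m, K); memory m*K*p, chunk if huge
    K = kinks.shape[1]
    gk = np.empty((m, K))
    chunk = max(1, int(2e7 // (K * A.shape[1] + 1)))
    for s in range(0, m, chunk):
        e = min(m, s + chunk)
        gk[s:e] = t * np.maximum(
            A[s:e, None, :] - kinks[s:e, :, None], 0.0
        ).sum(axis=2)
    gk -= np.maximum(0.0, Bp0[:, None] + t * kinks)
    gk += -np.maximum(0.0, Bm0[:, None] + t * kinks)
    # first kink with g <= 0 (exists: at alpha = max A the row of Theta is
    # zero and g <= 0); interpolate linearly on the bracketing segment
    nonpos = gk <= 0.0
    idx = np.argmax(nonpos, axis=1)
    ar = np.arange(m)
    a_hi = kinks[ar, idx]
    g_hi = gk[ar, idx]
    a_lo = np.where(idx > 0, kinks[ar, np.maximum(idx - 1, 0)], 0.0)
    g_lo = np.where(idx > 0, gk[ar, np.maximum(idx - 1, 0)], g0[rows])
    denom = g_lo - g_hi
    frac = np.where(denom > 0, g_lo / np.where(denom > 0, denom, 1.0), 1.0)
    alpha = a_lo + frac * (a_hi - a_lo)
    alpha = np.clip(alpha, a_lo, a_hi)
    thr_a = t * (0.5 * lam + alpha)[:, None]
    Th[rows] = _soft(Ta, thr_a)
    shift_a = t * (lam - alpha)
    bp[rows] = np.maximum(0.0, bpa - shift_a)
    bm[rows] = np.maximum(0.0, bma - shift_a)
    return bp, bm, Th


# ---------------------------------------------------------------------------
# lambda grid


def lambda_max(problem: HierLassoProblem) -> float:
    """Smallest penalty at which the fit is entirely zero (intercept only).

    At the intercept-only optimum the gradient of the smooth loss w.r.t.
    eta is ``(ybar - y)/n`` for both losses.  Row j of the all-zero fit is
    stationary iff some multiplier alpha_j >= 0 satisfies both
    ``alpha_j >= (max_c |gZ_jc| - lam)/2`` (interactions thresholded away)
    and ``alpha_j <= lam - |gX_j|`` (main parts stay at zero), which
    reduces to ``lam >= max(|gX_j|, (M_j + 2 |gX_j|)/3)`` with M_j the
    largest product-column correlation involving j.
    """
    y = problem.table.y
    ybar = y.mean()
    u = (ybar - y) / len(y)
    gX = np.abs(problem.X_norm.T @ u)
    gZ = np.abs(problem.design.Z.T @ u)
    p = problem.p
    M = np.zeros(p)
    for c, (j, k) in enumerate(problem.design.pair_index):
        if gZ[c] > M[j]:
            M[j] = gZ[c]
        if gZ[c] > M[k]:
            M[k] = gZ[c]
    per_row = np.maximum(gX, (M + 2.0 * gX) / 3.0)
    return float(per_row.max())


def default_lambda_grid(
    problem: HierLassoProblem, n_points: int = 16, min_ratio: float = 0.01
) -> np.ndarray:
    """Geometric grid of ``n_points`` values from lambda_max down to
    lambda_max * min_ratio (descending)."""
    lmax = lambda_max(problem)
    return lmax * np.geomspace(1.0, min_ratio, n_points)


# ---------------------------------------------------------------------------
# FISTA


def _power_step_size(problem: HierLassoProblem, n_iter: int = 8) -> float:
    """Initial step from a power-iteration estimate of the design's top
    singular value (backtracking corrects any underestimate)."""
    rng = np.random.default_rng(0)
    n = problem.n
    p = problem.p
    q = problem.design.n_pairs
    ju, ku = _pair_arrays(problem)
    v0 = 1.0
    vb = rng.standard_normal(p)
    vT = rng.standard_normal((p, p))
    np.fill_diagonal(vT, 0.0)
    sigma2 = 1.0
    for _ in range(n_iter):
        w = 0.5 * (vT[ju, ku] + vT[ku, ju])
        u = v0 + problem.X_norm @ vb + problem.design.Z @ w
        v0 = u.sum()
        vb = problem.X_norm.T @ u
        gz = problem.design.Z.T @ u
        vT = np.zeros((p, p))
        vT[ju, ku] = 0.5 * gz
        vT[ku, ju] = 0.5 * gz
        norm = np.sqrt(v0**2 + vb @ vb + (vT**2).sum())
        if norm == 0:
            break
        sigma2 = norm
        v0 /= norm
        vb /= norm
        vT /= norm
    lip = sigma2 / n * (0.25 if problem.loss == "logistic" else 1.0)
    return 1.0 / max(lip, 1e-12)


def _intercept_init(problem: HierLassoProblem) -> float:
    ybar = problem.table.y.mean()
    if problem.loss == "logistic":
        ybar = min(max(ybar, 1e-12), 1 - 1e-12)
        return float(np.log(ybar / (1 - ybar)))
    return float(ybar)


def fit_weak_hier_lasso(
    problem: HierLassoProblem,
    lam: float,
    max_iter: int = 5000,
    tol: float = 1e-7,
    warm_start: HierLassoFit | None = None,
) -> HierLassoFit:
    """Fit the weak hierarchical lasso at one penalty level.

    Monotone FISTA with backtracking line search: a gradient step on the
    smooth loss followed by the exact row-wise ONEROW prox.  The returned
    fit always satisfies the weak-hierarchy constraints (the prox is
    feasible by construction).  Convergence is declared when the relative
    objective change drops below ``tol``.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    n, p = problem.n, problem.p
    ju, ku = _pair_arrays(problem)
    X = problem.X_norm
    Z = problem.design.Z
    y = problem.table.y

    if problem.loss == "logistic":
        from scipy.special import expit

        def sval(eta):
            return float(np.sum(np.logaddexp(0.0, eta) - y * eta) / n)

        def sgrad(eta):
            return (expit(eta) - y) / n

    else:

        def sval(eta):
            return float(0.5 * np.sum((eta - y) ** 2) / n)

        def sgrad(eta):
            return (eta - y) / n

    def eta_of(b0, bp, bm, Th):
        w = 0.5 * (Th[ju, ku] + Th[ku, ju])
        return b0 + X @ (bp - bm) + Z @ w

    def full_obj(b0, bp, bm, Th, eta=None):
        if eta is None:
            eta = eta_of(b0, bp, bm, Th)
        return sval(eta) + _penalty(lam, bp, bm, Th)

    if warm_start is not None:
        b0 = float(warm_start.beta0)
        bp = warm_start.beta_plus.copy()
        bm = warm_start.beta_minus.copy()
        Th = warm_start.Theta.copy()
    else:
        b0 = _intercept_init(problem)
        bp = np.zeros(p)
        bm = np.zeros(p)
        Th = np.zeros((p, p))

    t = _power_step_size(problem)
    Fx = full_obj(b0, bp, bm, Th)
    trace = [Fx]

    yb0, ybp, ybm, yTh = b0, bp.copy(), bm.copy(), Th.copy()
    tk = 1.0
    converged = False
    it = 0

    def prox_from(c0, cp, cm, cT, step):
        eta_y = eta_of(c0, cp, cm, cT)
        f_y = sval(eta_y)
        u = sgrad(eta_y)
        g0 = u.sum()
        gX = X.T @ u
        gz = Z.T @ u
        gT = np.zeros((p, p))
        gT[ju, ku] = 0.5 * gz
        gT[ku, ju] = 0.5 * gz
        for _ in range(60):
            n0 = c0 - step * g0
            nbp, nbm, nTh = _prox_all_rows(
                cp - step * gX, cm + step * gX, cT - step * gT, lam, step
            )
            eta_z = eta_of(n0, nbp, nbm, nTh)
            f_z = sval(eta_z)
            d0 = n0 - c0
            dbp = nbp - cp
            dbm = nbm - cm
            dT = nTh - cT
            lin = g0 * d0 + gX @ (dbp - dbm) + float((gT * dT).sum())
            quad = 0.5 / step * (
                d0 * d0 + dbp @ dbp + dbm @ dbm + float((dT * dT).sum())
            )
            if f_z <= f_y + lin + quad + 1e-12 * max(1.0, abs(f_y)):
                return n0, nbp, nbm, nTh, f_z + _penalty(lam, nbp, nbm, nTh), step
            step *= 0.5
        raise RuntimeError("backtracking line search failed (divergent loss?)")

    for it in range(1, max_iter + 1):
        z0, zbp, zbm, zTh, Fz, t = prox_from(yb0, ybp, ybm, yTh, t)
        if not np.isfinite(Fz):
            raise RuntimeError("objective diverged to non-finite value")
        if Fz > Fx + 1e-12:
            # momentum overshoot: restart from the current iterate
            z0, zbp, zbm, zTh, Fz, t = prox_from(b0, bp, bm, Th, t)
            tk = 1.0
        if Fz <= Fx:
            prev0, prevbp, prevbm, prevTh = b0, bp, bm, Th
            b0, bp, bm, Th = z0, zbp, zbm, zTh
            F_prev, Fx = Fx, Fz
        else:  # keep x (monotone safeguard); still update momentum point
            prev0, prevbp, prevbm, prevTh = b0, bp, bm, Th
            F_prev = Fx
        trace.append(Fx)
        tk1 = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        mom = (tk - 1.0) / tk1
        yb0 = b0 + mom * (b0 - prev0)
        ybp = bp + mom * (bp - prevbp)
        ybm = bm + mom * (bm - prevbm)
        yTh = Th + mom * (Th - prevTh)
        tk = tk1
        if abs(F_prev - Fx) <= tol * max(1.0, abs(Fx)):
            converged = True
            break

    if not converged:
        logger.warning(
            "weak hierarchical lasso did not converge in %d iterations (lam=%g)",
            max_iter,
            lam,
        )
    fit = HierLassoFit(
        beta0=b0,
        beta_plus=bp,
        beta_minus=bm,
        Theta=Th,
        lam=lam,
        loss=problem.loss,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        feature_names=list(problem.kept_names),
    )
    fit.check_invariants()
    return fit


def fit_all_pair_lasso(
    problem: HierLassoProblem,
    lam: float,
    max_iter: int = 5000,
    tol: float = 1e-9,
    warm_start: HierLassoFit | None = None,
) -> HierLassoFit:
    """All-Pair Lasso baseline: uniform l1 penalty on the concatenated
    [mains, products] design, no hierarchy constraints.

    Fitted with the same monotone FISTA, the prox being a plain
    soft-threshold.  Returned in the common fit shape with ``Theta`` filled
    symmetrically from the pair coefficients; the weak-hierarchy invariant
    may well be violated, which is the point of the baseline.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    n, p = problem.n, problem.p
    q = problem.design.n_pairs
    ju, ku = _pair_arrays(problem)
    A = np.hstack([problem.X_norm, problem.design.Z])
    y = problem.table.y

    if problem.loss == "logistic":
        from scipy.special import expit

        def sval(eta):
            return float(np.sum(np.logaddexp(0.0, eta) - y * eta) / n)

        def sgrad(eta):
            return (expit(eta) - y) / n

        lip0 = 0.25
    else:

        def sval(eta):
            return float(0.5 * np.sum((eta - y) ** 2) / n)

        def sgrad(eta):
            return (eta - y) / n

        lip0 = 1.0

    if warm_start is not None:
        b0 = float(warm_start.beta0)
        c = np.concatenate(
            [warm_start.beta, warm_start.pair_weights(problem.design.pair_index)]
        )
    else:
        b0 = _intercept_init(problem)
        c = np.zeros(p + q)

    # top singular value of [1, A] via a few power iterations
    rng = np.random.default_rng(0)
    v = rng.standard_normal(1 + p + q)
    sigma2 = 1.0
    for _ in range(8):
        u = v[0] + A @ v[1:]
        v = np.concatenate([[u.sum()], A.T @ u])
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        sigma2 = nv
        v /= nv
    t = 1.0 / max(sigma2 * lip0 / n, 1e-12)

    def full_obj(b0_, c_, eta=None):
        if eta is None:
            eta = b0_ + A @ c_
        return sval(eta) + lam * np.abs(c_).sum()

    Fx = full_obj(b0, c)
    trace = [Fx]
    yb0, yc = b0, c.copy()
    tk = 1.0
    converged = False
    it = 0

    def prox_from(c0_, cc_, step):
        eta_y = c0_ + A @ cc_
        f_y = sval(eta_y)
        u = sgrad(eta_y)
        g0 = u.sum()
        g = A.T @ u
        for _ in range(60):
            n0 = c0_ - step * g0
            nc = _soft(cc_ - step * g, step * lam)
            eta_z = n0 + A @ nc
            f_z = sval(eta_z)
            d0 = n0 - c0_
            dc = nc - cc_
            lin = g0 * d0 + g @ dc
            quad = 0.5 / step * (d0 * d0 + dc @ dc)
            if f_z <= f_y + lin + quad + 1e-12 * max(1.0, abs(f_y)):
                return n0, nc, f_z + lam * np.abs(nc).sum(), step
            step *= 0.5
        raise RuntimeError("backtracking line search failed (divergent loss?)")

    for it in range(1, max_iter + 1):
        z0, zc, Fz, t = prox_from(yb0, yc, t)
        if not np.isfinite(Fz):
            raise RuntimeError("objective diverged to non-finite value")
        if Fz > Fx + 1e-12:
            z0, zc, Fz, t = prox_from(b0, c, t)
            tk = 1.0
        if Fz <= Fx:
            prev0, prevc = b0, c
            b0, c = z0, zc
            F_prev, Fx = Fx, Fz
        else:
            prev0, prevc = b0, c
            F_prev = Fx
        trace.append(Fx)
        tk1 = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        mom = (tk - 1.0) / tk1
        yb0 = b0 + mom * (b0 - prev0)
        yc = c + mom * (c - prevc)
        tk = tk1
        if abs(F_prev - Fx) <= tol * max(1.0, abs(Fx)):
            converged = True
            break

    beta = c[:p]
    w = c[p:]
    Theta = np.zeros((p, p))
    Theta[ju, ku] = w
    Theta[ku, ju] = w
    return HierLassoFit(
        beta0=b0,
        beta_plus=np.maximum(beta, 0.0),
        beta_minus=np.maximum(-beta, 0.0),
        Theta=Theta,
        lam=lam,
        loss=problem.loss,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        feature_names=list(problem.kept_names),
    )


def fit_path(
    problem: HierLassoProblem,
    lambdas: Sequence[float],
    max_iter: int = 5000,
    tol: float = 1e-7,
    fitter=fit_weak_hier_lasso,
) -> list[HierLassoFit]:
    """Warm-started fits along a strictly decreasing penalty grid."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    if lambdas.size > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    fits: list[HierLassoFit] = []
    warm = None
    for lam in lambdas:
        fit = fitter(problem, lam, max_iter=max_iter, tol=tol, warm_start=warm)
        fits.append(fit)
        warm = fit
    return fits


def objective_value(problem: HierLassoProblem, fit: HierLassoFit) -> float:
    """Penalized objective of a fit under this module's declared convention
    (useful for oracle comparisons and warm-start audits)."""
    ju, ku = _pair_arrays(problem)
    w = 0.5 * (fit.Theta[ju, ku] + fit.Theta[ku, ju])
    eta = _eta(problem, fit.beta0, fit.beta, w)
    return _smooth_value(problem, eta) + _penalty(
        fit.lam, fit.beta_plus, fit.beta_minus, fit.Theta
    )


def predict(
    fit: HierLassoFit,
    problem: HierLassoProblem,
    X_new: np.ndarray,
    feature_names: Sequence[str] | None = None,
):
    """Scores, labels (and probabilities for logistic fits) on new data.

    New data is normalized with the training centers/scales — aligned by
    name when ``feature_names`` is given — and the product columns are
    rebuilt with the training interaction normalization.  Labels threshold
    the probability at 0.5 (equivalently the score at 0).
    """
    X_norm_new = apply_normalization(problem.x_params, X_new, feature_names)
    Z_new = interaction_columns_for(
        problem.design.z_norm, problem.design.pair_index, X_norm_new
    )
    w = fit.pair_weights(problem.design.pair_index)
    scores = fit.beta0 + X_norm_new @ fit.beta + Z_new @ w
    labels = (scores > 0).astype(int)
    if fit.loss == "logistic":
        from scipy.special import expit

        return scores, labels, expit(scores)
    return scores, labels, None
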