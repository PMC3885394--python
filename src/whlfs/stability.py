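"""Stability selection with signed stable expectation scores.

For every penalty level in a grid and every one of B random half-size
subsamples (drawn without replacement), the weak hierarchical lasso is
refitted and thresholded.  The stability score S of a feature (or pair) is
the fraction of all (lambda, subsample) runs in which it was selected — a
number in [0, 1].  The stable expectation score E averages the SIGN of the
fitted coefficient over all runs (0 when not selected), so E lies in
[-1, 1] and |E| <= S always: a pair with E near +1 is consistently
selected with a synergistic (positive) weight, E near -1 marks a
consistently redundant (negative) interaction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureTable, pair_name
from .selection import DEFAULT_TAU, select_features
from .solver import fit_weak_hier_lasso, make_problem

logger = logging.getLogger(__name__)


@dataclass
class StabilityConfig:
    """Knobs of a stability-selection run.

    B subsamples per penalty level, a penalty grid, the subsample fraction
    (half by default), the selection threshold tau and the base seed.
    ``aggregate="mean"`` averages selection frequency over the whole
    (lambda, b) grid; ``"max"`` takes, per feature, the maximum frequency
    over lambda (the classic stability-selection rule).
    """

    B: int = 100
    lambdas: np.ndarray | list | None = None
    subsample_fraction: float = 0.5
    tau: float = DEFAULT_TAU
    seed: int = 0
    loss: str = "logistic"
    aggregate: str = "mean"
    solver_max_iter: int = 1000
    solver_tol: float = 1e-6

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0 < self.subsample_fraction < 1):
            raise ValueError("subsample_fraction must be in (0,1)")
        if self.lambdas is not None and len(self.lambdas) == 0:
            raise ValueError("lambda grid must be nonempty")
        if self.aggregate not in ("mean", "max"):
            raise ValueError("aggregate must be 'mean' or 'max'")


@dataclass
class StabilityResult:
    """Per-feature and per-pair stability (S) and signed expectation (E)
    scores, plus the configuration that produced them."""

    feature_names: list[str]
    S_main: np.ndarray
    E_main: np.ndarray
    S_int: np.ndarray  # (p, p) upper-triangular
    E_int: np.ndarray
    config: StabilityConfig
    n_runs: int
    failed_runs: int = 0

    @property
    def p(self) -> int:
        return len(self.feature_names)

    def pair_frame(self) -> pd.DataFrame:
        """All pairs with nonzero S, one row each."""
        ju, ku = np.triu_indices(self.p, k=1)
        mask = self.S_int[ju, ku] > 0
        return pd.DataFrame(
            {
                "feature_j": [self.feature_names[j] for j in ju[mask]],
                "feature_k": [self.feature_names[k] for k in ku[mask]],
                "name": [
                    pair_name(*sorted((self.feature_names[j], self.feature_names[k])))
                    for j, k in zip(ju[mask], ku[mask])
                ],
                "S": self.S_int[ju[mask], ku[mask]],
                "E": self.E_int[ju[mask], ku[mask]],
            }
        )

    def main_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.feature_names, "S": self.S_main, "E": self.E_main}
        )

    def to_json(self) -> str:
        mains = self.main_frame()
        pairs = self.pair_frame()
        return json.dumps(
            {
                "config": {
                    "B": self.config.B,
                    "lambdas": [float(l) for l in (self.config.lambdas or [])],
                    "subsample_fraction": self.config.subsample_fraction,
                    "tau": self.config.tau,
                    "seed": self.config.seed,
                    "loss": self.config.loss,
                    "aggregate": self.config.aggregate,
                },
                "n_runs": self.n_runs,
                "failed_runs": self.failed_runs,
                "main_effects": mains.to_dict(orient="records"),
                "interactions": pairs.to_dict(orient="records"),
            },
            indent=2,
        )


def subsample_indices(
    n: int, fraction: float, rng: np.random.Generator, y: np.ndarray | None = None
) -> np.ndarray:
    """Uniform subsample of floor(fraction*n) distinct indices.

    When ``y`` is given, redraw (up to 100 times) until both outcome
    classes appear in the subsample.
    """
    m = int(np.floor(fraction * n))
    if not (1 <= m < n):
        raise ValueError("fraction*n must give at least 1 and fewer than n samples")
    for _ in range(100):
        idx = rng.choice(n, size=m, replace=False)
        if y is None or len(np.unique(np.asarray(y)[idx])) == 2:
            return np.sort(idx)
    raise RuntimeError("could not draw a subsample containing both classes")


def _run_rng(seed: int, lam_idx: int, b: int) -> np.random.Generator:
    # independent stream per (seed, lambda-index, subsample) so results are
    # invariant to execution order
    return np.random.default_rng(np.random.SeedSequence([seed, lam_idx, b]))


def stability_run(table: FeatureTable, config: StabilityConfig) -> StabilityResult:
    """Run the full stability-selection grid on a feature table."""
    table.require_both_classes()
    lambdas = config.lambdas
    if lambdas is None:
        from .solver import default_lambda_grid

        problem_full = make_problem(table, loss=config.loss)
        lambdas = default_lambda_grid(problem_full)
    lambdas = np.asarray(lambdas, dtype=float)
    config.lambdas = lambdas.tolist()

    p = table.p
    names = list(table.feature_names)
    name_pos = {nm: j for j, nm in enumerate(names)}
    nlam = len(lambdas)
    sel_count = np.zeros(p)
    sign_sum = np.zeros(p)
    sel_count_int = np.zeros((p, p))
    sign_sum_int = np.zeros((p, p))
    # per-lambda counters for the "max" aggregation rule
    sel_count_by_lam = np.zeros((nlam, p))
    sel_count_int_by_lam = np.zeros((nlam, p, p))
    failed = 0
    total = nlam * config.B

    for li, lam in enumerate(lambdas):
        for b in range(config.B):
            rng = _run_rng(config.seed, li, b)
            ok = False
            for attempt in range(2):  # one retry with a fresh subsample
                try:
                    idx = subsample_indices(
                        table.n, config.subsample_fraction, rng, table.y
                    )
                    sub = table.subset(idx)
                    problem = make_problem(sub, loss=config.loss)
                    fit = fit_weak_hier_lasso(
                        problem,
                        lam,
                        max_iter=config.solver_max_iter,
                        tol=config.solver_tol,
                    )
                    ok = True
                    break
                except Exception as exc:  # noqa: BLE001 - logged, run skipped
                    logger.warning(
                        "stability run (lam=%g, b=%d, attempt %d) failed: %s",
                        lam,
                        b,
                        attempt,
                        exc,
                    )
            if not ok:
                failed += 1
                continue
            sel = select_features(fit, config.tau)
            # a subsample's normalization may drop constant columns, so map
            # the fit's indices back to the table's by name
            kept = problem.kept_names
            beta = fit.beta
            for j_local in sel.selected_main:
                j = name_pos[kept[j_local]]
                sel_count[j] += 1
                sel_count_by_lam[li, j] += 1
                sign_sum[j] += np.sign(beta[j_local])
            for j_local, k_local in sel.selected_pairs:
                j = name_pos[kept[j_local]]
                k = name_pos[kept[k_local]]
                if j > k:
                    j, k = k, j
                s = np.sign(
                    fit.Theta[j_local, k_local] + fit.Theta[k_local, j_local]
                )
                sel_count_int[j, k] += 1
                sel_count_int_by_lam[li, j, k] += 1
                sign_sum_int[j, k] += s

    effective = total - failed
    if effective == 0:
        raise RuntimeError("every stability run failed")
    if config.aggregate == "mean":
        S_main = sel_count / effective
        S_int = sel_count_int / effective
    else:  # classic rule: max over lambda of the per-lambda frequency
        S_main = (sel_count_by_lam / config.B).max(axis=0)
        S_int = (sel_count_int_by_lam / config.B).max(axis=0)
    E_main = sign_sum / effective
    E_int = sign_sum_int / effective
    return StabilityResult(
        feature_names=names,
        S_main=S_main,
        E_main=E_main,
        S_int=S_int,
        E_int=E_int,
        config=config,
        n_runs=effective,
        failed_runs=failed,
    )


def top_k_report(
    result: StabilityResult, k_main: int = 12, k_int: int = 34
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked tables of the k most stable mains and interactions.

    Sorted by S descending; ties broken by |E| descending, then by name —
    deterministic and invariant to input feature order.
    """
    mains = result.main_frame()
    mains["absE"] = mains["E"].abs()
    mains = mains.sort_values(
        ["S", "absE", "name"], ascending=[False, False, True]
    ).drop(columns="absE")
    pairs = result.pair_frame()
    pairs["absE"] = pairs["E"].abs()
    pairs = pairs.sort_values(
        ["S", "absE", "name"], ascending=[False, False, True]
    ).drop(columns="absE")
    return mains.head(k_main).reset_index(drop=True), pairs.head(k_int).reset_index(
        drop=True
    )


def top_signed_interactions(
    result: StabilityResult, k: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k positive and top-k negative interactions by E.

    Pairs with E exactly 0 are excluded from both lists.  Each row carries
    the E scores of the two related main effects, so a negative pair with
    two positive mains can be read off directly as a redundancy.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = result.pair_frame()
    e_of = dict(zip(result.feature_names, result.E_main))
    pairs["E_main_j"] = pairs["feature_j"].map(e_of)
    pairs["E_main_k"] = pairs["feature_k"].map(e_of)
    pos = (
        pairs[pairs["E"] > 0]
        .sort_values(["E", "S", "name"], ascending=[False, False, True])
        .head(k)
        .reset_index(drop=True)
    )
    neg = (
        pairs[pairs["E"] < 0]
        .sort_values(["E", "S", "name"], ascending=[True, False, True])
        .head(k)
        .reset_index(drop=True)
    )
    return pos, neg
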