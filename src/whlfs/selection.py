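"""Thresholded feature selection from a weak hierarchical lasso fit (wHLFS).

A fitted model is turned into a selected set by magnitude thresholding:
main effect j is kept when |beta_j| = |beta_plus_j - beta_minus_j| exceeds
tau, and the unordered pair (j, k) when |Theta_jk| + |Theta_kj| exceeds
2*tau (the two row entries of a pair pool their evidence).  Because every
fit obeys the row budgets ||Theta_j||_1 <= beta_plus_j + beta_minus_j, any
selected pair has at least one endpoint with a nonzero main-effect budget,
so the selected set inherits the weak hierarchy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureTable, InteractionDesign, pair_name
from .solver import (
    HierLassoFit,
    HierLassoProblem,
    fit_weak_hier_lasso,
    make_problem,
    predict,
)

logger = logging.getLogger(__name__)

DEFAULT_TAU = 1e-5


@dataclass
class SelectionResult:
    """Selected main effects and pairs at threshold tau."""

    selected_main: list[int]
    selected_pairs: list[tuple[int, int]]
    tau: float
    main_magnitudes: np.ndarray
    pair_magnitudes: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.selected_main) + len(self.selected_pairs)

    def to_frame(self, feature_names: list[str]) -> pd.DataFrame:
        """TSV-friendly listing: name, magnitude, selected flag."""
        rows = []
        for j, nm in enumerate(feature_names):
            rows.append(
                {
                    "name": nm,
                    "kind": "main",
                    "magnitude": float(self.main_magnitudes[j]),
                    "selected": j in set(self.selected_main),
                }
            )
        sel_pairs = set(self.selected_pairs)
        for (j, k), mag in sorted(self.pair_magnitudes.items()):
            rows.append(
                {
                    "name": pair_name(feature_names[j], feature_names[k]),
                    "kind": "interaction",
                    "magnitude": float(mag),
                    "selected": (j, k) in sel_pairs,
                }
            )
        return pd.DataFrame(rows)


def select_features(
    fit: HierLassoFit, tau: float = DEFAULT_TAU, pair_rule: str = "sum"
) -> SelectionResult:
    """Threshold a fit into a hierarchy-obeying selected set.

    ``pair_rule`` is ``"sum"`` (|Theta_jk| + |Theta_kj| > 2 tau, default)
    or ``"max"`` (max of the two entries > tau).
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    beta = fit.beta
    main_mag = np.abs(beta)
    selected_main = np.where(main_mag > tau)[0].tolist()
    budget = fit.beta_plus + fit.beta_minus
    ghost = np.where((main_mag <= tau) & (budget > tau))[0]
    if len(ghost):
        logger.debug(
            "%d feature(s) carry budget but near-zero net effect", len(ghost)
        )
    p = len(beta)
    absT = np.abs(fit.Theta)
    pair_mags = absT + absT.T  # [j,k] = |Theta_jk|+|Theta_kj|
    selected_pairs = []
    pair_magnitudes = {}
    ju, ku = np.triu_indices(p, k=1)
    for j, k in zip(ju.tolist(), ku.tolist()):
        mag = pair_mags[j, k]
        if mag > 0:
            pair_magnitudes[(j, k)] = float(mag)
        if pair_rule == "sum":
            hit = mag > 2 * tau
        elif pair_rule == "max":
            hit = max(absT[j, k], absT[k, j]) > tau
        else:
            raise ValueError(f"unknown pair_rule {pair_rule!r}")
        if hit:
            selected_pairs.append((j, k))
    return SelectionResult(
        selected_main=selected_main,
        selected_pairs=selected_pairs,
        tau=tau,
        main_magnitudes=main_mag,
        pair_magnitudes=pair_magnitudes,
    )


def reduced_design(
    table: FeatureTable,
    problem: HierLassoProblem,
    sel: SelectionResult,
) -> tuple[np.ndarray, list[str]]:
    """Matrix of the selected normalized main columns followed by the
    selected normalized pair columns, with name-based labels."""
    design: InteractionDesign = problem.design
    names = problem.kept_names
    p = problem.p
    for j in sel.selected_main:
        if j >= p:
            raise ValueError(f"selected main index {j} out of range")
    cols = []
    labels = []
    for j in sel.selected_main:
        cols.append(problem.X_norm[:, j])
        labels.append(names[j])
    for j, k in sel.selected_pairs:
        c = design.column_of(j, k)
        cols.append(design.Z[:, c])
        labels.append(pair_name(names[j], names[k]))
    if not cols:
        return np.empty((table.n, 0)), []
    return np.column_stack(cols), labels


class _MajorityClassifier:
    """Fallback when the reduced design is empty: predict the majority
    training class (ties go to class 0)."""

    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.label_ = int(vals[np.argmax(counts)])
        return self

    def predict(self, X):
        return np.full(len(X), self.label_, dtype=int)


def _make_classifier(kind: str, seed: int | None):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC, LinearSVC

    if kind == "linear-svm":
        return LinearSVC()
    if kind == "rbf-svm":
        return SVC(kernel="rbf", gamma="scale")
    if kind == "random-forest":
        return RandomForestClassifier(random_state=seed)
    if kind == "sparse-logistic":
        return LogisticRegression(penalty="l1", solver="liblinear", C=1.0)
    raise ValueError(f"unknown classifier {kind!r}")


@dataclass
class WhlfsPipeline:
    """Fitted wHLFS pipeline: hierarchical-lasso fit, thresholded
    selection, and an optional downstream classifier on the reduced design.

    With ``classifier="none"`` predictions come from the hierarchical-lasso
    fit itself (selection is reporting-only in that mode).
    """

    problem: HierLassoProblem
    fit: HierLassoFit
    selection: SelectionResult
    classifier_kind: str
    classifier: object | None

    def predict(self, X_new: np.ndarray, feature_names=None) -> np.ndarray:
        if self.classifier_kind == "none":
            _, labels, _ = predict(self.fit, self.problem, X_new, feature_names)
            return labels
        M = self._reduced_new(X_new, feature_names)
        return np.asarray(self.classifier.predict(M), dtype=int)

    def _reduced_new(self, X_new, feature_names=None) -> np.ndarray:
        from .data import apply_normalization, interaction_columns_for

        Xn = apply_normalization(self.problem.x_params, X_new, feature_names)
        cols = [Xn[:, j] for j in self.selection.selected_main]
        if self.selection.selected_pairs:
            Zn = interaction_columns_for(
                self.problem.design.z_norm,
                self.problem.design.pair_index,
                Xn,
            )
            for j, k in self.selection.selected_pairs:
                cols.append(Zn[:, self.problem.design.column_of(j, k)])
        if not cols:
            return np.empty((len(np.atleast_2d(X_new)), 0))
        return np.column_stack(cols)


def run_whlfs(
    table: FeatureTable,
    lam: float,
    tau: float = DEFAULT_TAU,
    classifier: str = "none",
    loss: str = "logistic",
    seed: int | None = 0,
    max_iter: int = 5000,
    tol: float = 1e-7,
) -> WhlfsPipeline:
    """Fit-select-classify in one call.

    Fits the weak hierarchical lasso at penalty ``lam``, thresholds at
    ``tau``, then trains ``classifier`` on the reduced design
    (``"none"`` keeps the lasso fit as the predictor; an empty selection
    with a downstream classifier degrades to a majority-class predictor).
    """
    table.require_both_classes()
    problem = make_problem(table, loss=loss)
    fit = fit_weak_hier_lasso(problem, lam, max_iter=max_iter, tol=tol)
    sel = select_features(fit, tau)
    clf = None
    if classifier != "none":
        M, _ = reduced_design(table, problem, sel)
        if M.shape[1] == 0:
            clf = _MajorityClassifier().fit(M, table.y)
        else:
            clf = _make_classifier(classifier, seed).fit(M, table.y)
    return WhlfsPipeline(
        problem=problem,
        fit=fit,
        selection=sel,
        classifier_kind=classifier,
        classifier=clf,
    )
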