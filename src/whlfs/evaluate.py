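"""Benchmark protocol: metrics, splits, inner CV and paired tests.

The evaluation mirrors a standard clinical-prediction benchmark: the
cohort is split 10 times into 9/10 training and 1/10 testing (stratified);
on each training set five-fold cross-validation picks the penalty level;
the method is refitted and scored on the held-out tenth by accuracy,
sensitivity (true-positive rate) and specificity (true-negative rate), all
in percent.  One-sided paired t-tests compare a reference method's
accuracy against each competitor across the splits.

A "method" is a feature-selection stage (none, main-effects lasso,
all-pair lasso, or the weak hierarchical lasso) combined with a
classification stage (the selector's own fit, linear SVM, RBF SVM, random
forest, or sparse logistic regression).  The competing selectors use the
squared loss; the hierarchical selector uses the logistic loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureTable, apply_normalization, interaction_columns_for, normalize_columns
from .selection import (
    DEFAULT_TAU,
    _MajorityClassifier,
    _make_classifier,
    select_features,
)
from .solver import (
    default_lambda_grid,
    fit_all_pair_lasso,
    fit_path,
    make_problem,
)

logger = logging.getLogger(__name__)

SELECTORS = ("none", "lasso", "allpair", "whlfs")
CLASSIFIERS = ("none", "linear-svm", "rbf-svm", "random-forest", "sparse-logistic")


@dataclass(frozen=True)
class MethodSpec:
    """One feature-selection x classifier combination.

    ``use_interactions`` only matters for selector ``"none"``: it switches
    between the raw main-effect features and the full main + pairwise
    product design.
    """

    selector: str = "whlfs"
    classifier: str = "random-forest"
    use_interactions: bool = False

    def __post_init__(self):
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.selector == "none" and self.classifier == "none":
            raise ValueError("selector 'none' needs a classifier")

    @property
    def name(self) -> str:
        base = self.selector
        if self.selector == "none":
            base = "interactions" if self.use_interactions else "raw"
        return base if self.classifier == "none" else f"{base}+{self.classifier}"


def default_method_grid() -> list[MethodSpec]:
    """The full benchmark grid of selector x classifier combinations."""
    grid = [
        MethodSpec("none", "linear-svm"),
        MethodSpec("none", "random-forest"),
        MethodSpec("none", "rbf-svm"),
        MethodSpec("none", "sparse-logistic"),
        MethodSpec("lasso", "none"),
        MethodSpec("lasso", "linear-svm"),
        MethodSpec("lasso", "random-forest"),
        MethodSpec("none", "linear-svm", use_interactions=True),
        MethodSpec("none", "random-forest", use_interactions=True),
        MethodSpec("allpair", "none"),
        MethodSpec("allpair", "linear-svm"),
        MethodSpec("allpair", "random-forest"),
        MethodSpec("whlfs", "none"),
        MethodSpec("whlfs", "linear-svm"),
        MethodSpec("whlfs", "random-forest"),
    ]
    return grid


@dataclass
class EvalProtocol:
    n_outer_splits: int = 10
    inner_folds: int = 5
    n_lambda: int = 16
    lambda_min_ratio: float = 0.01
    tau: float = DEFAULT_TAU
    methods: list[MethodSpec] = field(default_factory=default_method_grid)
    reference: MethodSpec | None = None  # defaults to whlfs+random-forest
    seed: int = 0
    solver_max_iter: int = 1000
    solver_tol: float = 1e-6

    def __post_init__(self):
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if not self.methods:
            raise ValueError("need at least one method")


@dataclass
class EvalResult:
    per_split: pd.DataFrame  # method, split, accuracy, sensitivity, specificity
    summary: pd.DataFrame  # method, mean/sd of each metric
    paired_tests: pd.DataFrame | None  # reference vs each competitor
    protocol: EvalProtocol


# ---------------------------------------------------------------------------
# metrics


def confusion_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """Accuracy, sensitivity and specificity in percent.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).  When a class is
    absent from ``y_true`` the corresponding rate is undefined and
    reported as NaN (never as 0, which would bias averages).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if not (np.all(np.isin(y_true, [0, 1])) and np.all(np.isin(y_pred, [0, 1]))):
        raise ValueError("labels must be binary {0,1}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = len(y_true)
    acc = 100.0 * (tp + tn) / n
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return acc, sens, spec


def outer_splits(
    n: int,
    y: np.ndarray,
    n_splits: int = 10,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified partition into ``n_splits`` folds; each fold serves once
    as the ~n/n_splits test set with the rest for training."""
    from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

    y = np.asarray(y)
    if n < max(n_splits, 2):
        raise ValueError("too few samples for the requested number of splits")
    if n_splits == 1:
        sss = StratifiedShuffleSplit(n_splits=1, test_size=0.1, random_state=seed)
        return [(tr, te) for tr, te in sss.split(np.zeros(n), y)]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(n), y)]


def paired_onesided_ttest(acc1, acc2) -> tuple[float, float, float]:
    """One-sided paired t-test of mean(acc1 - acc2) > 0.

    Returns (mean difference, standard error of the mean difference,
    p-value).  A degenerate all-equal pairing gives p = 0.5 by convention;
    constant nonzero differences give p -> 0 or 1 in the limit.
    """
    acc1 = np.asarray(acc1, dtype=float)
    acc2 = np.asarray(acc2, dtype=float)
    if acc1.shape != acc2.shape or acc1.ndim != 1 or len(acc1) < 2:
        raise ValueError("need equal-length paired vectors of length >= 2")
    d = acc1 - acc2
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(len(d)))
    if se == 0:
        if mean == 0:
            logger.info("identical paired vectors: p = 0.5 by convention")
            return mean, se, 0.5
        logger.info("zero-variance nonzero difference: degenerate limit p")
        return mean, se, 0.0 if mean > 0 else 1.0
    res = stats.ttest_rel(acc1, acc2, alternative="greater")
    return mean, se, float(res.pvalue)


# ---------------------------------------------------------------------------
# method fitting


class _FittedMethod:
    """A trained selection+classification pipeline exposing predict()."""

    def __init__(self, predict_fn, detail=None):
        self._fn = predict_fn
        self.detail = detail or {}

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        return np.asarray(self._fn(X_raw), dtype=int)


def _classifier_or_majority(kind, M, y, seed):
    if M.shape[1] == 0 or len(np.unique(y)) < 2:
        return _MajorityClassifier().fit(M, y)
    return _make_classifier(kind, seed).fit(M, y)


def _fit_method_path(
    train: FeatureTable,
    method: MethodSpec,
    lambdas: Sequence[float] | None,
    tau: float,
    seed: int,
    max_iter: int,
    tol: float,
) -> list[_FittedMethod]:
    """Fit one method at every penalty level of a descending grid (a single
    ``[None]`` grid for penalty-free methods), sharing warm starts."""
    y = train.y

    if method.selector == "none":
        Xn, xp = normalize_columns(train.X, train.feature_names)
        if method.use_interactions:
            from .data import build_interaction_design

            design = build_interaction_design(Xn, xp.kept_names)
            M = np.hstack([Xn, design.Z])

            def transform(X_raw):
                Xt = apply_normalization(xp, X_raw, train.feature_names)
                Zt = interaction_columns_for(design.z_norm, design.pair_index, Xt)
                return np.hstack([Xt, Zt])

        else:
            M = Xn

            def transform(X_raw):
                return apply_normalization(xp, X_raw, train.feature_names)

        clf = _classifier_or_majority(method.classifier, M, y, seed)
        return [_FittedMethod(lambda X, c=clf, t=transform: c.predict(t(X)))]

    if method.selector == "lasso":
        # main-effects-only l1 fit (squared loss), via scikit-learn
        from sklearn.linear_model import Lasso

        Xn, xp = normalize_columns(train.X, train.feature_names)
        out = []
        for lam in lambdas:
            model = Lasso(alpha=lam, fit_intercept=True, max_iter=50000)
            model.fit(Xn, y)
            sel = np.where(np.abs(model.coef_) > tau)[0]
            if method.classifier == "none":
                def fn(X_raw, m=model, xp=xp):
                    Xt = apply_normalization(xp, X_raw, train.feature_names)
                    return (m.predict(Xt) > 0.5).astype(int)
            else:
                Msel = Xn[:, sel]
                clf = _classifier_or_majority(method.classifier, Msel, y, seed)
                def fn(X_raw, c=clf, s=sel, xp=xp):
                    Xt = apply_normalization(xp, X_raw, train.feature_names)
                    return c.predict(Xt[:, s])
            out.append(
                _FittedMethod(fn, {"lambda": lam, "n_selected": len(sel)})
            )
        return out

    # allpair / whlfs share the problem + path machinery
    loss = "logistic" if method.selector == "whlfs" else "squared"
    problem = make_problem(train, loss=loss)
    fitter = fit_all_pair_lasso if method.selector == "allpair" else None
    kwargs = {"max_iter": max_iter, "tol": tol}
    if fitter is not None:
        fits = fit_path(problem, lambdas, fitter=fitter, **kwargs)
    else:
        fits = fit_path(problem, lambdas, **kwargs)

    thresh = 0.5 if loss == "squared" else 0.0
    out = []
    for fit in fits:
        sel = select_features(fit, tau)
        if method.classifier == "none":
            def fn(X_raw, f=fit, pr=problem):
                from .solver import predict as _predict

                scores, _, prob = _predict(f, pr, X_raw, train.feature_names)
                if prob is not None:
                    return (prob > 0.5).astype(int)
                return (scores > thresh).astype(int)
        else:
            from .selection import WhlfsPipeline

            pipe = WhlfsPipeline(
                problem=problem,
                fit=fit,
                selection=sel,
                classifier_kind=method.classifier,
                classifier=None,
            )
            M = pipe._reduced_new(train.X, train.feature_names)
            pipe.classifier = _classifier_or_majority(
                method.classifier, M, y, seed
            )
            def fn(X_raw, p=pipe):
                return p.predict(X_raw, train.feature_names)
        out.append(
            _FittedMethod(fn, {"lambda": fit.lam, "n_selected": sel.n_selected})
        )
    return out


def _method_lambda_grid(
    train: FeatureTable, method: MethodSpec, protocol: EvalProtocol
) -> list:
    if method.selector == "none":
        return [None]
    if method.selector == "lasso":
        Xn, _ = normalize_columns(train.X, train.feature_names)
        y = train.y
        lmax = float(np.abs(Xn.T @ (y - y.mean())).max() / len(y))
        return list(lmax * np.geomspace(1.0, protocol.lambda_min_ratio, protocol.n_lambda))
    loss = "logistic" if method.selector == "whlfs" else "squared"
    problem = make_problem(train, loss=loss)
    return list(
        default_lambda_grid(problem, protocol.n_lambda, protocol.lambda_min_ratio)
    )


def inner_cv_select(
    train: FeatureTable,
    method: MethodSpec,
    lambdas: Sequence[float] | None,
    folds: int = 5,
    seed: int = 0,
    tau: float = DEFAULT_TAU,
    max_iter: int = 1000,
    tol: float = 1e-6,
):
    """Pick the penalty by k-fold CV accuracy on the training set.

    Ties break toward the LARGER penalty (the sparser model).  Methods
    without a penalty return None.
    """
    if lambdas is None or lambdas[0] is None:
        return None
    lambdas = list(lambdas)
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = np.zeros((folds, len(lambdas)))
    for fi, (tr, va) in enumerate(skf.split(np.zeros(train.n), train.y)):
        sub_tr = train.subset(tr)
        sub_va = train.subset(va)
        fitted = _fit_method_path(
            sub_tr, method, lambdas, tau, seed, max_iter, tol
        )
        for li, fm in enumerate(fitted):
            pred = fm.predict(sub_va.X)
            acc[fi, li] = float(np.mean(pred == sub_va.y))
    mean_acc = acc.mean(axis=0)
    # grid is descending, so the first argmax is the largest lambda
    best = int(np.argmax(np.round(mean_acc, 12)))
    return lambdas[best]


def run_lambda_grid(
    table: FeatureTable, method: MethodSpec, protocol: EvalProtocol
) -> pd.DataFrame:
    """Per-(split, lambda) test accuracies with no inner CV.

    Fixing the splits and sweeping the full penalty grid gives
    n_splits x n_lambda result groups (10 x 16 = 160 with the default
    protocol); paired tests between methods can then be run over all
    groups rather than only over the CV-selected fits.
    """
    splits = outer_splits(
        table.n, table.y, protocol.n_outer_splits, seed=protocol.seed
    )
    rows = []
    for si, (tr, te) in enumerate(splits):
        train = table.subset(tr)
        test = table.subset(te)
        grid = _method_lambda_grid(train, method, protocol)
        fitted = _fit_method_path(
            train,
            method,
            grid,
            protocol.tau,
            protocol.seed,
            protocol.solver_max_iter,
            protocol.solver_tol,
        )
        for li, fm in enumerate(fitted):
            pred = fm.predict(test.X)
            acc, sens, spec = confusion_metrics(test.y, pred)
            rows.append(
                {
                    "method": method.name,
                    "split": si,
                    "lambda_index": li,
                    "lambda": grid[li],
                    "accuracy": acc,
                    "sensitivity": sens,
                    "specificity": spec,
                }
            )
    return pd.DataFrame(rows)


def run_benchmark(table: FeatureTable, protocol: EvalProtocol) -> EvalResult:
    """Full benchmark: outer splits x methods with inner-CV penalty choice.

    Per-method failures are recorded (NaN metrics) and the run continues.
    Returns per-split metrics, per-method mean/sd summaries and the paired
    one-sided accuracy tests of the reference method against the rest.
    """
    table.require_both_classes()
    splits = outer_splits(
        table.n, table.y, protocol.n_outer_splits, seed=protocol.seed
    )
    rows = []
    for method in protocol.methods:
        for si, (tr, te) in enumerate(splits):
            train = table.subset(tr)
            test = table.subset(te)
            try:
                grid = _method_lambda_grid(train, method, protocol)
                lam = inner_cv_select(
                    train,
                    method,
                    grid,
                    folds=protocol.inner_folds,
                    seed=protocol.seed,
                    tau=protocol.tau,
                    max_iter=protocol.solver_max_iter,
                    tol=protocol.solver_tol,
                )
                fit_grid = [lam] if lam is not None else [None]
                fm = _fit_method_path(
                    train,
                    method,
                    fit_grid,
                    protocol.tau,
                    protocol.seed,
                    protocol.solver_max_iter,
                    protocol.solver_tol,
                )[0]
                pred = fm.predict(test.X)
                acc, sens, spec = confusion_metrics(test.y, pred)
            except Exception as exc:  # noqa: BLE001 - recorded, run continues
                logger.warning(
                    "method %s failed on split %d: %s", method.name, si, exc
                )
                acc = sens = spec = float("nan")
                lam = None
            rows.append(
                {
                    "method": method.name,
                    "split": si,
                    "lambda": lam,
                    "accuracy": acc,
                    "sensitivity": sens,
                    "specificity": spec,
                }
            )
    per_split = pd.DataFrame(rows)
    summary = (
        per_split.groupby("method")[["accuracy", "sensitivity", "specificity"]]
        .agg(["mean", "std"])
        .reset_index()
    )

    paired = None
    if len(protocol.methods) >= 2:
        ref = protocol.reference
        if ref is None:
            whlfs_rf = [
                m
                for m in protocol.methods
                if m.selector == "whlfs" and m.classifier == "random-forest"
            ]
            ref = whlfs_rf[0] if whlfs_rf else protocol.methods[0]
        ref_acc = per_split.loc[
            per_split["method"] == ref.name, "accuracy"
        ].to_numpy()
        test_rows = []
        for method in protocol.methods:
            if method.name == ref.name:
                continue
            other = per_split.loc[
                per_split["method"] == method.name, "accuracy"
            ].to_numpy()
            ok = np.isfinite(ref_acc) & np.isfinite(other)
            if ok.sum() < 2:
                continue
            mean, se, p = paired_onesided_ttest(ref_acc[ok], other[ok])
            test_rows.append(
                {
                    "method1": ref.name,
                    "method2": method.name,
                    "mean_diff": mean,
                    "se": se,
                    "p_value": p,
                }
            )
        paired = pd.DataFrame(test_rows) if test_rows else None

    return EvalResult(
        per_split=per_split, summary=summary, paired_tests=paired, protocol=protocol
    )
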