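"""Feature tables, column normalization and the pairwise interaction design.

The pipeline's data model is a samples x features matrix ``X`` with named,
typed columns, a binary outcome ``y`` (internally coded {0, 1}) and an
optional per-feature group label (e.g. ``"M"`` for MRI morphometry and
``"E"`` for meta/cognitive features).  Interaction features are the
elementwise products of every unordered pair of normalized main columns,
re-normalized the same way, collected in an ``InteractionDesign``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Named feature matrix with a binary outcome.

    Attributes
    ----------
    X : (n, p) float array
        Feature values, one row per sample.
    feature_names : list of str
        Unique column names, length p.
    feature_groups : list of str
        Per-feature group label (same length as ``feature_names``).
    y : (n,) int array
        Outcome coded {0, 1}.
    label_mapping : dict
        Original outcome value -> internal {0, 1} code.
    """

    X: np.ndarray
    feature_names: list[str]
    feature_groups: list[str]
    y: np.ndarray
    label_mapping: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match X columns")
        if len(self.feature_groups) != self.X.shape[1]:
            raise ValueError("feature_groups length does not match X columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length does not match X rows")
        if not np.all(np.isin(self.y, [0, 1])):
            raise ValueError("y must be coded {0,1} internally")
        if not np.all(np.isfinite(self.X)):
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                f"non-finite feature value at row {bad[0]}, "
                f"column {self.feature_names[bad[1]]!r}"
            )

    def require_both_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise ValueError("outcome contains a single class; fitting requires both")

    def subset(self, idx: Sequence[int]) -> "FeatureTable":
        """Row subset (used by subsampling and cross-validation splits)."""
        idx = np.asarray(idx)
        return FeatureTable(
            X=self.X[idx],
            feature_names=list(self.feature_names),
            feature_groups=list(self.feature_groups),
            y=self.y[idx],
            label_mapping=dict(self.label_mapping),
        )


@dataclass
class NormalizationParams:
    """Per-column centering/scaling learned on training data.

    ``kept_names`` records which columns survived (constant columns are
    dropped); re-applying the transform aligns new data by name.
    """

    center: np.ndarray
    scale: np.ndarray
    kept_names: list[str]
    dropped_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("all scales must be positive")


@dataclass
class InteractionDesign:
    """All unordered-pair product features of a normalized matrix.

    ``Z`` has exactly p(p-1)/2 columns; ``pair_index[c] == (j, k)`` with
    ``j < k`` maps column c of Z back to the main-effect columns whose
    normalized product it holds (re-normalized via ``z_norm``).
    """

    Z: np.ndarray
    pair_index: list[tuple[int, int]]
    z_norm: NormalizationParams
    pair_names: list[str]

    @property
    def n_pairs(self) -> int:
        return self.Z.shape[1]

    def column_of(self, j: int, k: int) -> int:
        if j > k:
            j, k = k, j
        return self._lookup[(j, k)]

    def pair_frame(self) -> "pd.DataFrame":
        """TSV-friendly listing of the pair index: column, j, k, name."""
        return pd.DataFrame(
            {
                "column": range(self.n_pairs),
                "j": [j for j, _ in self.pair_index],
                "k": [k for _, k in self.pair_index],
                "name": self.pair_names,
            }
        )

    def __post_init__(self) -> None:
        self._lookup = {pair: c for c, pair in enumerate(self.pair_index)}


def load_feature_table(
    path: str | Path,
    outcome_column: str,
    group_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> FeatureTable:
    """Read a delimited text file (CSV/TSV with header) into a FeatureTable.

    The outcome column must hold exactly two distinct values; {0,1} and
    {-1,+1} are mapped to the internal {0,1} coding directly (the larger
    original value becomes 1), any other pair is mapped by sort order with
    the mapping recorded on the table.

    Parameters
    ----------
    path : str or Path
    outcome_column : str
        Name of the outcome column in the header.
    group_map : mapping, optional
        feature name -> group label; unknown features default to ``"?"``.
    sep : str, optional
        Field delimiter; inferred from the file extension when omitted
        (``.tsv`` -> tab, otherwise comma).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if outcome_column not in df.columns:
        raise ValueError(f"outcome column {outcome_column!r} not found in {path}")
    y_raw = df[outcome_column]
    features = df.drop(columns=[outcome_column])
    if features.columns.duplicated().any():
        dupes = features.columns[features.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dupes}")

    # reject missing / non-numeric cells with a row/column report
    for col in features.columns:
        vals = pd.to_numeric(features[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"missing or non-numeric value at row {bad[0]}, column {col!r}"
            )
        features[col] = vals
    if y_raw.isna().any():
        row = y_raw.index[y_raw.isna()][0]
        raise ValueError(f"missing outcome at row {row}")

    classes = sorted(pd.unique(y_raw))
    if len(classes) != 2:
        raise ValueError(
            f"outcome column must have exactly two distinct values, got {classes}"
        )
    mapping = {classes[0]: 0, classes[1]: 1}
    y = y_raw.map(mapping).to_numpy(dtype=int)

    names = list(features.columns)
    groups = [group_map.get(nm, "?") if group_map else "?" for nm in names]
    return FeatureTable(
        X=features.to_numpy(dtype=float),
        feature_names=names,
        feature_groups=groups,
        y=y,
        label_mapping=mapping,
    )


def normalize_columns(
    X: np.ndarray, names: Sequence[str] | None = None
) -> tuple[np.ndarray, NormalizationParams]:
    """Z-score every column to mean 0, standard deviation 1 (population sd).

    Constant columns carry no information and would produce a zero scale;
    they are dropped with a logged warning.  Requires n >= 2.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, p = X.shape
    if n < 2:
        raise ValueError("normalization requires at least 2 samples")
    if names is None:
        names = [f"f{j}" for j in range(p)]
    names = list(names)

    center = X.mean(axis=0)
    scale = X.std(axis=0)  # population sd (ddof=0)
    keep = scale > 0
    if not np.any(keep):
        raise ValueError("all columns are constant; nothing to normalize")
    dropped = [names[j] for j in range(p) if not keep[j]]
    if dropped:
        logger.warning("dropping %d constant column(s): %s", len(dropped), dropped)
    params = NormalizationParams(
        center=center[keep],
        scale=scale[keep],
        kept_names=[names[j] for j in range(p) if keep[j]],
        dropped_names=dropped,
    )
    X_norm = (X[:, keep] - params.center) / params.scale
    return X_norm, params


def apply_normalization(
    params: NormalizationParams,
    X_new: np.ndarray,
    names: Sequence[str] | None = None,
) -> np.ndarray:
    """Apply training-set centers/scales to new data (no refitting).

    When ``names`` is given, columns are aligned by name against
    ``params.kept_names`` (so columns dropped at fit time are ignored);
    otherwise the column count must match ``params`` exactly.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if names is not None:
        names = list(names)
        try:
            cols = [names.index(nm) for nm in params.kept_names]
        except ValueError as exc:
            raise ValueError(f"column required by normalization missing: {exc}")
        X_new = X_new[:, cols]
    if X_new.shape[1] != len(params.center):
        raise ValueError(
            f"expected {len(params.center)} columns, got {X_new.shape[1]}"
        )
    return (X_new - params.center) / params.scale


def denormalize(params: NormalizationParams, X_norm: np.ndarray) -> np.ndarray:
    """Invert :func:`normalize_columns` on the retained columns."""
    return np.asarray(X_norm, dtype=float) * params.scale + params.center


def pair_name(name_j: str, name_k: str) -> str:
    return f"{name_j}×{name_k}"


def build_interaction_design(
    X_norm: np.ndarray, feature_names: Sequence[str] | None = None
) -> InteractionDesign:
    """Build all p(p-1)/2 pairwise product columns of a normalized matrix.

    Each product column is itself normalized with the same z-scoring as the
    main columns.  A product column can be constant (e.g. when two columns
    are exactly proportional with n=2); such columns are kept with a unit
    scale rather than dropped so that the pair index stays a bijection onto
    all unordered pairs.
    """
    X_norm = np.asarray(X_norm, dtype=float)
    n, p = X_norm.shape
    if p < 2:
        raise ValueError("interaction design requires at least 2 features")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    ju, ku = np.triu_indices(p, k=1)
    Zraw = X_norm[:, ju] * X_norm[:, ku]
    center = Zraw.mean(axis=0)
    scale = Zraw.std(axis=0)
    degenerate = scale <= 0
    if np.any(degenerate):
        logger.warning(
            "%d constant interaction column(s) kept with unit scale",
            int(degenerate.sum()),
        )
        scale = np.where(degenerate, 1.0, scale)
    pairs = list(zip(ju.tolist(), ku.tolist()))
    names = [pair_name(feature_names[j], feature_names[k]) for j, k in pairs]
    z_norm = NormalizationParams(
        center=center, scale=scale, kept_names=names, dropped_names=[]
    )
    Z = (Zraw - center) / scale
    return InteractionDesign(Z=Z, pair_index=pairs, z_norm=z_norm, pair_names=names)


def interaction_columns_for(
    design_params: NormalizationParams,
    pair_index: list[tuple[int, int]],
    X_norm_new: np.ndarray,
) -> np.ndarray:
    """Product columns for new (already normalized) data, using training
    interaction normalization."""
    ju = np.array([j for j, _ in pair_index])
    ku = np.array([k for _, k in pair_index])
    Zraw = X_norm_new[:, ju] * X_norm_new[:, ku]
    return (Zraw - design_params.center) / design_params.scale
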