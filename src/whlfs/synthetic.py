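"""Synthetic cohorts with planted hierarchical interaction structure.

Generates feature tables that mimic the statistical shape of a clinical
conversion-prediction cohort: correlated feature blocks (a large
imaging-like block and a small clinical-score-like block), a sparse set of
true main effects, and a few true pairwise interactions that obey the weak
hierarchy (every planted pair has at least one endpoint with a nonzero
main effect).  Outcomes are Bernoulli draws from a logistic model on the
standardized features (or Gaussian, for squared-loss work).

Three named scenarios cover the archetypes the pipeline is meant to
detect: a generic sparse-recovery cohort, a synergistic pair (two modest
positive mains whose co-occurrence is strongly predictive), and a
redundant pair (two strong positive mains whose interaction is negative —
knowing both adds less than the sum of the parts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import FeatureTable


@dataclass
class SyntheticSpec:
    """Generator parameters.

    Effects are specified on the standardized feature scale (features are
    unit-variance by construction), so they survive the pipeline's
    z-scoring unchanged up to sampling noise.
    """

    n: int = 400
    p: int = 30
    block_fractions: tuple = (0.85, 0.15)  # imaging-like vs clinical-like
    rho: float = 0.2  # within-block equicorrelation
    true_beta: dict = field(default_factory=dict)  # index -> weight
    true_pairs: list = field(default_factory=list)  # (j, k, weight)
    outcome: str = "binary-logistic"  # or "gaussian"
    noise_sd: float = 1.0
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.p < 2:
            raise ValueError("need n >= 2 and p >= 2")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.outcome not in ("binary-logistic", "gaussian"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if abs(sum(self.block_fractions) - 1.0) > 1e-9:
            raise ValueError("block fractions must sum to 1")
        nonzero = {j for j, w in self.true_beta.items() if w != 0}
        for j, k, w in self.true_pairs:
            if not (0 <= j < self.p and 0 <= k < self.p and j != k):
                raise ValueError(f"invalid pair ({j},{k})")
            if j not in nonzero and k not in nonzero:
                raise ValueError(
                    f"pair ({j},{k}) violates weak hierarchy: neither endpoint "
                    "has a nonzero main effect"
                )


def _block_sizes(spec: SyntheticSpec) -> list[int]:
    sizes = [int(round(f * spec.p)) for f in spec.block_fractions]
    sizes[-1] = spec.p - sum(sizes[:-1])
    return [s for s in sizes if s > 0]


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, dict]:
    """Draw one cohort; returns the table and the ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    sizes = _block_sizes(spec)
    cols = []
    groups = []
    labels = ["M", "E", "G", "H"]
    for bi, size in enumerate(sizes):
        shared = rng.standard_normal((spec.n, 1))
        own = rng.standard_normal((spec.n, size))
        block = np.sqrt(spec.rho) * shared + np.sqrt(1 - spec.rho) * own
        cols.append(block)
        groups.extend([labels[min(bi, len(labels) - 1)]] * size)
    X = np.hstack(cols)

    beta = np.zeros(spec.p)
    for j, w in spec.true_beta.items():
        beta[j] = w
    eta = spec.intercept + X @ beta
    for j, k, w in spec.true_pairs:
        eta = eta + w * X[:, j] * X[:, k]

    if spec.outcome == "binary-logistic":
        y = (rng.random(spec.n) < expit(eta)).astype(int)
    else:
        y_cont = eta + spec.noise_sd * rng.standard_normal(spec.n)
        y = (y_cont > np.median(y_cont)).astype(int)  # binarized for the table
    names = [f"{groups[j]}{j:03d}" for j in range(spec.p)]
    table = FeatureTable(
        X=X, feature_names=names, feature_groups=groups, y=y,
        label_mapping={0: 0, 1: 1},
    )
    truth = {
        "beta": {names[j]: float(w) for j, w in spec.true_beta.items()},
        "pairs": [
            {"j": names[j], "k": names[k], "weight": float(w)}
            for j, k, w in spec.true_pairs
        ],
        "main_indices": sorted(j for j, w in spec.true_beta.items() if w != 0),
        "pair_indices": [(min(j, k), max(j, k)) for j, k, _ in spec.true_pairs],
        "intercept": spec.intercept,
        "seed": spec.seed,
    }
    return table, truth


def generic_scenario(seed: int = 0, n: int = 400, p: int = 30) -> tuple[FeatureTable, dict]:
    """Sparse-recovery cohort: 4 true mains, 2 hierarchy-obeying pairs,
    all standardized effects >= 0.5."""
    spec = SyntheticSpec(
        n=n,
        p=p,
        true_beta={0: 1.0, 1: 0.9, 2: -0.9, 3: 0.7},
        true_pairs=[(0, 4, 0.9), (2, 5, -0.8)],
        seed=seed,
    )
    return generate(spec)


def synergistic_scenario(seed: int = 0) -> tuple[FeatureTable, dict]:
    """Two positive mains — one moderate, one weak — whose co-occurrence is
    strongly predictive (planted pair weight > 0)."""
    spec = SyntheticSpec(
        n=400,
        p=20,
        true_beta={0: 0.8, 1: 0.2},
        true_pairs=[(0, 1, 1.0)],
        seed=seed,
    )
    return generate(spec)


def redundant_scenario(seed: int = 0) -> tuple[FeatureTable, dict]:
    """Two strong positive mains whose interaction is negative: either
    feature alone carries most of the signal, so the pair is redundant."""
    spec = SyntheticSpec(
        n=400,
        p=20,
        true_beta={0: 1.0, 1: 1.0},
        true_pairs=[(0, 1, -0.8)],
        seed=seed,
    )
    return generate(spec)


def interaction_dominant_scenario(seed: int = 0) -> tuple[FeatureTable, dict]:
    """Cohort where pairwise interactions carry most of the signal: two
    modest positive mains plus two strong hierarchy-obeying pairs (one
    synergistic, one redundant).  This is the regime where explicit product
    features should separate interaction-aware pipelines from
    main-effects-only ones."""
    spec = SyntheticSpec(
        n=400,
        p=15,
        true_beta={0: 0.5, 1: 0.5},
        true_pairs=[(0, 2, 1.3), (1, 3, -1.3)],
        seed=seed,
    )
    return generate(spec)


def write_csv(table: FeatureTable, truth: dict, csv_path, truth_path=None) -> None:
    """Write the cohort as a CSV consumable by :func:`load_feature_table`
    (outcome column ``"converter"``) and the truth as JSON."""
    df = pd.DataFrame(table.X, columns=table.feature_names)
    df["converter"] = table.y
    Path(csv_path).write_text(df.to_csv(index=False))
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=2))
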