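import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from whlfs.data import FeatureTable


def random_table(rng, n=30, p=5):
    """Small random feature table with both outcome classes present."""
    X = rng.standard_normal((n, p))
    y = rng.integers(0, 2, n)
    while len(np.unique(y)) < 2:
        y = rng.integers(0, 2, n)
    return FeatureTable(
        X=X,
        feature_names=[f"f{j}" for j in range(p)],
        feature_groups=["M"] * p,
        y=y,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    return random_table(rng)


@pytest.fixture
def tiny_csv(tmp_path):
    path = tmp_path / "tiny.csv"
    path.write_text(
        "a,b,converter\n1.0,2.0,0\n2.0,1.0,1\n3.0,4.0,0\n4.0,3.0,1\n"
    )
    return path
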