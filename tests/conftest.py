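import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from dpsample import DataTable


@pytest.fixture(scope="session")
def iris_table() -> DataTable:
    """The classic 150 x 4 three-class iris table."""
    from sklearn.datasets import load_iris

    iris = load_iris()
    return DataTable(
        values=iris.data,
        labels=iris.target,
        feature_names=tuple(iris.feature_names),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture()
def two_class_toy() -> DataTable:
    """Two classes of 4 rows each: small enough to enumerate all
    class-proportional subsets of size 4 (C(4,2)^2 = 36)."""
    r = np.random.default_rng(42)
    values = np.concatenate([r.normal(0.0, 1.0, 4), r.normal(3.0, 1.0, 4)])
    labels = np.repeat([0, 1], 4)
    return DataTable(values=values.reshape(-1, 1), labels=labels, feature_names=("x",))
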