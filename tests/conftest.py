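import numpy as np
import pandas as pd
import pytest

from forestbeta.io import DistanceMatrix, StemCensus, TraitTable


@pytest.fixture
def toy_delta():
    """Three species with d(A,B)=2, d(A,C)=d(B,C)=4 (ultrametric)."""
    return DistanceMatrix(
        ["A", "B", "C"],
        np.array([[0.0, 2.0, 4.0],
                  [2.0, 0.0, 4.0],
                  [4.0, 4.0, 0.0]]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_delta(n, rng, labels=None):
    """Random metric-ish distance matrix (symmetric, zero diagonal)."""
    x = rng.uniform(0, 5, size=(n, 3))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels or [f"s{i}" for i in range(n)], d)


@pytest.fixture
def small_census():
    stems = pd.DataFrame({
        "stem_id": [f"t{i}" for i in range(6)],
        "species": ["A", "A", "A", "B", "B", "C"],
        "x": [1.0, 2.0, 3.0, 12.0, 15.0, 25.0],
        "y": [1.0, 2.0, 3.0, 5.0, 8.0, 15.0],
    })
    return StemCensus(stems, width=30.0, height=20.0)


@pytest.fixture
def trait_table():
    rng = np.random.default_rng(7)
    species = [f"sp{i:02d}" for i in range(12)]
    data = rng.standard_normal((12, 5))
    return TraitTable(pd.DataFrame(
        data, index=pd.Index(species, name="species"),
        columns=[f"trait{i}" for i in range(1, 6)]))
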