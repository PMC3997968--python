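import numpy as np
import pandas as pd
import pytest

from stabref import NormalizedCountMatrix, RawCountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_counts():
    """Two-sample matrix with totals 1000 and 2000 for hand-checked scaling."""
    return RawCountMatrix(
        pd.DataFrame(
            {"s1": [100, 600, 300], "s2": [300, 1200, 500]},
            index=["x", "y", "z"],
        )
    )


@pytest.fixture
def quantity_matrix(rng):
    """Random positive genes x samples matrix for geNorm checks."""

    def make(n_genes=5, n_samples=8, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        q = np.exp(r.normal(0.0, 0.7, (n_genes, n_samples)))
        return pd.DataFrame(
            q,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )

    return make


@pytest.fixture
def norm_from_linear():
    """Wrap an already-normalized linear matrix without renormalizing."""

    def make(data: dict, index):
        return NormalizedCountMatrix(linear=pd.DataFrame(data, index=index))

    return make
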