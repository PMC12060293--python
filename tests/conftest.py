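import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from nichetraj import simulate_dataset1
from nichetraj.niche import build_niche_graphs


@pytest.fixture(scope="session")
def dataset1_small():
    """A 300-cell circular benchmark; small enough for fast graph tests."""
    return simulate_dataset1(n_cells=300, seed=0)


@pytest.fixture(scope="session")
def graphs_small(dataset1_small):
    return build_niche_graphs(dataset1_small.cells, k=20, sigma_rank=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cell_table(rng, n=60, n_types=4, samples=("s0",)):
    """A random but valid cell table used by several unit tests."""
    types = [chr(ord("A") + i) for i in range(n_types)]
    return pd.DataFrame(
        {
            "Cell_ID": [f"c{i}" for i in range(n)],
            "Sample": rng.choice(list(samples), n),
            "Cell_Type": rng.choice(types, n),
            "x": rng.uniform(0, 10, n),
            "y": rng.uniform(0, 10, n),
        }
    )


def random_adjacency(rng, n, p=0.3):
    """Random symmetric binary adjacency with zero diagonal."""
    a = (rng.uniform(size=(n, n)) < p).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    return sparse.csr_matrix(a)


def random_row_stochastic(rng, n, k):
    c = rng.uniform(0.01, 1.0, (n, k))
    return c / c.sum(axis=1, keepdims=True)
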