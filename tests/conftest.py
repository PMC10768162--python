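import numpy as np
import pytest

from tspgnn.connectome import ConnectivityMatrix, SparseGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_correlation(n: int, rng: np.random.Generator) -> ConnectivityMatrix:
    """A valid random correlation matrix via a Gaussian factor model."""
    a = rng.normal(size=(n, max(2, n // 2)))
    c = np.corrcoef(a)
    return ConnectivityMatrix(c)


def random_binary_graph(n: int, p: float, rng: np.random.Generator) -> SparseGraph:
    a = (rng.uniform(size=(n, n)) < p).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    return SparseGraph(a, density=float(np.triu(a, 1).sum() / (n * (n - 1) / 2)))


def random_weighted_graph(n: int, p: float, rng: np.random.Generator) -> SparseGraph:
    mask = np.triu((rng.uniform(size=(n, n)) < p), 1)
    w = np.where(mask, rng.uniform(0.1, 1.0, size=(n, n)), 0.0)
    w = w + w.T
    return SparseGraph(w, density=float(mask.sum() / (n * (n - 1) / 2)))
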