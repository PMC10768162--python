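"""Functional-connectivity matrices and their graph sparsifications.

A connectome is represented as a symmetric region-by-region Pearson
correlation matrix (:class:`ConnectivityMatrix`). Edge features used by the
decoding stage are the upper-triangle vectorization of this matrix; sparse
graphs used by the graph-theory stage are obtained by proportional
thresholding, with the retained density chosen by cost-efficiency
(global efficiency minus wiring cost).

Conventions, stated once and used everywhere:

* node indices are 0-based;
* edge order is upper triangle (i < j), row-major;
* negative correlations are zeroed before any graph-metric computation,
  while signed values are preserved for regression/classification features;
* weighted shortest-path length uses distance = 1 / weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "EdgeVector",
    "SparseGraph",
    "compute_fc",
    "vectorize",
    "devectorize",
    "threshold_graph",
    "global_efficiency",
    "optimize_density",
    "DEFAULT_DENSITY_GRID",
]

#: Default sparsity grid for cost-efficiency optimization: 5%..50% step 5%.
DEFAULT_DENSITY_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))

_SYMMETRY_TOL = 1e-10
_LOAD_SYMMETRY_TOL = 1e-8


def _default_node_ids(n: int) -> list[str]:
    return [f"n{i}" for i in range(n)]


@dataclass
class TimeSeriesMatrix:
    """A T x N matrix of regional time series (rows = timepoints)."""

    values: np.ndarray
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (timepoints x regions) array")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.node_ids is None:
            self.node_ids = _default_node_ids(self.values.shape[1])
        if len(self.node_ids) != self.values.shape[1]:
            raise ValueError("node_ids length does not match number of regions")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N correlation matrix with unit diagonal."""

    values: np.ndarray
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("connectivity matrix is not symmetric within 1e-10")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 1.0)
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < -1.0 - 1e-9 or off.max() > 1.0 + 1e-9):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)
        np.fill_diagonal(self.values, 1.0)
        if self.node_ids is None:
            self.node_ids = _default_node_ids(v.shape[0])
        if len(self.node_ids) != v.shape[0]:
            raise ValueError("node_ids length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeVector:
    """Upper-triangle (i<j, row-major) vectorization of a connectivity matrix."""

    values: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        expect = self.n_nodes * (self.n_nodes - 1) // 2
        if self.values.size != expect:
            raise ValueError(
                f"edge vector length {self.values.size} does not match "
                f"N(N-1)/2 = {expect} for N = {self.n_nodes}"
            )


@dataclass
class SparseGraph:
    """Nonnegative adjacency after proportional thresholding."""

    adjacency: np.ndarray
    density: float
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12, rtol=0.0):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if a.min() < 0:
            raise ValueError("adjacency must be nonnegative")
        self.adjacency = a
        if not self.node_ids:
            self.node_ids = _default_node_ids(a.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))


def compute_fc(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation matrix between the time series of each node pair.

    Raises
    ------
    ValueError
        If fewer than 3 timepoints are available or any region has a
        constant time series (zero variance), naming the offending node.
    """
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints to estimate correlations")
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time series for node '{ts.node_ids[bad[0]]}'")
    c = np.corrcoef(x, rowvar=False)
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(c, list(ts.node_ids))


def vectorize(c: ConnectivityMatrix) -> EdgeVector:
    """Extract the upper triangle (i<j, row-major) as a flat edge vector."""
    iu = np.triu_indices(c.n_nodes, k=1)
    return EdgeVector(c.values[iu], c.n_nodes)


def devectorize(v: EdgeVector | np.ndarray, n_nodes: int | None = None) -> ConnectivityMatrix:
    """Rebuild the symmetric unit-diagonal matrix from an edge vector."""
    if isinstance(v, EdgeVector):
        vals, n = v.values, v.n_nodes
    else:
        vals = np.asarray(v, dtype=float).ravel()
        if n_nodes is None:
            # solve m = n(n-1)/2 for n
            n = int(round((1 + np.sqrt(1 + 8 * vals.size)) / 2))
        else:
            n = n_nodes
        if n * (n - 1) // 2 != vals.size:
            raise ValueError(f"length {vals.size} is not a triangular number for N = {n}")
    m = np.eye(n)
    iu = np.triu_indices(n, k=1)
    m[iu] = vals
    m[(iu[1], iu[0])] = vals
    return ConnectivityMatrix(m)


def edge_index_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """Node-pair (i, j), i<j, for each position of the edge vector."""
    iu = np.triu_indices(n_nodes, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def threshold_graph(
    c: ConnectivityMatrix,
    density: float,
    mode: Literal["binary", "weighted"] = "weighted",
) -> SparseGraph:
    """Proportional threshold: keep the strongest ``density`` fraction of edges.

    Negative correlations are zeroed first (they never enter graph metrics),
    then the top ``round(density * N(N-1)/2)`` edges by weight are retained.
    Ties at the cutoff are broken by (i, j) lexicographic order.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    if mode not in ("binary", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    n = c.n_nodes
    w = np.where(c.values > 0, c.values, 0.0)
    np.fill_diagonal(w, 0.0)
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    m_total = vals.size
    k = int(round(density * m_total))
    if k == 0:
        raise ValueError(f"density {density} retains zero of {m_total} edges")
    # sort by (-weight, i, j): strongest first, lexicographic tie-break
    order = np.lexsort((iu[1], iu[0], -vals))
    keep = order[:k]
    keep = keep[vals[keep] > 0]  # never create zero-weight edges
    adj = np.zeros((n, n))
    ii, jj = iu[0][keep], iu[1][keep]
    adj[ii, jj] = 1.0 if mode == "binary" else vals[keep]
    adj = adj + adj.T
    return SparseGraph(adj, density, list(c.node_ids))


def _distance_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Edge lengths for shortest-path metrics: 1/weight, inf where no edge."""
    with np.errstate(divide="ignore"):
        d = np.where(adjacency > 0, 1.0 / adjacency, np.inf)
    np.fill_diagonal(d, 0.0)
    return d


def global_efficiency(g: SparseGraph | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Binary graphs use hop counts; weighted graphs use edge length 1/weight.
    Unreachable pairs contribute 0, so the value lies in [0, 1] for binary
    graphs and is 1 exactly on a complete binary graph.
    """
    adj = g.adjacency if isinstance(g, SparseGraph) else np.asarray(g, dtype=float)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = shortest_path(_distance_matrix(adj), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def optimize_density(
    c: ConnectivityMatrix,
    grid: Sequence[float] = DEFAULT_DENSITY_GRID,
) -> tuple[SparseGraph, float]:
    """Pick the grid density maximizing cost-efficiency on the binary graph.

    Cost-efficiency = global_efficiency(binary graph at density d) - d.
    Raw efficiency is trivially maximal at full density, so the wiring-cost
    penalty is what makes the optimum informative. Ties go to the smaller
    density; densities whose threshold retains no edges score efficiency 0.
    """
    grid = sorted(set(float(d) for d in grid))
    if not grid:
        raise ValueError("density grid must be non-empty")
    best_d, best_score = None, -np.inf
    for d in grid:
        try:
            g = threshold_graph(c, d, mode="binary")
            eff = global_efficiency(g)
        except ValueError:
            eff = 0.0
        score = eff - d
        if score > best_score + 1e-15:
            best_d, best_score = d, score
    assert best_d is not None
    try:
        chosen = threshold_graph(c, best_d, mode="binary")
    except ValueError:
        chosen = SparseGraph(np.zeros_like(c.values), best_d, list(c.node_ids))
    return chosen, best_d


# ---------------------------------------------------------------------------
# TSV round trip. All matrix files carry a header row of node ids; loading a
# matrix that is asymmetric beyond 1e-8 fails.
# ---------------------------------------------------------------------------

def save_matrix_tsv(path: str | Path, values: np.ndarray, node_ids: Sequence[str]) -> None:
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write("\t".join(node_ids) + "\n")
        for row in values:
            fh.write("\t".join(format(v, ".10g") for v in row) + "\n")


def load_connectivity_tsv(path: str | Path) -> ConnectivityMatrix:
    with open(path) as fh:
        node_ids = fh.readline().rstrip("\n").split("\t")
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square {values.shape}")
    asym = float(np.abs(values - values.T).max())
    if asym > _LOAD_SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix asymmetric (max |A - A^T| = {asym:.3g})")
    return ConnectivityMatrix(0.5 * (values + values.T), node_ids)


def save_timeseries_tsv(path: str | Path, ts: TimeSeriesMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ts.node_ids) + "\n")
        for row in ts.values:
            fh.write("\t".join(format(v, ".10g") for v in row) + "\n")


def load_timeseries_tsv(path: str | Path) -> TimeSeriesMatrix:
    with open(path) as fh:
        node_ids = fh.readline().rstrip("\n").split("\t")
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return TimeSeriesMatrix(values, node_ids)
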