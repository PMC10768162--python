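"""Node-level graph-theory measures on sparsified connectomes.

Eight measures are provided: strength, clustering coefficient, local
efficiency, PageRank centrality, betweenness centrality, eigenvector
centrality, flow coefficient, and k-coreness. All except the flow
coefficient (defined only for binary graphs) come in a binary and a
weighted variant, giving the default 15-column node attribute table.

Weighted conventions follow the Brain Connectivity Toolbox: Onnela
clustering with weights normalized by the maximum weight, shortest-path
distance 1/weight for betweenness and efficiency, PageRank damping 0.85.
The weighted k-coreness is the s-core value (weighted-degree core
decomposition), which is real-valued; the binary k-coreness is an integer.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .connectome import SparseGraph, global_efficiency, _distance_matrix

__all__ = [
    "strength",
    "clustering_coefficient",
    "local_efficiency",
    "pagerank_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "flow_coefficient",
    "kcoreness_centrality",
    "score_centrality",
    "metric_table",
    "DEFAULT_COLUMNS",
]

#: Deterministic column order of the default 15-attribute table.
DEFAULT_COLUMNS: tuple[str, ...] = (
    "strength_bin",
    "strength_wt",
    "clustering_bin",
    "clustering_wt",
    "local_efficiency_bin",
    "local_efficiency_wt",
    "pagerank_bin",
    "pagerank_wt",
    "betweenness_bin",
    "betweenness_wt",
    "eigenvector_bin",
    "eigenvector_wt",
    "kcoreness_bin",
    "kcoreness_wt",
    "flow_bin",
)


def _adj(g: SparseGraph | np.ndarray) -> np.ndarray:
    return g.adjacency if isinstance(g, SparseGraph) else np.asarray(g, dtype=float)


def _to_nx(a: np.ndarray) -> nx.Graph:
    return nx.from_numpy_array(a)


def _require_binary(a: np.ndarray, op: str) -> None:
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError(f"{op} is defined for binary graphs only")


def strength(g: SparseGraph | np.ndarray) -> np.ndarray:
    """Sum of edge weights per node (= degree on a binary graph)."""
    return _adj(g).sum(axis=1)


def clustering_coefficient(g: SparseGraph | np.ndarray, mode: str = "binary") -> np.ndarray:
    """Per-node clustering: triangle density (binary) or Onnela (weighted).

    Nodes of degree < 2 get 0. Weighted clustering normalizes weights by the
    maximum weight in the graph, then averages cube-rooted triangle
    intensities (Onnela et al. formulation, as in networkx).
    """
    a = _adj(g)
    gg = _to_nx(a)
    cc = nx.clustering(gg, weight="weight" if mode == "weighted" else None)
    return np.array([cc[i] for i in range(a.shape[0])])


def local_efficiency(g: SparseGraph | np.ndarray, mode: str = "binary") -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph.

    Neighbors are nodes with a positive edge to v; the subgraph keeps the
    original (binary or weighted) edges among them. Degree < 2 gives 0.
    """
    a = _adj(g)
    if mode == "binary":
        a = (a > 0).astype(float)
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(a[v] > 0)
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[v] = global_efficiency(sub)
    return out


def pagerank_centrality(g: SparseGraph | np.ndarray, damping: float = 0.85,
                        tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """PageRank stationary vector on the (weighted) graph; sums to 1.

    Dangling (isolated) nodes teleport uniformly. Dense power iteration,
    converged to ``tol`` in L1; this is exact enough for the small graphs
    used here and keeps the implementation free of sparse solver details.
    """
    a = _adj(g)
    n = a.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    deg = a.sum(axis=1)
    p = np.full(n, 1.0 / n)
    # column-stochastic transition with dangling mass spread uniformly
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            outflow = np.where(deg > 0, p / deg, 0.0)
        new = damping * (a.T @ outflow)
        dangling = p[deg == 0].sum()
        new += damping * dangling / n + (1 - damping) / n
        if np.abs(new - p).sum() < tol:
            return new / new.sum()
        p = new
    raise RuntimeError(f"PageRank did not converge within {max_iter} iterations")


def betweenness_centrality(g: SparseGraph | np.ndarray, mode: str = "binary") -> np.ndarray:
    """Brandes betweenness, normalized by (N-1)(N-2)/2; weighted uses 1/w."""
    a = _adj(g)
    gg = _to_nx(a)
    if mode == "weighted":
        for u, v, d in gg.edges(data=True):
            d["distance"] = 1.0 / d["weight"]
        bc = nx.betweenness_centrality(gg, weight="distance", normalized=True)
    else:
        bc = nx.betweenness_centrality(gg, normalized=True)
    return np.array([bc[i] for i in range(a.shape[0])])


def eigenvector_centrality(g: SparseGraph | np.ndarray) -> np.ndarray:
    """Principal adjacency eigenvector on the largest connected component.

    Nonnegative, unit Euclidean norm; nodes outside the largest component
    get 0. Components are compared by node count, ties by smallest node
    index. Raises on an edgeless graph (the principal direction is
    undefined there).
    """
    a = _adj(g)
    if not np.any(a > 0):
        raise ValueError("eigenvector centrality undefined on an empty graph")
    gg = _to_nx(a)
    comp = max(nx.connected_components(gg), key=lambda c: (len(c), -min(c)))
    idx = np.array(sorted(comp))
    sub = a[np.ix_(idx, idx)]
    vals, vecs = np.linalg.eigh(sub)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron vector of a nonnegative matrix is nonnegative
    v /= np.linalg.norm(v)
    out = np.zeros(a.shape[0])
    out[idx] = v
    return out


def flow_coefficient(g: SparseGraph | np.ndarray) -> np.ndarray:
    """Fraction of a node's neighbor pairs linked only through that node.

    For node v with degree k >= 2: the share of unordered neighbor pairs
    (i, j) with no direct i-j edge, i.e. length-2 paths through v that are
    non-redundant. Degree < 2 gives 0. Binary graphs only.
    """
    a = _adj(g)
    _require_binary(a, "flow coefficient")
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(a[v] > 0)
        k = nbrs.size
        if k < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        closed = np.triu(sub, 1).sum()
        total = k * (k - 1) / 2
        out[v] = (total - closed) / total
    return out


def kcoreness_centrality(g: SparseGraph | np.ndarray) -> np.ndarray:
    """Max k such that the node survives pruning of all degree-<k nodes."""
    a = _adj(g)
    _require_binary(a, "k-coreness")
    core = nx.core_number(_to_nx(a))
    return np.array([core[i] for i in range(a.shape[0])], dtype=float)


def score_centrality(g: SparseGraph | np.ndarray) -> np.ndarray:
    """Weighted core decomposition (s-core) by iterative strength pruning.

    A node's value is the largest strength threshold s at which it still
    belongs to the s-core: the subgraph obtained by repeatedly deleting
    every node whose remaining strength falls below s. Levels are peeled in
    increasing order; at each level m (the minimum surviving strength) the
    removal cascades until every survivor has strength strictly above m, so
    the levels are monotone and each node's value is the level at which it
    was removed.
    """
    a = _adj(g).copy()
    n = a.shape[0]
    alive = np.ones(n, dtype=bool)
    core = np.zeros(n)
    while alive.any():
        strengths = a.sum(axis=1)
        m = float(strengths[alive].min())
        # cascade: peel everything at or below level m
        while True:
            drop = alive & (a.sum(axis=1) <= m + 1e-12)
            if not drop.any():
                break
            core[drop] = m
            alive[drop] = False
            a[drop, :] = 0.0
            a[:, drop] = 0.0
    return core


def metric_table(
    g_bin: SparseGraph,
    g_wt: SparseGraph,
    columns: tuple[str, ...] = DEFAULT_COLUMNS,
) -> pd.DataFrame:
    """Assemble the configured per-node measures into one table.

    ``g_bin`` and ``g_wt`` must share the node set (same ids, same order);
    typically both come from :func:`tspgnn.connectome.threshold_graph` at
    the same density. Column order is deterministic.
    """
    if g_bin.node_ids != g_wt.node_ids:
        raise ValueError("binary and weighted graphs must share the node set")
    n = g_bin.n_nodes
    if g_wt.n_nodes != n:
        raise ValueError("dimension mismatch between binary and weighted graphs")

    def _eigen_or_zero(g: SparseGraph) -> np.ndarray:
        try:
            return eigenvector_centrality(g)
        except ValueError:
            return np.zeros(n)

    producers = {
        "strength_bin": lambda: strength(g_bin),
        "strength_wt": lambda: strength(g_wt),
        "clustering_bin": lambda: clustering_coefficient(g_bin, "binary"),
        "clustering_wt": lambda: clustering_coefficient(g_wt, "weighted"),
        "local_efficiency_bin": lambda: local_efficiency(g_bin, "binary"),
        "local_efficiency_wt": lambda: local_efficiency(g_wt, "weighted"),
        "pagerank_bin": lambda: pagerank_centrality(g_bin),
        "pagerank_wt": lambda: pagerank_centrality(g_wt),
        "betweenness_bin": lambda: betweenness_centrality(g_bin, "binary"),
        "betweenness_wt": lambda: betweenness_centrality(g_wt, "weighted"),
        "eigenvector_bin": lambda: _eigen_or_zero(g_bin),
        "eigenvector_wt": lambda: _eigen_or_zero(g_wt),
        "kcoreness_bin": lambda: kcoreness_centrality(g_bin),
        "kcoreness_wt": lambda: score_centrality(g_wt),
        "flow_bin": lambda: flow_coefficient(g_bin),
    }
    unknown = set(columns) - set(producers)
    if unknown:
        raise ValueError(f"unknown metric columns: {sorted(unknown)}")
    data = {c: producers[c]() for c in columns}
    df = pd.DataFrame(data, index=pd.Index(g_bin.node_ids, name="node_id"))
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("non-finite metric value produced")
    return df


def save_metric_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")


def load_metric_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="node_id")
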