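"""Node metrics checked against independent brute-force oracles.

Every oracle here is written from the definition (triangle enumeration,
explicit path enumeration, power iteration, iterative pruning) and never
calls the implementation or the library backing it.
"""

import itertools

import numpy as np
import pytest

from tspgnn.connectome import ConnectivityMatrix, SparseGraph, threshold_graph
from tspgnn import graph_metrics as gm
from conftest import random_binary_graph, random_weighted_graph

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_shortest_paths(a: np.ndarray) -> np.ndarray:
    """All-pairs distances by repeated relaxation (Bellman-Ford style)."""
    n = a.shape[0]
    with np.errstate(divide="ignore"):
        d = np.where(a > 0, 1.0 / a, np.inf)
    np.fill_diagonal(d, 0.0)
    for _ in range(n):
        for k in range(n):
            d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def brute_global_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = brute_shortest_paths(a)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_clustering_binary(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(a[v] > 0)
        k = nbrs.size
        if k < 2:
            continue
        tri = sum(1 for i, j in itertools.combinations(nbrs, 2) if a[i, j] > 0)
        out[v] = 2.0 * tri / (k * (k - 1))
    return out


def brute_clustering_onnela(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    w = a / a.max()
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(a[v] > 0)
        k = nbrs.size
        if k < 2:
            continue
        s = sum(
            (w[v, i] * w[v, j] * w[i, j]) ** (1.0 / 3.0)
            for i, j in itertools.combinations(nbrs, 2)
            if a[i, j] > 0
        )
        out[v] = 2.0 * s / (k * (k - 1))
    return out


def brute_local_efficiency(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(a[v] > 0)
        if nbrs.size < 2:
            continue
        out[v] = brute_global_efficiency(a[np.ix_(nbrs, nbrs)])
    return out


def brute_pagerank(a: np.ndarray, damping: float = 0.85) -> np.ndarray:
    n = a.shape[0]
    deg = a.sum(axis=1)
    p = np.full(n, 1.0 / n)
    for _ in range(200_000):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(deg > 0, p / deg, 0.0)
        new = damping * (a.T @ out) + damping * p[deg == 0].sum() / n + (1 - damping) / n
        if np.abs(new - p).sum() < 1e-14:
            break
        p = new
    return new / new.sum()


def brute_betweenness(a: np.ndarray, weighted: bool) -> np.ndarray:
    """Path-enumeration betweenness: count shortest paths per pair directly."""
    n = a.shape[0]
    d = brute_shortest_paths(a if weighted else (a > 0).astype(float))
    with np.errstate(divide="ignore"):
        adj_len = np.where(a > 0, (1.0 / a if weighted else 1.0), np.inf)
    score = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]):
            continue
        # enumerate all shortest s-t paths by DFS over tight edges
        paths = []

        def extend(node, dist, inner):
            if node == t:
                paths.append(list(inner))
                return
            for nxt in range(n):
                if adj_len[node, nxt] < np.inf and np.isclose(
                    dist + adj_len[node, nxt] + d[nxt, t], d[s, t]
                ):
                    extend(nxt, dist + adj_len[node, nxt], inner + [nxt])

        extend(s, 0.0, [])
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            frac = sum(1 for p in paths if v in p[:-1]) / len(paths)
            score[v] += frac
    return score / ((n - 1) * (n - 2) / 2)


def brute_eigenvector(a: np.ndarray) -> np.ndarray:
    """Power iteration on the largest component."""
    n = a.shape[0]
    # find components by flood fill
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(np.flatnonzero(a[v] > 0).tolist())
        seen |= comp
        comps.append(sorted(comp))
    comp = max(comps, key=lambda c: (len(c), -min(c)))
    idx = np.array(comp)
    sub = a[np.ix_(idx, idx)]
    v = np.ones(idx.size)
    for _ in range(100_000):
        # unit shift: A + I has the same principal eigenvector but a strictly
        # dominant eigenvalue even on bipartite components (+/- lambda pairs)
        new = sub @ v + v
        new /= np.linalg.norm(new)
        if np.abs(new - v).max() < 1e-13:
            break
        v = new
    out = np.zeros(n)
    out[idx] = np.abs(new)
    return out / np.linalg.norm(out)


def brute_flow(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(a[v] > 0)
        k = nbrs.size
        if k < 2:
            continue
        open_pairs = sum(
            1 for i, j in itertools.combinations(nbrs, 2) if a[i, j] == 0
        )
        out[v] = open_pairs / (k * (k - 1) / 2)
    return out


def brute_kcore(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    core = np.zeros(n)
    for k in range(1, n):
        alive = np.ones(n, dtype=bool)
        while True:
            deg = (a * alive).sum(axis=1) * alive
            drop = alive & (deg < k)
            if not drop.any():
                break
            alive[drop] = False
        core[alive] = k
    return core


def brute_score(a: np.ndarray) -> np.ndarray:
    """s-core by per-node binary search on the pruning threshold.

    survive(v, s): does v remain after iteratively deleting nodes whose
    strength is strictly below s? The node value is the supremum of s with
    survive(v, s) true, located by bisection (survival is monotone in s).
    """
    n = a.shape[0]

    def survives(s: float) -> np.ndarray:
        alive = np.ones(n, dtype=bool)
        while True:
            strength = (a * np.outer(alive, alive)).sum(axis=1)
            drop = alive & (strength < s)
            if not drop.any():
                return alive
            alive[drop] = False

    out = np.zeros(n)
    hi_all = float(a.sum(axis=1).max()) + 1.0
    for v in range(n):
        lo, hi = 0.0, hi_all
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if survives(mid)[v]:
                lo = mid
            else:
                hi = mid
        out[v] = lo
    return out


# ---------------------------------------------------------------------------
# trivial closed forms
# ---------------------------------------------------------------------------


def complete(n):
    return SparseGraph(np.ones((n, n)) - np.eye(n), 1.0)


def star(n):
    a = np.zeros((n, n))
    a[0, 1:] = a[1:, 0] = 1.0
    return SparseGraph(a, 2.0 / n)


class TestClosedForms:
    def test_strength(self):
        assert np.allclose(gm.strength(complete(5)), 4.0)
        g = star(4)
        assert gm.strength(g)[0] == 3.0

    def test_clustering(self):
        assert np.allclose(gm.clustering_coefficient(complete(4)), 1.0)
        assert gm.clustering_coefficient(star(5))[0] == 0.0

    def test_local_efficiency(self):
        assert np.allclose(gm.local_efficiency(complete(5)), 1.0)
        assert gm.local_efficiency(star(5))[0] == 0.0

    def test_pagerank_regular_graph_uniform(self):
        pr = gm.pagerank_centrality(complete(6))
        assert np.allclose(pr, 1.0 / 6)
        assert pr.sum() == pytest.approx(1.0)

    def test_betweenness_path_and_complete(self):
        p3 = np.zeros((3, 3))
        p3[0, 1] = p3[1, 0] = p3[1, 2] = p3[2, 1] = 1.0
        bc = gm.betweenness_centrality(SparseGraph(p3, 2 / 3))
        assert bc[1] == pytest.approx(1.0) and bc[0] == bc[2] == 0.0
        assert np.allclose(gm.betweenness_centrality(complete(5)), 0.0)

    def test_eigenvector_complete_uniform_unit_norm(self):
        v = gm.eigenvector_centrality(complete(5))
        assert np.allclose(v, v[0])
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_eigenvector_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gm.eigenvector_centrality(np.zeros((4, 4)))

    def test_flow_star_and_complete(self):
        assert gm.flow_coefficient(star(6))[0] == 1.0
        assert np.allclose(gm.flow_coefficient(complete(5)), 0.0)

    def test_kcore_complete_and_path(self):
        assert np.allclose(gm.kcoreness_centrality(complete(4)), 3.0)
        p4 = np.diag(np.ones(3), 1)
        p4 = p4 + p4.T
        assert np.allclose(gm.kcoreness_centrality(SparseGraph(p4, 0.5)), 1.0)


# ---------------------------------------------------------------------------
# oracle equivalence on random graphs
# ---------------------------------------------------------------------------

BINARY_ORACLES = [
    (lambda g: gm.strength(g), lambda a: a.sum(axis=1)),
    (lambda g: gm.clustering_coefficient(g, "binary"), brute_clustering_binary),
    (lambda g: gm.local_efficiency(g, "binary"), brute_local_efficiency),
    (lambda g: gm.pagerank_centrality(g), brute_pagerank),
    (lambda g: gm.betweenness_centrality(g, "binary"), lambda a: brute_betweenness(a, False)),
    (lambda g: gm.flow_coefficient(g), brute_flow),
    (lambda g: gm.kcoreness_centrality(g), brute_kcore),
]

WEIGHTED_ORACLES = [
    (lambda g: gm.strength(g), lambda a: a.sum(axis=1)),
    (lambda g: gm.clustering_coefficient(g, "weighted"), brute_clustering_onnela),
    (lambda g: gm.local_efficiency(g, "weighted"), brute_local_efficiency),
    (lambda g: gm.pagerank_centrality(g), brute_pagerank),
    (lambda g: gm.betweenness_centrality(g, "weighted"), lambda a: brute_betweenness(a, True)),
    (lambda g: gm.score_centrality(g), brute_score),
]


class TestOracleEquivalence:
    def test_binary_metrics_match_brute_force(self, rng):
        for trial in range(25):
            g = random_binary_graph(rng.integers(5, 13), rng.uniform(0.2, 0.7), rng)
            a = g.adjacency
            for impl, oracle in BINARY_ORACLES:
                assert np.allclose(impl(g), oracle(a), atol=1e-8), impl

    def test_weighted_metrics_match_brute_force(self, rng):
        for trial in range(25):
            g = random_weighted_graph(rng.integers(5, 11), rng.uniform(0.3, 0.7), rng)
            a = g.adjacency
            for impl, oracle in WEIGHTED_ORACLES:
                assert np.allclose(impl(g), oracle(a), atol=1e-8), impl

    def test_eigenvector_matches_dense_eigendecomposition(self, rng):
        for _ in range(20):
            g = random_binary_graph(9, 0.5, rng)
            if g.n_edges == 0:
                continue
            got = gm.eigenvector_centrality(g)
            expect = brute_eigenvector(g.adjacency)
            assert np.allclose(got, expect, atol=1e-6)


class TestProperties:
    def test_node_relabeling_equivariance(self, rng):
        g = random_weighted_graph(9, 0.5, rng)
        perm = rng.permutation(9)
        gp = SparseGraph(g.adjacency[np.ix_(perm, perm)], g.density)
        for fn in (
            gm.strength,
            lambda x: gm.clustering_coefficient(x, "weighted"),
            lambda x: gm.local_efficiency(x, "weighted"),
            gm.pagerank_centrality,
            lambda x: gm.betweenness_centrality(x, "weighted"),
            gm.score_centrality,
        ):
            assert np.allclose(fn(gp), fn(g)[perm], atol=1e-9)

    def test_binary_weighted_variants_coincide_on_01_graph(self, rng):
        g = random_binary_graph(10, 0.5, rng)
        assert np.allclose(
            gm.clustering_coefficient(g, "binary"), gm.clustering_coefficient(g, "weighted")
        )
        assert np.allclose(
            gm.local_efficiency(g, "binary"), gm.local_efficiency(g, "weighted")
        )

    def test_flow_and_kcore_reject_weighted_graphs(self, rng):
        g = random_weighted_graph(6, 0.8, rng)
        with pytest.raises(ValueError, match="binary"):
            gm.flow_coefficient(g)
        with pytest.raises(ValueError, match="binary"):
            gm.kcoreness_centrality(g)


class TestMetricTable:
    def test_shape_and_column_order(self, rng):
        g = random_weighted_graph(8, 0.6, rng)
        gb = SparseGraph((g.adjacency > 0).astype(float), g.density)
        t = gm.metric_table(gb, g)
        assert t.shape == (8, 15)
        assert list(t.columns) == list(gm.DEFAULT_COLUMNS)
        assert t["pagerank_bin"].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.array_equal(t["kcoreness_bin"], t["kcoreness_bin"].astype(int))

    def test_whole_brain_feature_count(self, rng):
        # 246 regions x 15 attributes flatten to 3690 features
        from conftest import random_correlation

        c = random_correlation(246, rng)
        gb = threshold_graph(c, 0.1, "binary")
        gw = threshold_graph(c, 0.1, "weighted")
        t = gm.metric_table(gb, gw)
        assert t.size == 3690

    def test_node_permutation_permutes_rows(self, rng):
        g = random_weighted_graph(7, 0.6, rng)
        gb = SparseGraph((g.adjacency > 0).astype(float), g.density)
        t = gm.metric_table(gb, g)
        perm = rng.permutation(7)
        g2 = SparseGraph(g.adjacency[np.ix_(perm, perm)], g.density,
                         [g.node_ids[i] for i in perm])
        gb2 = SparseGraph((g2.adjacency > 0).astype(float), g.density, g2.node_ids)
        t2 = gm.metric_table(gb2, g2)
        assert np.allclose(t2.to_numpy(), t.to_numpy()[perm], atol=1e-9)

    def test_mismatched_node_sets_rejected(self, rng):
        g1 = random_weighted_graph(5, 0.6, rng)
        g2 = random_weighted_graph(6, 0.6, rng)
        with pytest.raises(ValueError):
            gm.metric_table(g1, g2)
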