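"""From decoded edge sets to per-subject classification features.

A decoded task yields a :class:`TaskPattern`: the surviving edges and the
subnetwork of all nodes they touch. Classification features for a subject
are the FC values among the pattern nodes (all within-subnetwork pairs by
default, decoded edges only on request) concatenated with the per-node
graph-metric columns, each feature name carrying its provenance
(``fc:<i>-<j>`` or ``metric:<node>:<name>``). Dimension is then reduced by
recursive feature elimination under a ridge classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import RidgeClassifier

from .connectome import ConnectivityMatrix

__all__ = ["TaskPattern", "task_nodes", "combine_patterns", "build_features", "rfe_ridge"]


@dataclass
class TaskPattern:
    """Edges decoded for one task plus the node subnetwork they span."""

    task_name: str
    edges: tuple[tuple[int, int], ...]
    nodes: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        edges = tuple(sorted({(int(i), int(j)) for i, j in self.edges}))
        for i, j in edges:
            if not i < j:
                raise ValueError(f"edge ({i}, {j}) must satisfy i < j")
        self.edges = edges
        self.nodes = task_nodes_from_edges(edges)


def task_nodes_from_edges(edges: Sequence[tuple[int, int]]) -> tuple[int, ...]:
    nodes = sorted({n for e in edges for n in e})
    if not nodes:
        warnings.warn("empty edge set gives an empty task subnetwork", stacklevel=2)
    return tuple(nodes)


def task_nodes(pattern: TaskPattern) -> tuple[int, ...]:
    """Sorted union of edge endpoints — the task subnetwork."""
    return pattern.nodes


def combine_patterns(patterns: Sequence[TaskPattern]) -> TaskPattern:
    """Union of task patterns, named by underscore-joined sorted initials.

    ``combine([motor, social])`` has name ``M_S``; combining a pattern with
    itself is idempotent.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    edges = sorted({e for p in patterns for e in p.edges})
    initials = sorted({p.task_name[:1].upper() for p in patterns if p.task_name})
    return TaskPattern("_".join(initials), tuple(edges))


def build_features(
    fc_stack: Sequence[ConnectivityMatrix],
    pattern: TaskPattern,
    metric_tables: Sequence[pd.DataFrame] | None = None,
    subject_ids: Sequence[str] | None = None,
    include_fc: bool = True,
    include_metrics: bool = True,
    decoded_edges_only: bool = False,
) -> pd.DataFrame:
    """Per-subject feature matrix over the pattern subnetwork.

    FC features cover all m(m-1)/2 node pairs within the subnetwork (or only
    the decoded edges when ``decoded_edges_only``); metric features are the
    per-node columns of each subject's :func:`~tspgnn.graph_metrics.metric_table`
    restricted to pattern nodes. Column names are provenance-tagged and the
    order is deterministic.
    """
    if not fc_stack:
        raise ValueError("empty cohort")
    n_nodes = fc_stack[0].n_nodes
    for node in pattern.nodes:
        if node >= n_nodes:
            raise ValueError(f"pattern node {node} not present in cohort (N = {n_nodes})")
    if subject_ids is None:
        subject_ids = [f"sub-{s:04d}" for s in range(len(fc_stack))]
    if include_metrics and metric_tables is None:
        raise ValueError("include_metrics requires metric_tables")

    nodes = list(pattern.nodes)
    if decoded_edges_only:
        pairs = list(pattern.edges)
    else:
        pairs = [(nodes[a], nodes[b]) for a in range(len(nodes)) for b in range(a + 1, len(nodes))]

    columns: list[str] = []
    if include_fc:
        columns += [f"fc:{i}-{j}" for i, j in pairs]
    if include_metrics:
        metric_names = list(metric_tables[0].columns)
        columns += [f"metric:{v}:{m}" for v in nodes for m in metric_names]

    rows = np.empty((len(fc_stack), len(columns)))
    for s, c in enumerate(fc_stack):
        parts = []
        if include_fc:
            parts.append(np.array([c.values[i, j] for i, j in pairs]))
        if include_metrics:
            t = metric_tables[s]
            parts.append(t.iloc[nodes].to_numpy().ravel())
        rows[s] = np.concatenate(parts) if parts else np.empty(0)

    df = pd.DataFrame(rows, index=pd.Index(subject_ids, name="subject_id"), columns=columns)
    if df.isna().any().any():
        raise ValueError("feature matrix contains NaN")
    return df


def rfe_ridge(
    x: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    n_keep: int,
    step: float | int = 0.1,
    ridge_alpha: float = 1.0,
) -> np.ndarray:
    """Recursive feature elimination under a ridge classifier.

    Repeatedly fits ``RidgeClassifier(alpha=ridge_alpha)`` and removes the
    lowest-|coefficient| features until ``n_keep`` remain. An integer
    ``step`` removes that many features per round; a fractional step removes
    that share of the remaining features (at least one). Ties in |coef| are
    broken by dropping the higher index first, so the procedure is
    deterministic. Returns sorted original-column indices of the survivors.
    """
    xv = x.to_numpy() if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    p = xv.shape[1]
    if not 1 <= n_keep <= p:
        raise ValueError("n_keep must lie in [1, n_features]")
    alive = np.arange(p)
    while alive.size > n_keep:
        clf = RidgeClassifier(alpha=ridge_alpha)
        clf.fit(xv[:, alive], labels)
        imp = np.abs(clf.coef_.ravel())
        n_drop = int(step) if step >= 1 else max(1, int(step * alive.size))
        n_drop = min(n_drop, alive.size - n_keep)
        # weakest first; among equal importances drop the higher index
        order = np.lexsort((-np.arange(alive.size), imp))
        alive = np.delete(alive, order[:n_drop])
    return np.sort(alive)
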