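"""Feature graphs from fitted forests.

A fitted decision tree is read as a directed graph over *feature indices*:
for every parent split node and each of its non-leaf children, one edge runs
from the parent's split feature to the child's split feature. Leaves carry no
feature and contribute nothing. The per-tree graphs of a forest are unioned
into a single aggregated graph, which is then finalized into a binary
symmetric adjacency with unit diagonal — the mask applied to the first layer
of the graph-embedded network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from sklearn.tree._tree import TREE_LEAF


@dataclass
class FeatureGraph:
    """Binary adjacency over features (symmetric, unit diagonal once finalized)."""

    adjacency: np.ndarray
    n_features: int

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.adjacency.shape != (self.n_features, self.n_features):
            raise ValueError("adjacency shape mismatch")

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Upper-triangular edge list (u <= v), including self-loops."""
        iu, iv = np.nonzero(np.triu(self.adjacency))
        return list(zip(iu.tolist(), iv.tolist()))

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_edgelist(self, path, header: dict | None = None) -> None:
        """Serialize as `u<TAB>v` lines (0-based) plus a JSON header sidecar."""
        with open(path, "w") as fh:
            for u, v in self.edges:
                fh.write(f"{u}\t{v}\n")
        meta = {"n_features": int(self.n_features), **(header or {})}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def from_edgelist(cls, path) -> "FeatureGraph":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        n = meta["n_features"]
        adj = np.zeros((n, n), dtype=bool)
        with open(path) as fh:
            for line in fh:
                u, v = map(int, line.split())
                adj[u, v] = adj[v, u] = True
        return cls(adjacency=adj, n_features=n)


def fit_forest(
    X,
    y,
    p: int = 1000,
    seed: int | None = None,
    max_features="sqrt",
) -> RandomForestClassifier:
    """Fit a classification random forest of ``p`` trees (Gini, bootstrap on)."""
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a forest")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    if p < 1:
        raise ValueError("p must be >= 1")
    forest = RandomForestClassifier(
        n_estimators=p,
        criterion="gini",
        bootstrap=True,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def tree_to_graph(tree) -> set[tuple[int, int]]:
    """Directed (parent split feature -> child split feature) edge set of one tree.

    Accepts a fitted sklearn decision tree or its ``tree_`` attribute.
    Duplicate edges collapse; an all-leaf tree (a stump's children, or a
    single-leaf tree) yields an empty set.
    """
    t = getattr(tree, "tree_", tree)
    left, right, feature = t.children_left, t.children_right, t.feature
    edges: set[tuple[int, int]] = set()
    for node in range(t.node_count):
        if left[node] == TREE_LEAF:  # leaf: no split feature
            continue
        for child in (left[node], right[node]):
            if left[child] != TREE_LEAF:
                edges.add((int(feature[node]), int(feature[child])))
    return edges


def tree_vertices(tree) -> set[int]:
    """All feature indices the tree splits on."""
    t = getattr(tree, "tree_", tree)
    return {int(f) for f, l in zip(t.feature, t.children_left) if l != TREE_LEAF}


def aggregate_graphs(graphs, n_features: int) -> FeatureGraph:
    """Union the per-tree edge sets, then symmetrize and set a unit diagonal.

    The union is a plain set union (commutative, associative, idempotent);
    finalization makes the adjacency usable as a Hadamard weight mask, where
    direction is meaningless and each feature must reach its own hidden unit.
    """
    adj = np.zeros((n_features, n_features), dtype=bool)
    for edge_set in graphs:
        for u, v in edge_set:
            if not (0 <= u < n_features and 0 <= v < n_features):
                raise ValueError(f"edge ({u},{v}) outside feature range")
            adj[u, v] = True
    adj |= adj.T
    np.fill_diagonal(adj, True)
    return FeatureGraph(adjacency=adj, n_features=n_features)


def forest_to_graph(forest, n_features: int | None = None) -> FeatureGraph:
    """Aggregated feature graph of a fitted forest."""
    n = n_features if n_features is not None else forest.n_features_in_
    return aggregate_graphs(
        (tree_to_graph(est) for est in forest.estimators_), n_features=n
    )
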