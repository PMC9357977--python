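"""Independent brute-force oracles used by the tests.

Each oracle is written as plainly as possible (explicit loops, generic
solvers) and never shares code with the implementation paths it checks.
"""

import numpy as np
from scipy.optimize import minimize

from forgesel.svm import KernelSpec, kernel_matrix


def gcw_bruteforce(W_in, W1, A, gated=False):
    """Triple-loop evaluation of the connection-weights score."""
    n = W_in.shape[0]
    h = W1.shape[1]
    c = np.zeros(n)
    for i in range(n):
        for a in range(n):
            if A[i, a]:
                c[i] += abs(W_in[i, a])
        for b in range(n):
            if A[b, i]:
                c[i] += abs(W_in[b, i])
        has_neighbour = sum(1 for a in range(n) if A[i, a]) > 1
        if not gated or has_neighbour:
            for k in range(h):
                c[i] += abs(W1[i, k])
    return c


def union_bruteforce(edge_sets, n):
    """Element-wise boolean OR of dense per-graph adjacencies, then finalize."""
    mats = []
    for es in edge_sets:
        m = np.zeros((n, n), dtype=bool)
        for u, v in es:
            m[u, v] = True
        mats.append(m)
    out = np.zeros((n, n), dtype=bool)
    for m in mats:
        out = out | m
    out = out | out.T
    for i in range(n):
        out[i, i] = True
    return out


def tree_edges_bruteforce(tree):
    """Recursive parent/child scan of a fitted sklearn tree."""
    t = getattr(tree, "tree_", tree)

    def is_leaf(node):
        return t.children_left[node] == t.children_right[node]

    edges = set()

    def walk(node):
        if is_leaf(node):
            return
        for child in (t.children_left[node], t.children_right[node]):
            if not is_leaf(child):
                edges.add((int(t.feature[node]), int(t.feature[child])))
            walk(child)

    walk(0)
    return edges


def topk_bruteforce(scores, k):
    """Full sort by (-score, index), take the first k."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return order[:k]


def qp_dual_objective(X, y, C, spec=None):
    """Generic QP solve of the SVM dual; returns the optimal objective value."""
    spec = spec or KernelSpec()
    y = np.asarray(y, dtype=np.float64)
    K = kernel_matrix(X, X, spec)
    Q = np.outer(y, y) * K
    n = len(y)
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: Q @ a - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    return float(res.fun)


def random_separable_toy(rng, n_max=6):
    """A tiny linearly separable two-class problem with margin along axis 0."""
    n = int(rng.integers(3, n_max + 1))
    dim = int(rng.integers(2, 4))
    X = rng.normal(size=(n, dim))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    if abs(y.sum()) == n:  # ensure both classes
        y[0] = -y[0]
    X[:, 0] = y * rng.uniform(0.5, 1.5, n)
    return X, y.astype(int)
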