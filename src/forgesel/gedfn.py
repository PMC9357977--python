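"""Graph-embedded deep feed-forward network and connection-weights importance.

The network's first layer has one hidden unit per input feature; its weight
matrix is Hadamard-masked by the feature graph's adjacency, so a feature's
unit only receives input from the feature itself and its graph neighbours:

    Z1 = relu(X (W_in o A) + b_in)
    Z2 = relu(Z1 W1 + b1),  Z3 = relu(Z2 W2 + b2)
    y  = softmax(Z3 W_out + b_out)

Masked entries of W_in are exactly zero at initialization and after every
update (the gradient is masked too), so the sparsity invariant is exact.

Feature importance is scored by Graph Connection Weights (GCW): for feature
i, the absolute masked first-layer weights into and out of unit i plus the
absolute weights from unit i into the second hidden layer:

    c_i = sum_a |W_in[i,a]| 1(A[i,a]=1)
        + sum_b |W_in[b,i]| 1(A[b,i]=1)
        + sum_c |W1[i,c]|
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_X_y, check_array

from .forest_graph import FeatureGraph


@dataclass
class ImportanceScores:
    """Per-feature non-negative scores plus the descending-score ranking.

    Ties in the score break toward the smaller feature index (stable).
    """

    scores: np.ndarray
    ranking: np.ndarray

    @classmethod
    def from_scores(cls, scores) -> "ImportanceScores":
        scores = np.asarray(scores, dtype=np.float64)
        ranking = np.argsort(-scores, kind="stable")
        return cls(scores=scores, ranking=ranking)

    def to_tsv(self, path, feature_names=None) -> None:
        names = feature_names or [f"f{i}" for i in range(len(self.scores))]
        rank_of = np.empty(len(self.scores), dtype=int)
        rank_of[self.ranking] = np.arange(len(self.scores))
        with open(path, "w") as fh:
            fh.write("feature_name\tscore\trank\n")
            for i, name in enumerate(names):
                fh.write(f"{name}\t{self.scores[i]:.10g}\t{rank_of[i]}\n")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class GEDFN(ClassifierMixin, BaseEstimator):
    """Graph-embedded deep feed-forward network classifier.

    Parameters
    ----------
    adjacency : array-like of bool, shape (n_features, n_features), or FeatureGraph
        The feature-graph mask for the first layer. Required before ``fit``.
    hidden_dims : tuple of int
        Widths of the two hidden layers after the masked layer; together with
        the masked layer these are the network's three hidden layers.
    epochs, lr, batch_size : training schedule (mini-batch cross-entropy).
    optimizer : {"adam", "sgd"}
    class_weight : None or "balanced"
        Per-class loss weights; None (unweighted) by default.
    gcw_gated : bool
        If True, the second-layer term of the GCW score is only counted for
        features with at least one non-self graph neighbour. Default False
        (the term is ungated).
    random_state : int
        Seeds weight initialization and batch shuffling.
    """

    def __init__(
        self,
        adjacency=None,
        hidden_dims: tuple[int, int] = (64, 16),
        epochs: int = 50,
        lr: float = 1e-4,
        batch_size: int = 32,
        optimizer: str = "adam",
        class_weight=None,
        gcw_gated: bool = False,
        random_state: int | None = None,
    ):
        self.adjacency = adjacency
        self.hidden_dims = hidden_dims
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.class_weight = class_weight
        self.gcw_gated = gcw_gated
        self.random_state = random_state

    def _resolve_mask(self, n_features: int) -> np.ndarray:
        adj = self.adjacency
        if adj is None:
            raise ValueError("adjacency is required (a FeatureGraph or boolean matrix)")
        if isinstance(adj, FeatureGraph):
            adj = adj.adjacency
        adj = np.asarray(adj, dtype=np.float64)
        if adj.shape != (n_features, n_features):
            raise ValueError(
                f"adjacency shape {adj.shape} does not match n_features={n_features}"
            )
        return adj

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        n, d = X.shape
        self.n_features_in_ = d
        mask = self._resolve_mask(d)
        rng = np.random.default_rng(self.random_state)
        h2, h3 = self.hidden_dims

        # He-style init; W_in masked from the start.
        params = {
            "W_in": rng.standard_normal((d, d)) * np.sqrt(2.0 / d) * mask,
            "b_in": np.zeros(d),
            "W1": rng.standard_normal((d, h2)) * np.sqrt(2.0 / d),
            "b1": np.zeros(h2),
            "W2": rng.standard_normal((h2, h3)) * np.sqrt(2.0 / h2),
            "b2": np.zeros(h3),
            "W_out": rng.standard_normal((h3, 2)) * np.sqrt(2.0 / h3),
            "b_out": np.zeros(2),
        }

        y_idx = (y == self.classes_[1]).astype(int)  # 0/1 class index
        onehot = np.eye(2)[y_idx]
        if self.class_weight == "balanced":
            counts = np.bincount(y_idx, minlength=2)
            cw = n / (2.0 * counts)
            sample_w = cw[y_idx]
        else:
            sample_w = np.ones(n)

        if self.optimizer == "adam":
            opt = _Adam(params, self.lr)
        elif self.optimizer == "sgd":
            opt = None
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

        bs = min(self.batch_size, n)
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                Xb, Tb, wb = X[idx], onehot[idx], sample_w[idx]
                loss, grads = self._loss_and_grads(params, mask, Xb, Tb, wb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss ({loss}) at epoch "
                        f"{len(self.loss_curve_)}; lower the learning rate"
                    )
                epoch_loss += loss * len(idx)
                if opt is not None:
                    opt.step(params, grads)
                else:
                    for k, g in grads.items():
                        params[k] -= self.lr * g
                params["W_in"] *= mask  # exact mask conservation
            if not all(np.isfinite(v).all() for v in params.values()):
                raise RuntimeError(
                    f"non-finite network weights after epoch {len(self.loss_curve_)}; "
                    "lower the learning rate"
                )
            self.loss_curve_.append(epoch_loss / n)

        self.W_in_ = params["W_in"]
        self.b_in_ = params["b_in"]
        self.W1_, self.b1_ = params["W1"], params["b1"]
        self.W2_, self.b2_ = params["W2"], params["b2"]
        self.W_out_, self.b_out_ = params["W_out"], params["b_out"]
        self.mask_ = mask
        return self

    @staticmethod
    def _forward(params, mask, X):
        Z1 = np.maximum(X @ (params["W_in"] * mask) + params["b_in"], 0.0)
        Z2 = np.maximum(Z1 @ params["W1"] + params["b1"], 0.0)
        Z3 = np.maximum(Z2 @ params["W2"] + params["b2"], 0.0)
        logits = Z3 @ params["W_out"] + params["b_out"]
        return Z1, Z2, Z3, logits

    def _loss_and_grads(self, params, mask, X, T, w):
        Z1, Z2, Z3, logits = self._forward(params, mask, X)
        P = _softmax(logits)
        eps = 1e-12
        n = len(X)
        loss = -(w[:, None] * T * np.log(P + eps)).sum() / w.sum()

        dlogits = (P - T) * w[:, None] / w.sum()
        grads = {}
        grads["W_out"] = Z3.T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dZ3 = (dlogits @ params["W_out"].T) * (Z3 > 0)
        grads["W2"] = Z2.T @ dZ3
        grads["b2"] = dZ3.sum(axis=0)
        dZ2 = (dZ3 @ params["W2"].T) * (Z2 > 0)
        grads["W1"] = Z1.T @ dZ2
        grads["b1"] = dZ2.sum(axis=0)
        dZ1 = (dZ2 @ params["W1"].T) * (Z1 > 0)
        grads["W_in"] = (X.T @ dZ1) * mask  # masked gradient
        grads["b_in"] = dZ1.sum(axis=0)
        return loss, grads

    def _check_fitted_X(self, X):
        check_array(X, dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width mismatch")
        return X

    def predict_proba(self, X):
        X = self._check_fitted_X(X)
        params = {
            "W_in": self.W_in_, "b_in": self.b_in_,
            "W1": self.W1_, "b1": self.b1_,
            "W2": self.W2_, "b2": self.b2_,
            "W_out": self.W_out_, "b_out": self.b_out_,
        }
        *_, logits = self._forward(params, self.mask_, X)
        return _softmax(logits)

    def decision_function(self, X):
        p = self.predict_proba(X)
        return p[:, 1] - p[:, 0]

    def predict(self, X):
        p = self.predict_proba(X)
        return self.classes_[(p[:, 1] >= p[:, 0]).astype(int)]


def train_gedfn(
    X,
    y,
    graph: FeatureGraph,
    epochs: int = 50,
    lr: float = 1e-4,
    seed: int | None = None,
    **kwargs,
) -> GEDFN:
    """Train a GEDFN on (X, y) masked by ``graph``; thin wrapper over the estimator."""
    model = GEDFN(
        adjacency=graph, epochs=epochs, lr=lr, random_state=seed, **kwargs
    )
    return model.fit(X, y)


def gcw_scores(model: GEDFN, graph: FeatureGraph | None = None) -> ImportanceScores:
    """Graph Connection Weights importance of each feature (non-negative)."""
    mask = model.mask_ if graph is None else np.asarray(
        graph.adjacency if isinstance(graph, FeatureGraph) else graph, dtype=float
    )
    if mask.shape != model.W_in_.shape:
        raise ValueError("graph does not match the model's feature count")
    absw = np.abs(model.W_in_) * (mask != 0)
    c = absw.sum(axis=1) + absw.sum(axis=0)
    third = np.abs(model.W1_).sum(axis=1)
    if model.gcw_gated:
        has_neighbour = (mask != 0).sum(axis=1) > 1  # beyond the self-loop
        third = third * has_neighbour
    return ImportanceScores.from_scores(c + third)


def select_top_k(scores: ImportanceScores, k: int = 900) -> np.ndarray:
    """Indices of the k highest-scoring features, descending score, ties by index."""
    n = len(scores.scores)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return scores.ranking[:k].copy()
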