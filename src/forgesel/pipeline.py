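"""End-to-end orchestration: forest graph -> GEDFN -> GCW selection -> SVM.

The full method fits a random forest on the training matrix, unions its trees
into a feature graph, trains the graph-embedded network, ranks features by
their Graph Connection Weights score, keeps the top k, and trains a kernel
SVM on the selected columns. Evaluation follows the usual virtual-screening
protocol: stratified k-fold cross-validation with pooled (micro) confusion
counts, or a stratified 70/30 train/test split, reporting TPR, FPR,
Precision, Specificity, F1 and AUC.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold

from .featurize import FusedFeatureMatrix
from .forest_graph import fit_forest, forest_to_graph
from .gedfn import GEDFN, gcw_scores, select_top_k
from .metrics import EvalReport, compute_metrics, confusion_counts, roc_auc
from .svm import KernelSVC


@dataclass
class PipelineConfig:
    """Hyperparameters of the full method and its evaluation protocol.

    Defaults follow the reference operating point: 1000 trees, three hidden
    layers, learning rate 1e-4, 50 epochs, top-900 features, linear kernel,
    10-fold cross-validation, 70% training fraction.
    """

    trees: int = 1000
    epochs: int = 50
    lr: float = 1e-4
    k_selected: int = 900
    kernel: str = "linear"
    C: float = 1.0
    cv_folds: int = 10
    train_fraction: float = 0.7
    selection_scope: str = "per_fold"
    hidden_dims: tuple[int, int] = (64, 16)
    batch_size: int = 32
    gcw_gated: bool = False
    svm_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.k_selected < 1:
            raise ValueError("k_selected must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.selection_scope not in ("per_fold", "global"):
            raise ValueError("selection_scope must be 'per_fold' or 'global'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hidden_dims" in raw:
            raw["hidden_dims"] = tuple(raw["hidden_dims"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        return d


class ForgeNetSVM(ClassifierMixin, BaseEstimator):
    """Forest-graph feature selection wrapped around a kernel SVM.

    ``fit`` runs the full chain; fitted attributes expose every stage:
    ``forest_``, ``graph_``, ``gedfn_``, ``importances_``,
    ``selected_features_`` (column indices, length ``k_selected``) and the
    final ``svm_``.

    ``classifier`` swaps the final stage: any scikit-learn-style classifier
    (fit / predict, ideally decision_function or predict_proba) is cloned and
    trained on the selected columns in place of the kernel SVM.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        epochs: int = 50,
        lr: float = 1e-4,
        k_selected: int = 900,
        kernel: str = "linear",
        C: float = 1.0,
        hidden_dims: tuple[int, int] = (64, 16),
        batch_size: int = 32,
        gcw_gated: bool = False,
        svm_tol: float = 1e-4,
        classifier=None,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.epochs = epochs
        self.lr = lr
        self.k_selected = k_selected
        self.kernel = kernel
        self.C = C
        self.hidden_dims = hidden_dims
        self.batch_size = batch_size
        self.gcw_gated = gcw_gated
        self.svm_tol = svm_tol
        self.classifier = classifier
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if self.k_selected > X.shape[1]:
            raise ValueError(
                f"k_selected={self.k_selected} exceeds feature width {X.shape[1]}"
            )
        ss = np.random.SeedSequence(self.random_state)
        forest_seed, net_seed = [int(s) % (2**31 - 1) for s in ss.generate_state(2)]

        self.forest_ = fit_forest(X, y, p=self.n_trees, seed=forest_seed)
        self.graph_ = forest_to_graph(self.forest_, X.shape[1])
        self.gedfn_ = GEDFN(
            adjacency=self.graph_,
            hidden_dims=self.hidden_dims,
            epochs=self.epochs,
            lr=self.lr,
            batch_size=self.batch_size,
            gcw_gated=self.gcw_gated,
            random_state=net_seed,
        ).fit(X, y)
        self.importances_ = gcw_scores(self.gedfn_)
        self.selected_features_ = select_top_k(self.importances_, self.k_selected)
        if self.classifier is None:
            final = KernelSVC(kernel=self.kernel, C=self.C, tol=self.svm_tol)
        else:
            final = clone(self.classifier)
        self.svm_ = final.fit(X[:, self.selected_features_], y)
        self.classes_ = self.svm_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        Xs = X[:, self.selected_features_]
        if hasattr(self.svm_, "decision_function"):
            return self.svm_.decision_function(Xs)
        proba = self.svm_.predict_proba(Xs)  # fall back to probability margin
        return proba[:, 1] - proba[:, 0]

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self.svm_.predict(X[:, self.selected_features_])


def _as_xy(data):
    if isinstance(data, FusedFeatureMatrix):
        if data.labels is None:
            raise ValueError("feature matrix carries no labels")
        return data.matrix, np.asarray(data.labels), data.column_names
    X, y = data
    return np.asarray(X), np.asarray(y), None


def _estimator(cfg: PipelineConfig, seed: int) -> ForgeNetSVM:
    return ForgeNetSVM(
        n_trees=cfg.trees,
        epochs=cfg.epochs,
        lr=cfg.lr,
        k_selected=cfg.k_selected,
        kernel=cfg.kernel,
        C=cfg.C,
        hidden_dims=cfg.hidden_dims,
        batch_size=cfg.batch_size,
        gcw_gated=cfg.gcw_gated,
        svm_tol=cfg.svm_tol,
        random_state=seed,
    )


def _evaluate(y_true, y_pred, decision_values) -> EvalReport:
    tp, fp, fn, tn = confusion_counts(y_true, y_pred)
    report = compute_metrics(tp, fp, fn, tn)
    try:
        report.auc, _ = roc_auc(decision_values, y_true)
    except ValueError:
        report.auc = None
    return report


def run_forgenet_svm(train, test, cfg: PipelineConfig):
    """Fit the full chain on ``train`` and evaluate on ``test``.

    Returns ``(EvalReport, selected_feature_names_or_indices)``.
    """
    X_tr, y_tr, names = _as_xy(train)
    X_te, y_te, _ = _as_xy(test)
    if X_tr.shape[1] != X_te.shape[1]:
        raise ValueError("train and test must share the column space")
    est = _estimator(cfg, cfg.seed).fit(X_tr, y_tr)
    y_pred = est.predict(X_te)
    report = _evaluate(y_te, y_pred, est.decision_function(X_te))
    sel = est.selected_features_
    selected = [names[j] for j in sel] if names is not None else sel.tolist()
    return report, selected


def cross_validate(data, cfg: PipelineConfig):
    """Stratified k-fold evaluation of the full chain.

    With ``selection_scope='per_fold'`` every stage (forest, network,
    selection, SVM) is refitted inside each training fold — no information
    leaks from the held-out fold. ``'global'`` performs the selection once on
    the whole table and refits only the SVM per fold (a single-pass
    selection protocol; optimistic by construction).

    Returns ``(pooled EvalReport, list of per-fold EvalReports)``; the pooled
    report sums confusion counts across folds (micro aggregation) and pools
    decision values for the AUC.
    """
    X, y, names = _as_xy(data)
    if len(X) < cfg.cv_folds:
        raise ValueError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    ss = np.random.SeedSequence(cfg.seed)
    fold_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(cfg.cv_folds)]

    selected_global = None
    if cfg.selection_scope == "global":
        est_g = _estimator(cfg, cfg.seed).fit(X, y)
        selected_global = est_g.selected_features_

    pooled_true, pooled_pred, pooled_dec = [], [], []
    fold_reports = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                "a training fold lacks one class; stratify labels or use fewer folds"
            )
        if cfg.selection_scope == "per_fold":
            est = _estimator(cfg, fold_seeds[fold]).fit(X[tr], y[tr])
            y_pred = est.predict(X[te])
            dec = est.decision_function(X[te])
        else:
            svm = KernelSVC(kernel=cfg.kernel, C=cfg.C, tol=cfg.svm_tol).fit(
                X[tr][:, selected_global], y[tr]
            )
            y_pred = svm.predict(X[te][:, selected_global])
            dec = svm.decision_function(X[te][:, selected_global])
        fold_reports.append(_evaluate(y[te], y_pred, dec))
        pooled_true.append(y[te])
        pooled_pred.append(y_pred)
        pooled_dec.append(dec)

    y_true = np.concatenate(pooled_true)
    pooled = _evaluate(y_true, np.concatenate(pooled_pred), np.concatenate(pooled_dec))
    pooled.per_fold = fold_reports
    return pooled, fold_reports


def split_train_test(data, train_fraction: float = 0.7, seed: int | None = None):
    """Stratified train/test split with floor allocation to the test set.

    The test set receives ``floor((1 - train_fraction) * n_c)`` samples of
    each class c; the remainder trains.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    X, y, _ = _as_xy(data)
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        n_test = int(np.floor((1.0 - train_fraction) * len(members)))
        test_idx.append(rng.choice(members, size=n_test, replace=False))
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    if isinstance(data, FusedFeatureMatrix):
        return data.subset_rows(train_idx), data.subset_rows(test_idx)
    return (X[train_idx], y[train_idx]), (X[test_idx], y[test_idx])


def k_sweep(data, cfg: PipelineConfig, ks=(50, 100, 200, 500, 600, 700, 800, 900, 1000, 1200)):
    """Cross-validated metrics as a function of the number of selected features.

    Returns a list of dicts with both pooled metrics and per-fold means for
    every k that fits the feature width.
    """
    X, _, _ = _as_xy(data)
    rows = []
    for k in ks:
        if k > X.shape[1]:
            continue
        cfg_k = dataclasses.replace(cfg, k_selected=k)
        pooled, folds = cross_validate(data, cfg_k)
        fold_means = {
            name: float(np.mean([getattr(r, attr) for r in folds if getattr(r, attr) is not None]))
            for name, attr in [
                ("TPR", "tpr"), ("FPR", "fpr"), ("Precision", "precision"),
                ("Specificity", "specificity"), ("F1", "f1"), ("AUC", "auc"),
            ]
        }
        rows.append({"k": k, "pooled": pooled.to_dict(), "fold_means": fold_means})
    return rows


def report_to_json(
    report: EvalReport, cfg: PipelineConfig, selected=None, extra=None
) -> str:
    """Deterministic JSON rendering of an evaluation report."""
    payload = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        **report.to_dict(),
        "per_fold": [r.to_dict() for r in report.per_fold],
    }
    if selected is not None:
        payload["selected_features"] = list(selected)
    if extra:
        payload.update(extra)
    return json.dumps(payload, indent=2, sort_keys=True)
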