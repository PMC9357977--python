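"""Confusion-matrix metrics and ROC/AUC for active/decoy classification.

Rates follow the usual definitions: TPR = TP/(TP+FN), FPR = FP/(FP+TN),
Precision = TP/(TP+FP), Specificity = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN).
A zero denominator makes the rate undefined; undefined rates are carried as
None and rendered blank, never as 0. Reports render rates in six-decimal
fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class EvalReport:
    """Confusion counts plus the derived rate bundle (None = undefined)."""

    tp: int
    fp: int
    fn: int
    tn: int
    tpr: float | None = None
    fpr: float | None = None
    precision: float | None = None
    specificity: float | None = None
    f1: float | None = None
    auc: float | None = None
    per_fold: list = field(default_factory=list)

    def rates_dict(self) -> dict:
        return {
            "TPR": self.tpr,
            "FPR": self.fpr,
            "Precision": self.precision,
            "Specificity": self.specificity,
            "F1": self.f1,
            "AUC": self.auc,
        }

    def to_dict(self) -> dict:
        return {
            "confusion": {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn},
            "rates": {
                k: (None if v is None else round(float(v), 6))
                for k, v in self.rates_dict().items()
            },
        }

    def render_rates(self) -> dict[str, str]:
        """Six-decimal fixed-point strings; undefined rates render blank."""
        return {
            k: ("" if v is None else f"{v:.6f}") for k, v in self.rates_dict().items()
        }


def _rate(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> EvalReport:
    """Rate bundle from non-negative integer confusion counts."""
    counts = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
    for name, v in counts.items():
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    tp, fp, fn, tn = int(tp), int(fp), int(fn), int(tn)
    if tp + fn == 0 and fp + tn == 0:
        raise ValueError("confusion matrix is empty")
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        tpr=_rate(tp, tp + fn),
        fpr=_rate(fp, fp + tn),
        precision=_rate(tp, tp + fp),
        specificity=_rate(tn, tn + fp),
        f1=_rate(2 * tp, 2 * tp + fp + fn),
    )


def confusion_counts(y_true, y_pred, positive=+1) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) with ``positive`` as the active class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    pred_pos = y_pred == positive
    tp = int(np.sum(pos & pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    return tp, fp, fn, tn


def roc_auc(decision_values, labels, positive=+1):
    """AUC (rank statistic, half-credit ties) and ROC points by threshold sweep.

    Returns ``(auc, points)`` where points is an (m, 3) array of
    (threshold, FPR, TPR) rows.
    """
    decision_values = np.asarray(decision_values, dtype=np.float64)
    labels = np.asarray(labels)
    y = (labels == positive).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute ROC/AUC")
    auc = float(roc_auc_score(y, decision_values))
    fpr, tpr, thresholds = roc_curve(y, decision_values)
    points = np.column_stack([thresholds, fpr, tpr])
    return auc, points


def write_roc_tsv(points, path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tFPR\tTPR\n")
        for thr, f, t in points:
            fh.write(f"{thr:.10g}\t{f:.6f}\t{t:.6f}\n")
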