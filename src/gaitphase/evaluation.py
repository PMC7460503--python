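"""Multiclass evaluation calculus for the four gait phases.

Implements the exact metric definitions the networks are judged by:
confusion matrices (rows = actual, columns = predicted, class order
HS, FF, HO, SW), per-class one-vs-rest precision / recall / F1 as
percentages, overall accuracy, macro precision and recall as unweighted
class means, macro-F1 as the *harmonic mean of macro-P and macro-R*

    macro-F1 = 2 * macro-P * macro-R / (macro-P + macro-R)

(note: not the mean of per-class F1 scores), and one-vs-rest ROC curves with
macro-AUC as the unweighted mean of the per-class areas.  Divisions 0/0
yield 0 — a class that is never predicted and never occurs scores zero, the
convention used in the reference result tables.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PHASE_NAMES", "ConfusionMatrix", "ClassMetrics", "MetricsReport",
    "confusion_matrix", "per_class_prf", "accuracy", "macro_metrics",
    "roc_ovr", "evaluate",
]

PHASE_NAMES = ("HS", "FF", "HO", "SW")
N_CLASSES = 4

logger = logging.getLogger(__name__)


def _safe_div(num: float, den: float) -> float:
    """x/y with the 0/0 -> 0 convention used throughout the metric set."""
    return 0.0 if den == 0 else num / den


@dataclass
class ConfusionMatrix:
    """4x4 integer counts; ``counts[i, j]`` = examples of true class i
    predicted as class j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("confusion matrix must be 4x4")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self) -> str:
        head = "true\\pred " + " ".join(f"{p:>6}" for p in PHASE_NAMES)
        rows = [
            f"{PHASE_NAMES[i]:>9} " + " ".join(f"{c:6d}" for c in self.counts[i])
            for i in range(N_CLASSES)
        ]
        return "\n".join([head, *rows])


@dataclass
class ClassMetrics:
    """One-vs-rest counts and percentage P/R/F1 for a single phase."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float  # %
    recall: float  # %
    f1: float  # %


@dataclass
class MetricsReport:
    """Full scorecard for one model on one test set (percent scale except
    macro_auc, which is 0-1)."""

    accuracy: float
    macro_p: float
    macro_r: float
    macro_f1: float
    macro_auc: float
    per_class: dict[str, ClassMetrics]
    confusion: ConfusionMatrix
    roc_points: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 1),
            "macro_p": round(self.macro_p, 1),
            "macro_r": round(self.macro_r, 1),
            "macro_f1": round(self.macro_f1, 1),
            "macro_auc": round(self.macro_auc, 4),
            "per_class": {
                name: {
                    "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
                    "precision": round(m.precision, 1),
                    "recall": round(m.recall, 1),
                    "f1": round(m.f1, 1),
                }
                for name, m in self.per_class.items()
            },
            "confusion": self.confusion.counts.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = ["Phase       Precision(%)  Recall(%)    F1(%)"]
        for name in PHASE_NAMES:
            m = self.per_class[name]
            lines.append(
                f"{name:<12}{m.precision:11.1f}{m.recall:11.1f}{m.f1:9.1f}"
            )
        lines += [
            "",
            f"Accuracy (%):  {self.accuracy:.1f}",
            f"Macro-P (%):   {self.macro_p:.1f}",
            f"Macro-R (%):   {self.macro_r:.1f}",
            f"Macro-F1 (%):  {self.macro_f1:.1f}",
            f"Macro-AUC:     {self.macro_auc:.4f}",
            "",
            self.confusion.to_text(),
        ]
        return "\n".join(lines)


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a 4x4 matrix."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError(f"{name} labels must lie in 0..3")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def per_class_prf(cm: ConfusionMatrix) -> dict[str, ClassMetrics]:
    """One-vs-rest TP/FP/FN/TN and percentage P, R, F1 per phase.

    P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); any 0/0 gives 0.
    """
    c = cm.counts
    total = c.sum()
    out: dict[str, ClassMetrics] = {}
    for i, name in enumerate(PHASE_NAMES):
        tp = int(c[i, i])
        fp = int(c[:, i].sum() - tp)
        fn = int(c[i, :].sum() - tp)
        tn = int(total - tp - fp - fn)
        p = 100.0 * _safe_div(tp, tp + fp)
        r = 100.0 * _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * p * r, p + r)
        out[name] = ClassMetrics(tp=tp, fp=fp, fn=fn, tn=tn,
                                 precision=p, recall=r, f1=f1)
    return out


def accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of correctly classified examples: 100 * trace / total."""
    total = cm.total
    if total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / total


def macro_metrics(per_class: dict[str, ClassMetrics]) -> tuple[float, float, float]:
    """(macro-P, macro-R, macro-F1): unweighted means of per-class P and R,
    combined by their harmonic mean."""
    ps = [m.precision for m in per_class.values()]
    rs = [m.recall for m in per_class.values()]
    macro_p = float(np.mean(ps))
    macro_r = float(np.mean(rs))
    macro_f1 = _safe_div(2 * macro_p * macro_r, macro_p + macro_r)
    return macro_p, macro_r, macro_f1


def _binary_roc(truth: np.ndarray, scores: np.ndarray):
    """ROC points (fpr, tpr) at every distinct threshold, descending, plus
    trapezoidal AUC.  ``truth`` is boolean, ``scores`` higher = more
    positive."""
    order = np.argsort(-scores, kind="stable")
    truth = truth[order].astype(float)
    scores = scores[order]
    tps = np.cumsum(truth)
    fps = np.cumsum(1.0 - truth)
    # keep the last index of each run of equal scores
    distinct = np.r_[np.flatnonzero(np.diff(scores)), len(scores) - 1]
    tps, fps = tps[distinct], fps[distinct]
    p = tps[-1]
    n = fps[-1]
    tpr = np.r_[0.0, tps / p] if p > 0 else np.zeros(len(tps) + 1)
    fpr = np.r_[0.0, fps / n] if n > 0 else np.zeros(len(fps) + 1)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_ovr(y_true, scores) -> tuple[dict[str, np.ndarray], float]:
    """One-vs-rest ROC per phase and the macro-AUC.

    ``scores`` is (N, 4) with row-wise class probabilities.  Returns
    ``(roc_points, macro_auc)`` where ``roc_points[name]`` is an array of
    (fpr, tpr) rows and macro-AUC is the unweighted mean of the per-class
    AUCs.  A class absent from ``y_true`` has no defined AUC; it is excluded
    from the mean with a warning.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != N_CLASSES:
        raise ValueError("scores must be (N, 4)")
    if len(y_true) != len(scores):
        raise ValueError("labels and scores disagree in length")
    roc: dict[str, np.ndarray] = {}
    aucs = []
    for i, name in enumerate(PHASE_NAMES):
        truth = y_true == i
        if truth.sum() == 0 or truth.sum() == len(truth):
            warnings.warn(
                f"class {name} absent from one side of the labels; "
                "its AUC is undefined and excluded from the macro mean",
                stacklevel=2,
            )
            continue
        fpr, tpr, auc = _binary_roc(truth, scores[:, i])
        roc[name] = np.column_stack([fpr, tpr])
        aucs.append(auc)
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    return roc, macro_auc


def evaluate(y_true, y_pred, scores=None) -> MetricsReport:
    """Assemble the full report from labels, predictions and (optionally)
    probability scores for ROC/AUC."""
    cm = confusion_matrix(y_true, y_pred)
    per_class = per_class_prf(cm)
    macro_p, macro_r, macro_f1 = macro_metrics(per_class)
    if scores is not None:
        roc, macro_auc = roc_ovr(y_true, scores)
    else:
        roc, macro_auc = {}, float("nan")
    return MetricsReport(
        accuracy=accuracy(cm),
        macro_p=macro_p,
        macro_r=macro_r,
        macro_f1=macro_f1,
        macro_auc=macro_auc,
        per_class=per_class,
        confusion=cm,
        roc_points=roc,
    )
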