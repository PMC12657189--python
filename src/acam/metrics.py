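"""Classification metrics: confusion matrix, P/R/F1, ROC/AUC, PR/AP.

Per-class precision, recall, F1 and accuracy follow the standard
one-vs-rest confusion-matrix definitions

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the convention that a metric is 0 when its denominator is 0. ROC
curves/AUC (trapezoidal, half credit for score ties — the rank-sum
equivalent) and PR curves/step-interpolated AP are delegated to
scikit-learn. Aggregates are reported both macro- and support-weighted;
for single-label problems the weighted recall equals the accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

__all__ = [
    "BinaryCounts",
    "MetricsReport",
    "confusion",
    "one_vs_rest",
    "prf_metrics",
    "roc_auc",
    "pr_ap",
    "evaluate",
]


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Confusion matrix: rows are true classes, columns predicted classes."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and of equal length")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= n_classes or y_pred.min() < 0 or y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    m = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(m, (y_true, y_pred), 1)
    return m


def one_vs_rest(m: np.ndarray, k: int) -> BinaryCounts:
    """Reduce a multiclass confusion matrix to binary counts for class k."""
    m = np.asarray(m)
    tp = int(m[k, k])
    fn = int(m[k].sum() - tp)
    fp = int(m[:, k].sum() - tp)
    tn = int(m.sum() - tp - fn - fp)
    return BinaryCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def prf_metrics(c: BinaryCounts) -> tuple[float, float, float, float]:
    """(precision, recall, F1, accuracy) with zero-denominator -> 0."""
    precision = _safe_div(c.tp, c.tp + c.fp)
    recall = _safe_div(c.tp, c.tp + c.fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    accuracy = _safe_div(c.tp + c.tn, c.total)
    return precision, recall, f1, accuracy


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve points (fpr, tpr) and trapezoidal AUC for binary labels."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/AUC is undefined without both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr]), float(roc_auc_score(labels, scores))


def pr_ap(scores, labels) -> tuple[np.ndarray, float]:
    """PR curve points (recall, precision) and step-interpolated AP."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("average precision is undefined without positives")
    precision, recall, _ = precision_recall_curve(labels, scores)
    return np.column_stack([recall, precision]), float(average_precision_score(labels, scores))


@dataclass
class MetricsReport:
    """Scalar summaries plus per-class curves for one evaluation run."""

    accuracy: float
    confusion_matrix: list
    per_class: list  # dicts: class, support, precision, recall, f1, auc, ap
    macro: dict
    weighted: dict
    curves: dict = field(default_factory=dict)  # class -> {"roc": [...], "pr": [...]}

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def confusion_to_csv(self, path) -> None:
        np.savetxt(path, np.asarray(self.confusion_matrix, dtype=int), fmt="%d", delimiter=",")


def _aggregate(rows: list[dict], weights: np.ndarray) -> dict:
    out = {}
    for key in ("precision", "recall", "f1"):
        vals = np.array([r[key] for r in rows])
        out[key] = float(np.average(vals, weights=weights)) if weights.sum() else 0.0
    return out


def report_from_scores(y_true: np.ndarray, proba: np.ndarray, n_classes: int) -> MetricsReport:
    """Build a full report from true labels and class-score rows."""
    y_true = np.asarray(y_true, dtype=int)
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty split")
    y_pred = proba.argmax(axis=1)
    m = confusion(y_true, y_pred, n_classes)
    rows, curves = [], {}
    for k in range(n_classes):
        counts = one_vs_rest(m, k)
        precision, recall, f1, _ = prf_metrics(counts)
        binary = (y_true == k).astype(int)
        auc = ap = None
        if 0 < binary.sum() < binary.size:
            roc_pts, auc = roc_auc(proba[:, k], binary)
            pr_pts, ap = pr_ap(proba[:, k], binary)
            curves[str(k)] = {"roc": roc_pts.tolist(), "pr": pr_pts.tolist()}
        rows.append(
            {
                "class": k,
                "support": int(m[k].sum()),
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "auc": auc,
                "ap": ap,
            }
        )
    support = np.array([r["support"] for r in rows], dtype=float)
    return MetricsReport(
        accuracy=float(np.trace(m) / m.sum()),
        confusion_matrix=m.tolist(),
        per_class=rows,
        macro=_aggregate(rows, np.ones(n_classes)),
        weighted=_aggregate(rows, support),
        curves=curves,
    )


def evaluate(bundle, images: np.ndarray, manifest, split: str = "test") -> MetricsReport:
    """Run inference on one manifest split and build the metrics report."""
    idx = manifest.split_index(split)
    if idx.size == 0:
        raise ValueError(f"split {split!r} is empty")
    y_true = manifest.records["class"].to_numpy()[idx]
    clf = bundle.classifier if hasattr(bundle, "classifier") else bundle
    proba = clf.predict_proba(images[idx])
    return report_from_scores(y_true, proba, n_classes=len(clf.classes_))
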