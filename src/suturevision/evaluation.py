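"""Multiclass evaluation: confusion matrix, P/R/F1, accuracy, one-vs-rest AUC.

For each age-range label X the confusion matrix yields TP (diagonal), FP
(column residue), FN (row residue) and TN (everything else), from which

    P_X = TP / (TP + FP)        R_X = TP / (TP + FN)
    F1_X = 2 P R / (P + R)      Acc = trace / total

ROC analysis is one-vs-rest on the class-X softmax score with a rank-based
(Mann-Whitney, midrank-tied) AUC; the summary value is the arithmetic mean
of the five per-class AUCs.

Accuracy note: the per-class quantity (TP_X + TN_X) / N summed over classes
(without dividing by the class count) is also reported as
``per_class_acc_sum``; it is a different statistic from the proportion of
correctly identified samples, which is the primary ``accuracy``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import N_CLASSES, label_name

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "class_metrics",
    "accuracy",
    "f1_score",
    "roc_auc",
    "roc_curve_points",
    "evaluate_predictions",
]


@dataclass
class ConfusionMatrix:
    """Counts[i][j] = number of samples with actual label i predicted as j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected {N_CLASSES}x{N_CLASSES} counts, got {self.counts.shape}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true_labels, pred_labels) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(pred_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size and (t.min() < 0 or t.max() >= N_CLASSES or p.min() < 0 or p.max() >= N_CLASSES):
        raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class MetricsReport:
    """Per-class counts and rates plus the aggregate accuracy figures."""

    per_class: pd.DataFrame
    accuracy: float
    per_class_acc_sum: float
    average_auc: float | None = None

    def to_table(self) -> pd.DataFrame:
        """Evaluation table: one row per label (age range) plus summary rows."""
        df = self.per_class.copy()
        df.insert(0, "label (age range)", [f"{i} ({label_name(i)})" for i in df.index])
        return df


def class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class TP/FP/FN/TN with precision, recall and F1; 0/0 reported as 0."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    for x in range(N_CLASSES):
        tp = int(counts[x, x])
        fp = int(counts[:, x].sum() - tp)
        fn = int(counts[x, :].sum() - tp)
        tn = total - tp - fp - fn
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        rows.append(
            {
                "TP": tp,
                "FP": fp,
                "FN": fn,
                "TN": tn,
                "precision": p,
                "recall": r,
                "f1": f1_score(p, r),
                "precision_defined": bool(tp + fp),
                "recall_defined": bool(tp + fn),
                "support": tp + fn,
            }
        )
    per_class = pd.DataFrame(rows)
    acc = float(np.trace(counts) / total)
    # per-class (TP+TN)/N summed over the five classes (no division by 5)
    pc_sum = float(sum((row["TP"] + row["TN"]) / total for row in rows))
    return MetricsReport(per_class=per_class, accuracy=acc, per_class_acc_sum=pc_sum)


def accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of correctly identified samples: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def _auc_rank(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.concatenate([pos_scores, neg_scores])
    ranks = stats.rankdata(scores)  # midranks
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    rank_sum_pos = ranks[:n_pos].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: np.ndarray, true_labels) -> tuple[dict[int, float], float]:
    """One-vs-rest AUC per class and their arithmetic mean.

    ``scores`` is the n x 5 probability matrix (rows sum to 1). Classes
    absent from the truth (or covering all samples) have undefined AUC and
    are excluded from the average with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    t = np.asarray(true_labels, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[1] != N_CLASSES:
        raise ValueError(f"expected n x {N_CLASSES} score matrix, got {scores.shape}")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("score rows must sum to 1")
    aucs: dict[int, float] = {}
    for x in range(N_CLASSES):
        pos = scores[t == x, x]
        neg = scores[t != x, x]
        if len(pos) == 0 or len(neg) == 0:
            warnings.warn(f"class {x} absent from one side of the truth; AUC undefined")
            continue
        aucs[x] = _auc_rank(pos, neg)
    avg = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return aucs, avg


def roc_curve_points(scores: np.ndarray, true_labels, class_x: int) -> pd.DataFrame:
    """Empirical one-vs-rest ROC curve (FPR, TPR) for one class."""
    s = np.asarray(scores)[:, class_x]
    y = (np.asarray(true_labels) == class_x).astype(int)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tps = np.concatenate([[0], np.cumsum(y)])
    fps = np.concatenate([[0], np.cumsum(1 - y)])
    tpr = tps / max(tps[-1], 1)
    fpr = fps / max(fps[-1], 1)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def evaluate_predictions(scores: np.ndarray, true_labels) -> MetricsReport:
    """Full report from a score matrix: confusion-based rates plus AUCs."""
    preds = np.asarray(scores).argmax(axis=1)
    report = class_metrics(confusion(true_labels, preds))
    aucs, avg = roc_auc(scores, true_labels)
    report.per_class["auc"] = [aucs.get(x, float("nan")) for x in range(N_CLASSES)]
    report.average_auc = avg
    return report
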