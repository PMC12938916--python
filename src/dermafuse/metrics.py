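"""Classification metrics from confusion counts and score matrices.

Balanced accuracy (unweighted mean of per-class recall), overall accuracy,
per-class precision/recall/F1, one-vs-rest specificity and class-wise
accuracy, and macro AUC via the rank (Mann-Whitney) statistic with midrank
tie handling.  Everything is computed at full precision; percentages are
rounded half-up to one decimal only when a report is assembled.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionSummary",
    "accuracy",
    "bacc",
    "balanced_accuracy_from_recalls",
    "f1_from_precision_recall",
    "macro_auc",
    "metrics_report",
    "precision_recall_f1",
    "round_half_up",
    "specificity_and_class_accuracy",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (0.05 -> 0.1)."""
    factor = 10.0 ** decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


class ConfusionSummary:
    """k×k confusion counts, rows = true class, cols = predicted."""

    def __init__(self, counts):
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be >= 0")

    @classmethod
    def from_labels(cls, y_true, y_pred, n_classes: int = 6) -> "ConfusionSummary":
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            counts[int(t), int(p)] += 1
        return cls(counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, i: int) -> int:
        return int(self.counts[i, i])

    def fn(self, i: int) -> int:
        return int(self.counts[i].sum() - self.counts[i, i])

    def fp(self, i: int) -> int:
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def tn(self, i: int) -> int:
        return self.total - self.tp(i) - self.fp(i) - self.fn(i)


def bacc(cm: ConfusionSummary) -> float:
    """Balanced accuracy in percent: mean per-class recall."""
    recalls = []
    for i in range(cm.n_classes):
        denom = cm.tp(i) + cm.fn(i)
        if denom == 0:
            raise ValueError(f"class {i} has no true samples; recall undefined")
        recalls.append(cm.tp(i) / denom)
    return 100.0 * float(np.mean(recalls))


def balanced_accuracy_from_recalls(recalls_percent) -> float:
    """Mean of per-class recalls already expressed in percent."""
    return float(np.mean(np.asarray(recalls_percent, dtype=float)))


def accuracy(cm: ConfusionSummary) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def f1_from_precision_recall(precision_pct: float, recall_pct: float) -> float:
    if precision_pct + recall_pct == 0:
        return float("nan")
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def precision_recall_f1(cm: ConfusionSummary, i: int) -> tuple[float, float, float]:
    """(precision %, recall %, F1 %); undefined denominators yield NaN flags."""
    pp = cm.tp(i) + cm.fp(i)
    ap = cm.tp(i) + cm.fn(i)
    precision = 100.0 * cm.tp(i) / pp if pp > 0 else float("nan")
    recall = 100.0 * cm.tp(i) / ap if ap > 0 else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = f1_from_precision_recall(precision, recall)
    return precision, recall, f1


def specificity_and_class_accuracy(cm: ConfusionSummary, i: int) -> tuple[float, float]:
    """One-vs-rest (specificity %, class-wise accuracy %)."""
    tn, fp = cm.tn(i), cm.fp(i)
    specificity = 100.0 * tn / (tn + fp) if tn + fp > 0 else float("nan")
    class_acc = 100.0 * (cm.tp(i) + tn) / cm.total if cm.total > 0 else float("nan")
    return specificity, class_acc


def _binary_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-statistic AUC with midrank tie credit."""
    scores = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(scores)  # midranks
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    rank_sum = ranks[:n_pos].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def macro_auc(scores: np.ndarray, y_true) -> float:
    """Unweighted mean one-vs-rest AUC, in percent.

    Classes absent from the labels are excluded with a warning (the mean is
    then over the present classes only).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.ndim != 2:
        raise ValueError("scores must be (n, n_classes)")
    present = np.unique(y_true)
    if len(present) < 2:
        raise ValueError("need at least 2 classes present to compute AUC")
    aucs = []
    for c in range(scores.shape[1]):
        mask = y_true == c
        if not mask.any():
            warnings.warn(f"class {c} absent from labels; excluded from macro AUC "
                          f"(mean taken over present classes)")
            continue
        if mask.all():
            warnings.warn(f"class {c} has no negatives; excluded from macro AUC")
            continue
        aucs.append(_binary_auc(scores[mask, c], scores[~mask, c]))
    return 100.0 * float(np.mean(aucs))


def metrics_report(y_true, y_pred, scores=None,
                   class_labels=("ACK", "BCC", "MEL", "NEV", "SCC", "SEK")) -> dict:
    """Assemble the {bacc, acc, macro_auc, per_class} report, percentages
    rounded half-up to one decimal."""
    cm = ConfusionSummary.from_labels(y_true, y_pred, n_classes=len(class_labels))
    # mean recall over classes actually present, so small evaluation sets
    # that miss a rare class entirely still yield a report
    recalls = [cm.tp(i) / (cm.tp(i) + cm.fn(i))
               for i in range(cm.n_classes) if cm.tp(i) + cm.fn(i) > 0]
    report = {
        "bacc": round_half_up(100.0 * float(np.mean(recalls))),
        "acc": round_half_up(accuracy(cm)),
        "macro_auc": round_half_up(macro_auc(scores, y_true)) if scores is not None else None,
        "per_class": {},
    }
    scores = None if scores is None else np.asarray(scores, dtype=float)
    y_arr = np.asarray(y_true)
    for i, name in enumerate(class_labels):
        p, r, f1 = precision_recall_f1(cm, i)
        spec, ca = specificity_and_class_accuracy(cm, i)
        entry = {
            "precision": round_half_up(p) if np.isfinite(p) else None,
            "sensitivity": round_half_up(r) if np.isfinite(r) else None,
            "specificity": round_half_up(spec) if np.isfinite(spec) else None,
            "f1": round_half_up(f1) if np.isfinite(f1) else None,
            "class_accuracy": round_half_up(ca) if np.isfinite(ca) else None,
        }
        if scores is not None and (y_arr == i).any() and not (y_arr == i).all():
            auc_i = _binary_auc(scores[y_arr == i, i], scores[y_arr != i, i])
            entry["auc"] = round_half_up(100.0 * auc_i)
        else:
            entry["auc"] = None
        report["per_class"][name] = entry
    return report
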