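"""Multi-label evaluation metrics.

The headline metric is the label-based accuracy (Hamming score): the mean
per-compound Jaccard overlap between the predicted and true label sets,

    A = (1/n) * sum_i |y_i & yhat_i| / |y_i | yhat_i|

which credits partially correct predictions, unlike the exact match ratio.
A row where both sets are empty contributes 1 (the standard convention for
this accuracy; flagged in the report because real amenability data rarely
triggers it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .tabular_io import LabelMatrix


def _as_binary(m) -> np.ndarray:
    arr = m.labels if isinstance(m, LabelMatrix) else np.asarray(m)
    arr = np.asarray(arr, dtype=int)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _check_shapes(truth: np.ndarray, pred: np.ndarray) -> None:
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape} vs pred {pred.shape}")


def label_based_accuracy(truth, pred) -> float:
    """Mean per-row Jaccard overlap of the label sets (in [0, 1])."""
    t, p = _as_binary(truth), _as_binary(pred)
    _check_shapes(t, p)
    inter = (t & p).sum(axis=1).astype(float)
    union = (t | p).sum(axis=1).astype(float)
    scores = np.where(union == 0, 1.0, inter / np.where(union == 0, 1, union))
    return float(scores.mean())


def exact_match_ratio(truth, pred) -> float:
    """Fraction of rows whose predicted label set is exactly correct."""
    t, p = _as_binary(truth), _as_binary(pred)
    _check_shapes(t, p)
    return float((t == p).all(axis=1).mean())


@dataclass
class MetricsReport:
    """Per-class and averaged classification report, percentages to 2 dp."""

    class_names: list[str]
    per_class: dict[str, dict[str, float]]      # precision/recall/f1/accuracy
    confusion: dict[str, dict[str, int]]        # TP/FP/FN/TN per class
    averages: dict[str, dict[str, float]]       # micro/macro/weighted/samples
    label_based_accuracy: float                 # percent
    exact_match_ratio: float                    # percent
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "per_class": self.per_class,
            "confusion": self.confusion,
            "averages": self.averages,
            "label_based_accuracy": self.label_based_accuracy,
            "exact_match_ratio": self.exact_match_ratio,
            "flags": self.flags,
        }

    def to_tsv(self) -> str:
        """Classification-report table in the per-class / averages layout."""
        lines = ["\tPrecision\tRecall\tF1-Score\tAccuracy"]
        for cls in self.class_names:
            row = self.per_class[cls]
            lines.append(f"{cls} class\t{row['precision']:.2f}\t{row['recall']:.2f}"
                         f"\t{row['f1']:.2f}\t{row['accuracy']:.2f}")
        for avg in ("micro", "macro", "weighted", "samples"):
            row = self.averages[avg]
            lines.append(f"{avg.capitalize()} average\t{row['precision']:.2f}"
                         f"\t{row['recall']:.2f}\t{row['f1']:.2f}\t")
        return "\n".join(lines) + "\n"


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(f"zero denominator in {what}; reported as 0")
        return 0.0
    return num / den


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def classification_report(truth, pred,
                          class_names: tuple[str, str] = ("GC", "LC"),
                          ) -> MetricsReport:
    """Per-class precision/recall/F1/accuracy with micro, macro, weighted and
    samples averages, all as percentages rounded to 2 decimals."""
    t, p = _as_binary(truth), _as_binary(pred)
    _check_shapes(t, p)
    n, k = t.shape
    if k != len(class_names):
        raise ValueError("class_names length must match label columns")
    flags: list[str] = []

    per_class: dict[str, dict[str, float]] = {}
    confusion: dict[str, dict[str, int]] = {}
    precisions, recalls, f1s, supports = [], [], [], []
    for j, cls in enumerate(class_names):
        tp = int(((t[:, j] == 1) & (p[:, j] == 1)).sum())
        fp = int(((t[:, j] == 0) & (p[:, j] == 1)).sum())
        fn = int(((t[:, j] == 1) & (p[:, j] == 0)).sum())
        tn = int(((t[:, j] == 0) & (p[:, j] == 0)).sum())
        prec = _safe_div(tp, tp + fp, flags, f"{cls} precision")
        rec = _safe_div(tp, tp + fn, flags, f"{cls} recall")
        confusion[cls] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
        per_class[cls] = {
            "precision": round(100 * prec, 2),
            "recall": round(100 * rec, 2),
            "f1": round(100 * _f1(prec, rec), 2),
            "accuracy": round(100 * (tp + tn) / n, 2),
        }
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(_f1(prec, rec))
        supports.append(tp + fn)

    # micro: pool the 2x2 counts over classes
    tp_all = sum(confusion[c]["TP"] for c in class_names)
    fp_all = sum(confusion[c]["FP"] for c in class_names)
    fn_all = sum(confusion[c]["FN"] for c in class_names)
    micro_p = _safe_div(tp_all, tp_all + fp_all, flags, "micro precision")
    micro_r = _safe_div(tp_all, tp_all + fn_all, flags, "micro recall")

    weights = np.asarray(supports, dtype=float)
    if weights.sum() == 0:
        flags.append("zero total support; weighted averages reported as 0")
        weights = np.ones_like(weights)
    weights = weights / weights.sum()

    # samples: per-row precision/recall/F1 averaged over rows; empty
    # prediction or truth sets give that row 0 for the affected rate
    row_inter = (t & p).sum(axis=1).astype(float)
    n_pred = p.sum(axis=1).astype(float)
    n_true = t.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_prec = np.where(n_pred == 0, 0.0, row_inter / np.where(n_pred == 0, 1, n_pred))
        row_rec = np.where(n_true == 0, 0.0, row_inter / np.where(n_true == 0, 1, n_true))
    denom = row_prec + row_rec
    row_f1 = np.where(denom == 0, 0.0, 2 * row_prec * row_rec / np.where(denom == 0, 1, denom))
    if (n_pred == 0).any() or (n_true == 0).any():
        flags.append("rows with empty prediction or truth set scored 0 in samples average")

    averages = {
        "micro": {"precision": round(100 * micro_p, 2),
                  "recall": round(100 * micro_r, 2),
                  "f1": round(100 * _f1(micro_p, micro_r), 2)},
        "macro": {"precision": round(100 * float(np.mean(precisions)), 2),
                  "recall": round(100 * float(np.mean(recalls)), 2),
                  "f1": round(100 * float(np.mean(f1s)), 2)},
        "weighted": {"precision": round(100 * float(np.dot(weights, precisions)), 2),
                     "recall": round(100 * float(np.dot(weights, recalls)), 2),
                     "f1": round(100 * float(np.dot(weights, f1s)), 2)},
        "samples": {"precision": round(100 * float(row_prec.mean()), 2),
                    "recall": round(100 * float(row_rec.mean()), 2),
                    "f1": round(100 * float(row_f1.mean()), 2)},
    }
    if ((t.sum(axis=1) == 0) & (p.sum(axis=1) == 0)).any():
        flags.append("rows with both label sets empty scored 1 in label-based accuracy")

    return MetricsReport(
        class_names=list(class_names),
        per_class=per_class,
        confusion=confusion,
        averages=averages,
        label_based_accuracy=round(100 * label_based_accuracy(t, p), 2),
        exact_match_ratio=round(100 * exact_match_ratio(t, p), 2),
        flags=flags,
    )


def roc_auc(truth_column, scores) -> tuple[np.ndarray, float]:
    """ROC curve points and AUC for one label.

    The AUC is the rank statistic: the probability that a random positive
    outscores a random negative, with ties counted 1/2.  This equals the
    trapezoidal area under the empirical ROC step curve.  Binary 0/1 scores
    yield the one-point ROC, in which case the AUC is the balanced accuracy.
    """
    y = np.asarray(truth_column, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.shape != s.shape:
        raise ValueError("truth and scores must have the same length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return np.column_stack([fpr, tpr]), float(auc)
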