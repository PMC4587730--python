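"""Binary and multi-class classification performance measures.

Binary measures (accuracy, precision, recall, Matthews correlation
coefficient) are computed from tp/tn/fp/fn counts. Multi-class measures
come from the full K x K confusion matrix C, where C[i, j] counts items of
true class i predicted as class j. Two multi-class accuracies are
reported because both conventions appear in practice: the overall
proportion of correctly classified instances (trace / N, the headline
number here) and the mean of the per-class one-vs-rest binary accuracies.
The multi-class MCC is the generalized correlation coefficient over all
entries of C (range -1..1, 1 = perfect, 0 = random-like structure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "BinaryCounts",
    "binary_metrics",
    "confusion",
    "multiclass_metrics",
    "metrics_report",
]


@dataclass(frozen=True)
class BinaryCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def binary_metrics(counts: BinaryCounts) -> dict:
    """Accuracy, precision, recall and MCC from binary counts.

    Metrics with a zero denominator are returned as NaN and named in the
    ``degenerate`` set, except MCC where the 0/0 case returns 0 by the
    usual convention (single-class predictions carry no correlation) and
    is likewise flagged.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    degenerate: set[str] = set()

    if counts.total == 0:
        accuracy = math.nan
        degenerate.add("accuracy")
    else:
        accuracy = (tp + tn) / counts.total

    if tp + fp == 0:
        precision = math.nan
        degenerate.add("precision")
    else:
        precision = tp / (tp + fp)

    if tp + fn == 0:
        recall = math.nan
        degenerate.add("recall")
    else:
        recall = tp / (tp + fn)

    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        mcc = 0.0
        degenerate.add("mcc")
    else:
        mcc = (tp * tn - fp * fn) / denom

    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "mcc": mcc,
        "degenerate": frozenset(degenerate),
    }


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K confusion matrix over 1-based integer class labels.

    C[i-1, j-1] counts items of true class i predicted as class j.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.arange(1, n_classes + 1)
    for vec, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        bad = np.setdiff1d(vec, labels)
        if bad.size:
            raise ValueError(f"{name} contains label(s) {bad.tolist()} outside 1..{n_classes}")
    return _sk_confusion(y_true, y_pred, labels=labels)


def _binary_counts_for_class(C: np.ndarray, k: int) -> BinaryCounts:
    """One-vs-rest binarization of the confusion matrix for class index k (0-based)."""
    tp = int(C[k, k])
    fn = int(C[k].sum() - C[k, k])
    fp = int(C[:, k].sum() - C[k, k])
    tn = int(C.sum() - tp - fn - fp)
    return BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def mcc_multiclass(C: np.ndarray) -> tuple[float, bool]:
    """Generalized MCC over all entries of the confusion matrix.

    numerator   = sum_{k,l,m} C_kk * C_ml - C_lk * C_km
    denominator = sqrt(sum_k colsum_k * (N - colsum_k))
                * sqrt(sum_k rowsum_k * (N - rowsum_k))

    Returns (value, degenerate); a zero denominator (all mass in one row
    or one column) yields 0 with the degenerate flag set.
    """
    C = np.asarray(C, dtype=float)
    s = C.sum()
    trace = np.trace(C)
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    numerator = trace * s - float(col @ row)
    denom = math.sqrt(max(s * s - float(col @ col), 0.0)) * math.sqrt(
        max(s * s - float(row @ row), 0.0)
    )
    if denom == 0:
        return 0.0, True
    return numerator / denom, False


def multiclass_metrics(C: np.ndarray) -> dict:
    """Global and per-class measures from a K x K confusion matrix."""
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] < 2:
        raise ValueError("confusion matrix must be square with K >= 2")
    if np.any(C < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    n = C.sum()
    if n == 0:
        raise ValueError("confusion matrix is all zero")
    k_classes = C.shape[0]

    per_class = {m: [] for m in ("precision", "recall", "mcc")}
    acc_binary = []
    for k in range(k_classes):
        bm = binary_metrics(_binary_counts_for_class(C, k))
        acc_binary.append(bm["accuracy"])
        for m in per_class:
            per_class[m].append(bm[m])

    mcc, degenerate = mcc_multiclass(C)
    return {
        "accuracy_overall": float(np.trace(C) / n),
        "accuracy_table_mean": float(np.mean(acc_binary)),
        "mcc_multiclass": mcc,
        "mcc_degenerate": degenerate,
        "per_class": {m: np.array(v) for m, v in per_class.items()},
    }


def metrics_report(C: np.ndarray, classes: list[str]) -> pd.DataFrame:
    """One row per class plus a global row, ready for CSV export."""
    res = multiclass_metrics(C)
    rows = []
    for k, name in enumerate(classes):
        rows.append(
            {
                "class": name,
                "precision": res["per_class"]["precision"][k],
                "recall": res["per_class"]["recall"][k],
                "mcc": res["per_class"]["mcc"][k],
            }
        )
    rows.append(
        {
            "class": "GLOBAL",
            "precision": math.nan,
            "recall": math.nan,
            "mcc": res["mcc_multiclass"],
            "accuracy_overall": res["accuracy_overall"],
            "accuracy_table_mean": res["accuracy_table_mean"],
        }
    )
    return pd.DataFrame(rows)
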