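"""Confusion matrix and per-class classification metrics.

Precision = TP / (TP + FP), Recall = TP / (TP + FN),
F1 = 2 P R / (P + R), overall accuracy = trace / total.
Zero-denominator cases yield 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_matrix",
    "average_accuracy",
    "per_class_metrics",
    "f1_score",
    "metrics_table",
    "write_metrics_csv",
    "round_half_up",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K), rows = true class, columns = predicted
    class_labels: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.class_labels = tuple(str(l) for l in self.class_labels)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if self.counts.shape[0] != len(self.class_labels):
            raise ValueError("label count does not match matrix size")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.counts, index=list(self.class_labels),
                          columns=list(self.class_labels))
        df.index.name = "true\\pred"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=np.int64), tuple(df.columns))


@dataclass
class ClassMetrics:
    labels: tuple
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray


def confusion_matrix(truth: Sequence, pred: Sequence,
                     labels: Sequence[str]) -> ConfusionMatrix:
    """Count table: entry (i, j) = occurrences of true label i predicted as j."""
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise ValueError(
            f"truth ({len(truth)}) and pred ({len(pred)}) lengths differ"
        )
    labels = [str(l) for l in labels]
    index = {lab: i for i, lab in enumerate(labels)}
    if len(index) != len(labels):
        raise ValueError("labels contain duplicates")
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truth, pred):
        t, p = str(t), str(p)
        if t not in index or p not in index:
            raise ValueError(f"observed label not in label set: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(labels))


def average_accuracy(cm: ConfusionMatrix) -> float:
    """Sum of per-class true positives over the total sample count."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    bad = den == 0
    if bad.any():
        warnings.warn(f"{what}: zero denominator for {int(bad.sum())} class(es); "
                      "reporting 0", stacklevel=3)
    out[~bad] = num[~bad] / den[~bad]
    return out


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def per_class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    counts = cm.counts
    total = cm.total
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn
    precision = _safe_div(tp.astype(float), (tp + fp).astype(float), "precision")
    recall = _safe_div(tp.astype(float), (tp + fn).astype(float), "recall")
    denom = precision + recall
    f1 = np.zeros_like(precision)
    nz = denom > 0
    f1[nz] = 2.0 * precision[nz] * recall[nz] / denom[nz]
    return ClassMetrics(labels=cm.class_labels, tp=tp, fp=fp, fn=fn, tn=tn,
                        precision=precision, recall=recall, f1=f1)


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (0.0005 -> 0.001 at 3 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def metrics_table(cm: ConfusionMatrix, rounding: int = 3) -> pd.DataFrame:
    """Per-class P/R/F table plus an overall-accuracy summary row."""
    m = per_class_metrics(cm)
    rows = []
    for i, lab in enumerate(cm.class_labels):
        rows.append({
            "class": lab,
            "precision": round_half_up(m.precision[i], rounding),
            "recall": round_half_up(m.recall[i], rounding),
            "f1": round_half_up(m.f1[i], rounding),
            "support": int(cm.counts[i].sum()),
        })
    acc = round_half_up(average_accuracy(cm), rounding)
    rows.append({
        "class": "__accuracy__",
        "precision": np.nan,
        "recall": np.nan,
        "f1": np.nan,
        "support": cm.total,
        "accuracy": acc,
    })
    df = pd.DataFrame(rows)
    df.attrs["average_accuracy"] = acc
    return df


def write_metrics_csv(cm: ConfusionMatrix, path, rounding: int = 3) -> pd.DataFrame:
    df = metrics_table(cm, rounding)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df
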