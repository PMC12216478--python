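"""Confusion-matrix construction and per-class / macro classification metrics.

All metrics derive from a K x K confusion matrix (rows = true class, columns
= predicted class) through one-vs-rest binarization: class ``c`` contributes
TP = cm[c, c], FN = row c minus TP, FP = column c minus TP, TN = the rest.

Per-class definitions::

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F-measure = 2 * precision * recall / (precision + recall)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Note that per-class *accuracy* is the one-vs-rest binarized accuracy, which
with many classes sits near 1 even for a mediocre classifier — this matches
the reporting convention of multiclass dermoscopy benchmarks.  Macro averages
are unweighted arithmetic means over classes.  Any metric whose denominator
is zero is defined as 0 (documented convention).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from math import sqrt

import numpy as np
import pandas as pd

METRIC_NAMES = ("accuracy", "precision", "recall", "f_measure", "mcc")


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix with ``counts[i, j] = #(true == i and pred == j)``."""
    yt = np.asarray(y_true, dtype=np.int64).ravel()
    yp = np.asarray(y_pred, dtype=np.int64).ravel()
    if yt.shape != yp.shape:
        raise ValueError(f"label vectors differ in length: {yt.size} vs {yp.size}")
    if yt.size and (
        yt.min() < 0 or yt.max() >= n_classes or yp.min() < 0 or yp.max() >= n_classes
    ):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (yt, yp), 1)
    return cm


def binarize(cm: np.ndarray, c: int) -> tuple[int, int, int, int]:
    """One-vs-rest reduction of class ``c`` to (TP, TN, FP, FN)."""
    cm = np.asarray(cm)
    if not 0 <= c < cm.shape[0]:
        raise ValueError(f"class index {c} out of range for {cm.shape[0]} classes")
    tp = int(cm[c, c])
    fn = int(cm[c].sum()) - tp
    fp = int(cm[:, c].sum()) - tp
    tn = int(cm.sum()) - tp - fn - fp
    return tp, tn, fp, fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def class_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, precision, recall, F-measure and MCC from binary counts."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix: no samples to evaluate")
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f_measure = _safe_div(2 * precision * recall, precision + recall)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, sqrt(mcc_den)) if mcc_den > 0 else 0.0
    return {
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure,
        "mcc": mcc,
    }


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return _safe_div(2 * precision * recall, precision + recall)


def metric_report(cm: np.ndarray, *, class_names: list[str] | None = None) -> pd.DataFrame:
    """Per-class metric table with an unweighted macro ``Average`` row.

    Values are fractions in [0, 1] (MCC in [-1, 1]) at full precision; use
    :func:`format_report` for the percentage table layout.
    """
    cm = np.asarray(cm)
    k = cm.shape[0]
    names = class_names or [f"C{i + 1}" for i in range(k)]
    rows = [class_metrics(*binarize(cm, c)) for c in range(k)]
    df = pd.DataFrame(rows, index=names)
    df.loc["Average"] = df.mean(axis=0)
    return df


def macro_average(per_class: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean over the per-class rows."""
    arr = np.asarray(per_class, dtype=float)
    if arr.ndim == 1:  # a vector of per-class values for one metric
        arr = arr[:, None]
    if arr.shape[0] < 1:
        raise ValueError("need at least one class row")
    return arr.mean(axis=0)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for printed table output."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Render a fractional report as percentages rounded half-up to 2 d.p."""
    return report.map(lambda v: round_half_up(100.0 * v, 2))


def write_report(report: pd.DataFrame, path, *, fmt: str = "csv") -> None:
    """Persist a report as CSV or JSON mirroring the per-class + Average layout."""
    out = format_report(report)
    if fmt == "csv":
        out.to_csv(path, index_label="class")
    elif fmt == "json":
        out.to_json(path, orient="index", indent=2)
    else:
        raise ValueError(f"unknown report format: {fmt}")
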