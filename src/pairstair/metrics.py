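"""Ordinal and agreement metrics computable from a confusion matrix.

MAE assumes unit spacing between consecutive classes.  Degenerate
denominators (e.g. constant predictions) yield 0 together with a
:class:`DegenerateMetricWarning`, never an exception.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateMetricWarning, PairstairError


@dataclass(frozen=True)
class ConfusionMatrix:
    """p x p count table; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise PairstairError("confusion matrix must be square")
        if (counts < 0).any():
            raise PairstairError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def p(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred, p: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise PairstairError("y_true and y_pred must have equal length")
    if y_true.size and (
        (y_true < 0).any() or (y_true >= p).any()
        or (y_pred < 0).any() or (y_pred >= p).any()
    ):
        raise PairstairError(f"labels must lie in 0..{p - 1}")
    counts = np.zeros((p, p), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def _as_cm(y_true, y_pred, p: Optional[int]) -> ConfusionMatrix:
    if isinstance(y_true, ConfusionMatrix):
        return y_true
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise PairstairError("metrics need at least one sample")
    if p is None:
        p = int(max(y_true.max(), y_pred.max())) + 1
    return confusion(y_true, y_pred, p)


def _degenerate(name: str) -> float:
    warnings.warn(
        f"{name}: degenerate denominator, returning 0",
        DegenerateMetricWarning,
        stacklevel=3,
    )
    return 0.0


def mae(y_true, y_pred=None, p: Optional[int] = None) -> float:
    """Mean absolute class distance (unit spacing)."""
    cm = _as_cm(y_true, y_pred, p)
    i, j = np.indices(cm.counts.shape)
    if cm.total == 0:
        return _degenerate("mae")
    return float((cm.counts * np.abs(i - j)).sum() / cm.total)


def accuracy(y_true, y_pred=None, p: Optional[int] = None) -> float:
    cm = _as_cm(y_true, y_pred, p)
    if cm.total == 0:
        return _degenerate("accuracy")
    return float(np.trace(cm.counts) / cm.total)


def per_class_recall(y_true, y_pred=None, p: Optional[int] = None) -> np.ndarray:
    """Diagonal over row totals; 0 (with warning) for empty classes."""
    cm = _as_cm(y_true, y_pred, p)
    rows = cm.counts.sum(axis=1)
    out = np.zeros(cm.p)
    for c in range(cm.p):
        if rows[c] == 0:
            out[c] = _degenerate(f"recall[{c}]")
        else:
            out[c] = cm.counts[c, c] / rows[c]
    return out


def balanced_accuracy(y_true, y_pred=None, p: Optional[int] = None) -> float:
    """Unweighted mean of per-class recalls."""
    return float(per_class_recall(y_true, y_pred, p).mean())


def macro_f1(y_true, y_pred=None, p: Optional[int] = None) -> float:
    """Unweighted mean of per-class F1 (0 for undefined classes)."""
    cm = _as_cm(y_true, y_pred, p)
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    f1s = np.zeros(cm.p)
    for c in range(cm.p):
        denom = rows[c] + cols[c]
        if denom == 0:
            f1s[c] = _degenerate(f"f1[{c}]")
        else:
            f1s[c] = 2.0 * cm.counts[c, c] / denom
    return float(f1s.mean())


def cohen_kappa(y_true, y_pred=None, p: Optional[int] = None) -> float:
    cm = _as_cm(y_true, y_pred, p)
    n = cm.total
    if n == 0:
        return _degenerate("cohen_kappa")
    po = np.trace(cm.counts) / n
    pe = float((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum()) / (n * n)
    if pe == 1.0:
        return _degenerate("cohen_kappa")
    return float((po - pe) / (1.0 - pe))


def mcc_multiclass(y_true, y_pred=None, p: Optional[int] = None) -> float:
    """Covariance-based multiclass Matthews correlation coefficient."""
    cm = _as_cm(y_true, y_pred, p)
    s = cm.total
    if s == 0:
        return _degenerate("mcc")
    c = int(np.trace(cm.counts))
    t = cm.counts.sum(axis=1).astype(float)  # true-class totals
    q = cm.counts.sum(axis=0).astype(float)  # predicted-class totals
    num = c * s - float((t * q).sum())
    denom = np.sqrt((s * s - float((q * q).sum())) * (s * s - float((t * t).sum())))
    if denom == 0:
        return _degenerate("mcc")
    return float(num / denom)


METRICS = {
    "mae": mae,
    "accuracy": accuracy,
    "balanced_accuracy": balanced_accuracy,
    "macro_f1": macro_f1,
    "cohen_kappa": cohen_kappa,
    "mcc": mcc_multiclass,
}


def metric_report(y_true, y_pred=None, p: Optional[int] = None) -> dict:
    """All metrics plus any degeneracy warnings, as a plain dict."""
    cm = _as_cm(y_true, y_pred, p)
    values = {}
    notes = []
    for name, fn in METRICS.items():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", DegenerateMetricWarning)
            values[name] = fn(cm)
        notes.extend(
            str(w.message) for w in caught
            if issubclass(w.category, DegenerateMetricWarning)
        )
    return {"metrics": values, "warnings": notes, "n": cm.total}


def write_metric_report(report: dict, tsv_path=None, json_path=None):
    if tsv_path is not None:
        with open(tsv_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("metric\tvalue\twarnings\n")
            for name, value in report["metrics"].items():
                related = ";".join(w for w in report["warnings"] if name[:3] in w)
                fh.write(f"{name}\t{value:.6f}\t{related}\n")
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")
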