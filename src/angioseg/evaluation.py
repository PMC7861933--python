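"""Per-class and overall performance metrics from predicted labels.

Multiclass predictions are binarized one-vs-rest: for each class c,
TP counts samples with true = predicted = c, FP those predicted c but
truly another class, FN those truly c predicted otherwise, TN the rest.
From these counts:

    false-positive ratio  FPR = FP / (TN + FP)
    false-negative ratio  FNR = FN / (TP + FN)
    specificity               = TN / (TN + FP)
    precision                 = TP / (TP + FP)
    recall (sensitivity)      = TP / (TP + FN)
    per-class accuracy        = (TP + TN) / n
    overall accuracy          = (number correct) / n  =  Σ_c TP_c / n
    F-measure                 = 2·precision·recall / (precision + recall)

The F-measure is the standard F1 score, the harmonic mean of precision
and recall.  A zero denominator yields 0.0 with a logged warning rather
than NaN, so batch reports never fail.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import ClassLabel

__all__ = [
    "ClassCounts",
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "fpr",
    "fnr",
    "specificity",
    "precision",
    "recall",
    "f_measure",
    "accuracy",
    "overall_accuracy",
    "report",
    "dice_coefficient",
]

logger = logging.getLogger(__name__)

REPORT_NOTES = ("f_measure is the standard F1 score (harmonic mean of "
                "precision and recall); zero-denominator metrics are "
                "reported as 0.0")


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest counts over one evaluated sample set."""

    per_class: dict
    n_samples: int


def _coerce_labels(seq, classes=None):
    labels = [ClassLabel.coerce(l) for l in seq]
    if classes is not None:
        allowed = set(classes)
        for l in labels:
            if l not in allowed:
                raise ValueError(f"label {l.value!r} not in declared classes")
    return labels


def confusion(y_true, y_pred, classes=None) -> ConfusionCounts:
    """One-vs-rest confusion counts for every class present (or declared)."""
    yt = _coerce_labels(y_true, classes)
    yp = _coerce_labels(y_pred, classes)
    if len(yt) != len(yp):
        raise ValueError(
            f"length mismatch: {len(yt)} true vs {len(yp)} predicted labels")
    if not yt:
        raise ValueError("label vectors must be nonempty")
    if classes is None:
        classes = sorted(set(yt) | set(yp), key=lambda l: l.code)
    per_class = {}
    n = len(yt)
    for c in classes:
        tp = sum(1 for t, p in zip(yt, yp) if t is c and p is c)
        fp = sum(1 for t, p in zip(yt, yp) if t is not c and p is c)
        fn = sum(1 for t, p in zip(yt, yp) if t is c and p is not c)
        per_class[c] = ClassCounts(tp=tp, fp=fp, fn=fn, tn=n - tp - fp - fn)
    return ConfusionCounts(per_class=per_class, n_samples=n)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; reporting 0.0", what)
        return 0.0
    return num / den


def fpr(counts: ClassCounts) -> float:
    """False-positive ratio FP / (TN + FP)."""
    return _safe_div(counts.fp, counts.tn + counts.fp, "false-positive ratio")


def fnr(counts: ClassCounts) -> float:
    """False-negative ratio FN / (TP + FN)."""
    return _safe_div(counts.fn, counts.tp + counts.fn, "false-negative ratio")


def specificity(counts: ClassCounts) -> float:
    return _safe_div(counts.tn, counts.tn + counts.fp, "specificity")


def precision(counts: ClassCounts) -> float:
    return _safe_div(counts.tp, counts.tp + counts.fp, "precision")


def recall(counts: ClassCounts) -> float:
    return _safe_div(counts.tp, counts.tp + counts.fn, "recall")


def f_measure(counts: ClassCounts) -> float:
    """F1: harmonic mean of precision and recall (0.0 when both are 0)."""
    p, r = precision(counts), recall(counts)
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def accuracy(counts: ClassCounts) -> float:
    """Per-class accuracy (TP + TN) / n under one-vs-rest binarization."""
    return _safe_div(counts.tp + counts.tn, counts.n, "accuracy")


def overall_accuracy(conf: ConfusionCounts) -> float:
    """Fraction of correct predictions: Σ_c TP_c / n."""
    correct = sum(c.tp for c in conf.per_class.values())
    return _safe_div(correct, conf.n_samples, "overall accuracy")


@dataclass
class MetricsReport:
    """Per-class metric table plus the overall accuracy."""

    per_class: dict
    overall_accuracy: float
    n_samples: int
    notes: str = REPORT_NOTES

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, metrics in self.per_class.items():
            rows.append({"class": name, **metrics})
        rows.append({"class": "overall", "fpr": np.nan, "fnr": np.nan,
                     "f_measure": np.nan, "specificity": np.nan,
                     "precision": np.nan, "recall": np.nan,
                     "accuracy": self.overall_accuracy})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {"notes": self.notes,
                "n_samples": self.n_samples,
                "per_class": self.per_class,
                "overall_accuracy": self.overall_accuracy}


def report(y_true, y_pred, out_dir=None, classes=None) -> MetricsReport:
    """Full metrics report; optionally writes CSV and JSON twins.

    The CSV has one row per class plus an ``overall`` row; the JSON twin
    carries identical values.  Both are written into ``out_dir`` when given.
    """
    conf = confusion(y_true, y_pred, classes=classes)
    per_class = {}
    for c, counts in conf.per_class.items():
        per_class[c.value] = {
            "fpr": fpr(counts),
            "fnr": fnr(counts),
            "f_measure": f_measure(counts),
            "specificity": specificity(counts),
            "precision": precision(counts),
            "recall": recall(counts),
            "accuracy": accuracy(counts),
        }
    rep = MetricsReport(per_class=per_class,
                        overall_accuracy=overall_accuracy(conf),
                        n_samples=conf.n_samples)
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rep.to_dataframe().to_csv(out_dir / "metrics.csv", index=False,
                                  float_format="%.10g")
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(rep.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return rep


def dice_coefficient(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks (1.0 if both empty)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
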