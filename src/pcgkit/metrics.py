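"""Confusion-matrix bookkeeping and the eight screening statistics.

The positive class is "abnormal" throughout: sensitivity is the recall of
abnormal heart sounds, specificity the recall of normal ones. With
P = TP + FN and N = FP + TN:

    sensitivity = TP / P                specificity = TN / N
    fpr         = 1 - specificity       precision   = TP / (TP + FP)
    f_score     = 2 R P' / (R + P')     accuracy    = (TP + TN) / (P + N)
    error       = 1 - accuracy
    mcc         = (TP*TN - FP*FN) / sqrt((TP+FP) * P * N * (TN+FN))

Undefined ratios (zero denominators) are reported as NaN with a warning,
never silently as 0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

POSITIVE_CLASS = "abnormal"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.p + self.n

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp, self.tn + other.tn)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    fpr: float
    precision: float
    f_score: float
    accuracy: float
    error: float
    mcc: float
    per_class_accuracy: dict
    confusion: ConfusionMatrix
    positive_class: str = POSITIVE_CLASS

    def as_dict(self) -> dict:
        d = {
            "positive_class": self.positive_class,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fpr": self.fpr,
            "precision": self.precision,
            "f_score": self.f_score,
            "accuracy": self.accuracy,
            "error": self.error,
            "mcc": self.mcc,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion_matrix": self.confusion.as_dict(),
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), **kwargs)


def confusion_from_labels(y_true, y_pred,
                          positive_class: str = POSITIVE_CLASS) -> ConfusionMatrix:
    """Count TP/FN/FP/TN from parallel label sequences."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty label sequences")
    if len(y_true) != len(y_pred):
        raise ValueError("true and predicted labels differ in length")
    valid = {"normal", "abnormal"}
    bad = (set(y_true) | set(y_pred)) - valid
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    tp = fn = fp = tn = 0
    for yt, yp in zip(y_true, y_pred):
        if yt == positive_class:
            tp += yp == positive_class
            fn += yp != positive_class
        else:
            fp += yp == positive_class
            tn += yp != positive_class
    return ConfusionMatrix(int(tp), int(fn), int(fp), int(tn))


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def compute_metrics(cm: ConfusionMatrix,
                    positive_class: str = POSITIVE_CLASS) -> MetricsReport:
    """Evaluate all eight statistics from one confusion matrix."""
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    p, n = cm.p, cm.n
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    fpr = 1.0 - spec if not math.isnan(spec) else math.nan
    prec = _ratio(tp, tp + fp, "precision")
    if math.isnan(sens) or math.isnan(prec) or (sens + prec) == 0:
        if not (math.isnan(sens) or math.isnan(prec)):
            warnings.warn("f_score undefined (recall + precision = 0); reporting NaN")
        f = math.nan
    else:
        f = 2.0 * sens * prec / (sens + prec)
    acc = _ratio(tp + tn, p + n, "accuracy")
    err = 1.0 - acc if not math.isnan(acc) else math.nan
    denom = (tp + fp) * p * n * (tn + fn)
    if denom == 0:
        warnings.warn("mcc undefined (zero denominator); reporting NaN")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    per_class = {
        positive_class: sens,
        "normal" if positive_class == "abnormal" else "abnormal": spec,
    }
    return MetricsReport(sens, spec, fpr, prec, f, acc, err, mcc,
                         per_class, cm, positive_class)
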