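"""Confusion-matrix bookkeeping and the nine standard evaluation metrics.

Accuracy, precision, sensitivity (recall), specificity, F1, negative
predictive value (NPV), Matthews correlation coefficient (MCC),
false-negative rate and false-positive rate, all from the 2x2 counts.
Metrics with a zero denominator are reported as 0 with an explicit
degenerate flag rather than NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "compute_metrics",
           "ovr_reports"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("at least one counted case required")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    npv: float
    mcc: float
    fnr: float
    fpr: float
    degenerate_flags: tuple = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("accuracy", "precision", "sensitivity", "specificity",
                 "f1", "npv", "mcc", "fnr", "fpr")}


def confusion(labels, predictions, positive_class=1) -> ConfusionCounts:
    """Standard 2x2 counts with the stated positive class."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    pos_l = labels == positive_class
    pos_p = predictions == positive_class
    return ConfusionCounts(
        tp=int(np.count_nonzero(pos_l & pos_p)),
        tn=int(np.count_nonzero(~pos_l & ~pos_p)),
        fp=int(np.count_nonzero(~pos_l & pos_p)),
        fn=int(np.count_nonzero(pos_l & ~pos_p)),
    )


def _ratio(num: float, den: float, name: str, flags: list) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """The nine metric formulas; zero-denominator metrics come back as 0
    with the metric name listed in ``degenerate_flags``."""
    flags: list = []
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    accuracy = (tp + tn) / c.total
    precision = _ratio(tp, tp + fp, "precision", flags)
    sensitivity = _ratio(tp, tp + fn, "sensitivity", flags)
    specificity = _ratio(tn, tn + fp, "specificity", flags)
    npv = _ratio(tn, tn + fn, "npv", flags)
    fnr = _ratio(fn, tp + fn, "fnr", flags)
    fpr = _ratio(fp, tn + fp, "fpr", flags)
    if precision + sensitivity == 0:
        flags.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(accuracy=accuracy, precision=precision,
                         sensitivity=sensitivity, specificity=specificity,
                         f1=f1, npv=npv, mcc=mcc, fnr=fnr, fpr=fpr,
                         degenerate_flags=tuple(flags))


def ovr_reports(labels, predictions) -> dict:
    """One-vs-rest report per class plus the macro average of each metric.

    Binary problems should use :func:`confusion` + :func:`compute_metrics`
    directly; this layout serves multi-class label sets.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    classes = np.unique(labels)
    per_class = {}
    for cls in classes:
        per_class[cls] = compute_metrics(confusion(labels, predictions, cls))
    macro = {k: float(np.mean([r.as_dict()[k] for r in per_class.values()]))
             for k in next(iter(per_class.values())).as_dict()}
    return {"per_class": per_class, "macro": macro}
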