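"""Binary classification metrics on a 2x2 confusion matrix.

The positive class is PD throughout (TP = PD correctly flagged).  Per-class
metrics treat each class as positive in turn, matching the two-column
layout of clinical reports: precision, sensitivity (recall), F1, overall
accuracy, macro and support-weighted averages, Cohen's kappa and error
rate.  Undefined metrics (zero denominators) are reported as NaN rather
than coerced to 0, so macro averages are never silently inflated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix2x2",
    "ClassReport",
    "confusion_from_class_stats",
    "confusion_from_labels",
    "accuracy",
    "precision",
    "sensitivity",
    "f1",
    "cohens_kappa",
    "error_rate",
    "full_report",
]

CONTROL, PD = "control", "pd"


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts with PD as the positive class.

    tp: PD predicted PD; fn: PD predicted control;
    tn: control predicted control; fp: control predicted PD.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def support(self, cls: str) -> int:
        return self.tn + self.fp if cls == CONTROL else self.tp + self.fn

    def predicted(self, cls: str) -> int:
        return self.tn + self.fn if cls == CONTROL else self.tp + self.fp

    def correct(self, cls: str) -> int:
        return self.tn if cls == CONTROL else self.tp


def confusion_from_class_stats(
    support: Sequence[int], sensitivity: Sequence[float]
) -> ConfusionMatrix2x2:
    """Reconstruct the matrix from per-class supports and sensitivities.

    Order is (control, PD).  Correct counts are the nearest integers to
    sensitivity*support; a reconstruction off by more than one count from
    an integer raises, off by up to one warns.
    """
    if len(support) != 2 or len(sensitivity) != 2:
        raise ValueError("need (control, pd) supports and sensitivities")
    correct = []
    for sup, sens in zip(support, sensitivity):
        if not (0.0 <= sens <= 1.0):
            raise ValueError(f"sensitivity {sens} outside [0, 1]")
        if sup <= 0:
            raise ValueError("supports must be positive")
        exact = sens * sup
        c = round(exact)
        if abs(exact - c) > 1.0:
            raise ValueError(f"sensitivity {sens} inconsistent with support {sup}")
        if abs(exact - c) > 0.5:  # unreachable via round, guards manual counts
            warnings.warn("reconstructed count off by up to one", stacklevel=2)
        if c > sup:
            raise ValueError("reconstructed correct count exceeds support")
        correct.append(int(c))
    tn, tp = correct
    return ConfusionMatrix2x2(tp=tp, tn=tn, fp=support[0] - tn, fn=support[1] - tp)


def confusion_from_labels(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix2x2:
    """Counts from label vectors; 1 = PD (positive), 0 = control."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionMatrix2x2(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def accuracy(cm: ConfusionMatrix2x2) -> float:
    return (cm.tp + cm.tn) / cm.total


def error_rate(cm: ConfusionMatrix2x2) -> float:
    return 1.0 - accuracy(cm)


def precision(cm: ConfusionMatrix2x2, cls: str = PD) -> float:
    denom = cm.predicted(cls)
    if denom == 0:
        return math.nan
    return cm.correct(cls) / denom


def sensitivity(cm: ConfusionMatrix2x2, cls: str = PD) -> float:
    denom = cm.support(cls)
    if denom == 0:
        return math.nan
    return cm.correct(cls) / denom


def f1(cm: ConfusionMatrix2x2, cls: str = PD) -> float:
    p = precision(cm, cls)
    s = sensitivity(cm, cls)
    if math.isnan(p) or math.isnan(s) or (p + s) == 0:
        return math.nan
    return 2.0 * p * s / (p + s)


def cohens_kappa(cm: ConfusionMatrix2x2) -> float:
    """Chance-corrected agreement from the row/column marginals."""
    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    p_e = (cm.support(CONTROL) * cm.predicted(CONTROL) + cm.support(PD) * cm.predicted(PD)) / (n * n)
    if p_e == 1.0:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class ClassReport:
    """Per-class and averaged metrics in the two-column table layout."""

    precision: dict[str, float]
    sensitivity: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    accuracy: float
    error_rate: float
    kappa: float
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, vals in (("Precision", self.precision), ("Sensitivity", self.sensitivity), ("F1-measure", self.f1)):
            rows.append(
                {
                    "Metric": name,
                    "Control": vals[CONTROL],
                    "PD": vals[PD],
                    "Accuracy": self.accuracy,
                    "Macro avg.": self.macro_avg[name.lower()],
                    "Weighted avg.": self.weighted_avg[name.lower()],
                }
            )
        rows.append(
            {
                "Metric": "Support",
                "Control": self.support[CONTROL],
                "PD": self.support[PD],
                "Accuracy": "",
                "Macro avg.": "",
                "Weighted avg.": "",
            }
        )
        return pd.DataFrame(rows)


def _avg(vals: dict[str, float], weights: dict[str, float] | None = None) -> float:
    pair = [vals[CONTROL], vals[PD]]
    if any(math.isnan(v) for v in pair):
        return math.nan
    if weights is None:
        return float(np.mean(pair))
    w = np.array([weights[CONTROL], weights[PD]], dtype=float)
    return float(np.average(pair, weights=w))


def full_report(cm: ConfusionMatrix2x2) -> ClassReport:
    prec = {c: precision(cm, c) for c in (CONTROL, PD)}
    sens = {c: sensitivity(cm, c) for c in (CONTROL, PD)}
    f1s = {c: f1(cm, c) for c in (CONTROL, PD)}
    sup = {c: cm.support(c) for c in (CONTROL, PD)}
    w = {c: float(sup[c]) for c in (CONTROL, PD)}
    return ClassReport(
        precision=prec,
        sensitivity=sens,
        f1=f1s,
        support=sup,
        accuracy=accuracy(cm),
        error_rate=error_rate(cm),
        kappa=cohens_kappa(cm),
        macro_avg={
            "precision": _avg(prec),
            "sensitivity": _avg(sens),
            "f1-measure": _avg(f1s),
        },
        weighted_avg={
            "precision": _avg(prec, w),
            "sensitivity": _avg(sens, w),
            "f1-measure": _avg(f1s, w),
        },
    )


def write_report(report: ClassReport, path) -> None:
    """Tab-separated table matching the (Metric, Control, PD, ...) column order."""
    report.to_frame().to_csv(path, sep="\t", index=False)
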