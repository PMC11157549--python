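"""Reconstruction checks against the published benchmark tables.

Each check rebuilds the best-model 2x2 confusion matrix of a study split
from its class supports and per-class sensitivities alone, recomputes
every derived metric with :mod:`gaitopt.metrics`, and compares with the
published value at an absolute tolerance of 1e-6 (printed precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import metrics
from .framework import XGB_RANGES
from .reference import BENCHMARKS, HYPERPARAM_SELECTIONS, SplitBenchmark

__all__ = ["TargetResult", "reconstruct_split_metrics", "validate_tables", "validate_hyperparam_ranges"]

TOL = 1e-6


@dataclass(frozen=True)
class TargetResult:
    target: str
    computed: float
    expected: float

    @property
    def delta(self) -> float:
        return self.computed - self.expected

    @property
    def ok(self) -> bool:
        return abs(self.delta) <= TOL


def reconstruct_split_metrics(bench: SplitBenchmark) -> dict[str, float]:
    """All derived metrics, computed only from supports and sensitivities."""
    cm = metrics.confusion_from_class_stats(bench.support, bench.sensitivity)
    rep = metrics.full_report(cm)
    return {
        "control_precision": rep.precision[metrics.CONTROL],
        "pd_precision": rep.precision[metrics.PD],
        "control_sensitivity": rep.sensitivity[metrics.CONTROL],
        "pd_sensitivity": rep.sensitivity[metrics.PD],
        "control_f1": rep.f1[metrics.CONTROL],
        "pd_f1": rep.f1[metrics.PD],
        "accuracy": rep.accuracy,
        "macro_precision": rep.macro_avg["precision"],
        "weighted_precision": rep.weighted_avg["precision"],
        "macro_sensitivity": rep.macro_avg["sensitivity"],
        "weighted_sensitivity": rep.weighted_avg["sensitivity"],
        "macro_f1": rep.macro_avg["f1-measure"],
        "weighted_f1": rep.weighted_avg["f1-measure"],
        "kappa": rep.kappa,
        "error_rate": rep.error_rate,
    }


def validate_tables() -> list[TargetResult]:
    """Recompute every published best-model metric for the three splits."""
    results = []
    for key, bench in BENCHMARKS.items():
        computed = reconstruct_split_metrics(bench)
        expected = {
            "control_precision": bench.precision[0],
            "pd_precision": bench.precision[1],
            "control_sensitivity": bench.sensitivity[0],
            "pd_sensitivity": bench.sensitivity[1],
            "control_f1": bench.f1[0],
            "pd_f1": bench.f1[1],
            "accuracy": bench.accuracy,
            "macro_precision": bench.macro_precision,
            "weighted_precision": bench.weighted_precision,
            "macro_sensitivity": bench.macro_sensitivity,
            "weighted_sensitivity": bench.weighted_sensitivity,
            "macro_f1": bench.macro_f1,
            "weighted_f1": bench.weighted_f1,
            "kappa": bench.kappa,
            "error_rate": bench.error_rate,
        }
        for metric, exp in expected.items():
            results.append(TargetResult(f"{key}_{metric}", computed[metric], exp))
    return results


def validate_hyperparam_ranges() -> list[str]:
    """Bound check for every published realized hyperparameter selection.

    Returns the names of out-of-range entries (empty = all pass).  Bounds
    only are checked: some published depth values are fractional, so
    integrality is not asserted.
    """
    names = ["learning_rate", "min_child_weight", "subsample", "colsample_by_tree", "max_depth", "gamma"]
    bad = []
    for split, table in HYPERPARAM_SELECTIONS.items():
        for algo, values in table.items():
            for name, value in zip(names, values):
                lo, hi = XGB_RANGES[name][:2]
                if not (lo - 1e-12 <= value <= hi + 1e-12) or not math.isfinite(value):
                    bad.append(f"{split}/{algo}/{name}={value}")
    return bad
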