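"""Nonparametric outcome validation across optimizer result samples.

Per (algorithm, problem) sample of per-run best objective values:
Shapiro-Wilk screens normality (alpha 0.05); when normality fails, the
control method is compared against each competitor with a one-sided
Wilcoxon signed-rank test (alternative: control's objective is lower),
at alpha 0.1.  Zero paired differences are dropped before ranking and
ties are mid-ranked (the classical Wilcoxon convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ResultSample", "normality_screen", "control_comparison"]


@dataclass(frozen=True)
class ResultSample:
    algorithm: str
    problem: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size < 3:
            raise ValueError("need at least 3 values per sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("sample values must be finite")


def normality_screen(samples: list[ResultSample], alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk p-value per sample; reject normality when p < alpha.

    Constant samples have no defined test statistic and are reported with
    a NaN p-value and a null reject flag.
    """
    rows = []
    for s in samples:
        if np.ptp(s.values) == 0:
            warnings.warn(f"constant sample for {s.algorithm}/{s.problem}; normality undefined")
            p = math.nan
            reject = pd.NA
        else:
            p = float(sps.shapiro(s.values).pvalue)
            reject = p < alpha
        rows.append({"algorithm": s.algorithm, "problem": s.problem, "p_value": p, "reject_normality": reject})
    return pd.DataFrame(rows)


def control_comparison(
    control: ResultSample, others: list[ResultSample], alpha: float = 0.1
) -> pd.DataFrame:
    """One-sided Wilcoxon signed-rank: is the control's objective lower?

    Samples are paired by run; all-zero difference vectors (identical
    samples) yield p = 1 (no evidence of a difference).
    """
    rows = []
    for other in others:
        if other.values.size != control.values.size:
            raise ValueError(
                f"cannot pair {control.algorithm} (n={control.values.size}) "
                f"with {other.algorithm} (n={other.values.size})"
            )
        diffs = control.values - other.values
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(
                sps.wilcoxon(
                    control.values, other.values, alternative="less", zero_method="wilcox"
                ).pvalue
            )
        rows.append(
            {
                "algorithm": other.algorithm,
                "problem": other.problem,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
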