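"""Separate one-way ANOVA of treatment at a single time point.

This is analysis approach (iii): each time point is analyzed in isolation
with a classical fixed-effects one-way ANOVA using only that time point's
observations, ignoring the repeated-measures correlation entirely.  It is a
marginally valid test (each time point's data are i.i.d. normal within arm)
but borrows no strength across time points.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .gls import TestResult


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA at a single time point.

    ``pairwise_sem = sqrt(2 * MSE / n)`` is the standard error of a pairwise
    difference of arm means under the pooled error variance.
    """

    time_index: int
    test: TestResult
    mse: float
    pairwise_sem: float


def oneway_f(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way ANOVA from per-arm response vectors (balanced)."""
    G = len(groups)
    if G < 2:
        raise ValueError("need at least 2 arms")
    ns = [len(g) for g in groups]
    if min(ns) < 2:
        raise ValueError("each arm needs at least 2 observations")
    if len(set(ns)) != 1:
        raise ValueError("balanced design required (equal n per arm)")
    n = ns[0]
    means = np.array([np.mean(g) for g in groups])
    grand = float(np.mean(means))
    ssb = n * float(np.sum((means - grand) ** 2))
    sse = float(sum(np.sum((np.asarray(g) - m) ** 2) for g, m in zip(groups, means)))
    df_num = G - 1
    df_den = G * (n - 1)
    mse = sse / df_den
    if mse <= 0:
        raise ValueError("degenerate data: zero within-arm variability")
    F = (ssb / df_num) / mse
    p = float(stats.f.sf(F, df_num, df_den))
    return AnovaResult(
        time_index=-1,
        test=TestResult(statistic=F, df_num=df_num, df_den=float(df_den), p_value=p),
        mse=mse,
        pairwise_sem=float(np.sqrt(2.0 * mse / n)),
    )


def anova_at_time(data: pd.DataFrame, time_index: int) -> AnovaResult:
    """One-way treatment ANOVA using only the rows at one time point.

    ``time_index`` is the 0-based position of the week in the sorted unique
    weeks present in ``data``; rows at other weeks cannot influence the
    result.
    """
    weeks = sorted(data["week"].unique())
    if not 0 <= time_index < len(weeks):
        raise IndexError(f"time_index {time_index} out of range [0, {len(weeks)})")
    sub = data[data["week"] == weeks[time_index]]
    arms = sorted(sub["treatment"].unique())
    groups = [sub.loc[sub["treatment"] == a, "response"].to_numpy(dtype=float) for a in arms]
    res = oneway_f(groups)
    return dataclasses.replace(res, time_index=time_index)
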