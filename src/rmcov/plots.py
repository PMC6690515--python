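"""Histogram grids of p-values and SEM draws across methods and time points.

Mirrors the study's diagnostic displays: one row per analysis method, one
column per test (overall tests then per-time-point contrasts), proportions
per 0.05-wide bin for p-values and per data-driven bin for SEMs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import RejectionSummary, pvalue_histogram, summarize_sems


def _grid(summaries: list[RejectionSummary]):
    methods = list(dict.fromkeys(s.method for s in summaries))
    tests = list(dict.fromkeys(s.test_id for s in summaries))
    return methods, tests


def pvalue_grid(summaries: list[RejectionSummary], path) -> None:
    """Save a method x test grid of p-value histograms."""
    methods, tests = _grid(summaries)
    by_key = {(s.method, s.test_id): s for s in summaries}
    fig, axes = plt.subplots(
        len(methods), len(tests), figsize=(2.2 * len(tests), 2.0 * len(methods)),
        squeeze=False, sharex=True,
    )
    for i, m in enumerate(methods):
        for j, t in enumerate(tests):
            ax = axes[i][j]
            s = by_key.get((m, t))
            if s is None or len(s.p_values) == 0:
                ax.axis("off")
                continue
            h = pvalue_histogram(s.p_values)
            ax.bar(h.bin_edges[:-1], h.proportions, width=0.05, align="edge")
            ax.axhline(0.05, color="grey", lw=0.5, ls="--")
            if i == 0:
                ax.set_title(t, fontsize=8)
            if j == 0:
                ax.set_ylabel(m, fontsize=8)
    fig.suptitle(summaries[0].scenario.label, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def sem_grid(summaries: list[RejectionSummary], path) -> None:
    """Save a method x time-point grid of pairwise-SEM histograms."""
    with_sems = [s for s in summaries if s.sem_draws is not None and len(s.sem_draws)]
    if not with_sems:
        raise ValueError("no SEM draws to plot")
    methods, tests = _grid(with_sems)
    by_key = {(s.method, s.test_id): s for s in with_sems}
    lo = min(float(np.min(s.sem_draws)) for s in with_sems)
    hi = max(float(np.max(s.sem_draws)) for s in with_sems)
    fig, axes = plt.subplots(
        len(methods), len(tests), figsize=(2.2 * len(tests), 2.0 * len(methods)),
        squeeze=False, sharex=True,
    )
    for i, m in enumerate(methods):
        for j, t in enumerate(tests):
            ax = axes[i][j]
            s = by_key.get((m, t))
            if s is None:
                ax.axis("off")
                continue
            summ = summarize_sems(s.sem_draws)
            width = summ.bin_edges[1] - summ.bin_edges[0]
            ax.bar(summ.bin_edges[:-1], summ.proportions, width=width, align="edge")
            ax.set_xlim(lo, hi)
            if i == 0:
                ax.set_title(t, fontsize=8)
            if j == 0:
                ax.set_ylabel(m, fontsize=8)
    fig.suptitle(f"{with_sems[0].scenario.label} pairwise SEM", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
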