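"""Scenario-level Monte-Carlo loop and its summaries.

For one scenario the loop simulates ``n_reps`` balanced replicates and
analyzes *each* replicate three ways on the same data (common random
numbers):

- ``rma_correct``      — REML fit with the generating structure's own kind;
- ``rma_homogeneous``  — REML fit with the equal-variance (homogeneous)
  counterpart, the canonical misspecification;
- ``separate_anova``   — independent one-way ANOVA at each time point.

Collected per method and test are the replicate p-values (overall treatment,
time, interaction for the RMA methods; the joint per-time-point treatment
contrast for all methods) and, per time point, the pairwise SEM draws.
Rejection rates use strict ``p < alpha``.  Replicates whose REML fit fails
to converge are excluded from that method's denominator; a warning fires if
exclusions exceed 1% in any method.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats as sstats

from .anova import oneway_f
from .covariance import HOMOGENEOUS_COUNTERPART
from .gls import RepeatedMeasuresGLS, SufficientStats, TestResult
from .params import ParameterTable, ScenarioConfig
from .simulate import simulate_arrays

METHODS: tuple[str, ...] = ("rma_correct", "rma_homogeneous", "separate_anova")
OVERALL_TEST_IDS: tuple[str, ...] = ("treatment", "time", "interaction")


def week_test_ids(params: ParameterTable) -> tuple[str, ...]:
    return tuple(f"week{w}" for w in params.weeks)


@dataclasses.dataclass(frozen=True)
class RejectionSummary:
    """Replicate-level p-values and SEM draws for one method x test."""

    scenario: ScenarioConfig
    method: str
    test_id: str
    p_values: np.ndarray
    sem_draws: np.ndarray | None
    n_converged: int
    rejection_rate: float


@dataclasses.dataclass(frozen=True)
class PValueHistogram:
    """20-bin histogram of p-values on [0, 1] (bin width 0.05, proportions)."""

    bin_edges: np.ndarray
    proportions: np.ndarray


@dataclasses.dataclass(frozen=True)
class SemSummary:
    """Descriptive summary of SEM draws plus a 20-bin histogram."""

    mean: float
    sd: float
    bin_edges: np.ndarray
    proportions: np.ndarray


def proportion_below(p_values: np.ndarray, alpha: float) -> float:
    """Strict-inequality rejection proportion: #{p < alpha} / #p."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(np.mean(p < alpha))


def uniformity_check(p_values: np.ndarray) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against Uniform(0, 1).

    A correctly calibrated test's null p-values should pass (KS p not
    small).  ``df_num``/``df_den`` carry 1 and the sample size, as the KS
    statistic has no F-type degrees of freedom.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a uniformity check")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    res = sstats.kstest(p, "uniform")
    return TestResult(
        statistic=float(res.statistic),
        df_num=1,
        df_den=float(p.size),
        p_value=float(res.pvalue),
    )


def pvalue_histogram(p_values: np.ndarray) -> PValueHistogram:
    """Histogram of p-values in 20 bins of width 0.05; the first bin's
    proportion is the rejection rate at alpha = 0.05 (strict, up to ties
    exactly at 0.05, which have probability zero for continuous tests)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    edges = np.linspace(0.0, 1.0, 21)
    counts, _ = np.histogram(p, bins=edges)
    return PValueHistogram(bin_edges=edges, proportions=counts / p.size)


def summarize_sems(sem_draws: np.ndarray) -> SemSummary:
    """Mean, SD and a 20-bin histogram of SEM draws (data-driven range)."""
    s = np.asarray(sem_draws, dtype=float)
    if s.size == 0:
        raise ValueError("empty SEM vector")
    if np.any(s <= 0):
        raise ValueError("SEM draws must be positive")
    lo, hi = float(s.min()), float(s.max())
    if hi <= lo:
        hi = lo + max(1e-12, abs(lo) * 1e-12)
    edges = np.linspace(lo, hi, 21)
    counts, _ = np.histogram(s, bins=edges)
    return SemSummary(
        mean=float(s.mean()),
        sd=float(s.std(ddof=1)) if s.size > 1 else 0.0,
        bin_edges=edges,
        proportions=counts / s.size,
    )


def _stats_from_arrays(
    values: np.ndarray, params: ParameterTable
) -> SufficientStats:
    """SufficientStats straight from the (G, n, T) simulation array."""
    G, n, T = values.shape
    group_means = values.mean(axis=1)
    S = np.zeros((T, T))
    for g in range(G):
        R = values[g] - group_means[g]
        S += R.T @ R
    return SufficientStats(
        arms=params.arms,
        weeks=params.weeks,
        n_per_arm=np.full(G, n),
        group_means=group_means,
        S=S,
        n_subjects=G * n,
    )


def run_scenario(
    params: ParameterTable,
    scenario: ScenarioConfig,
    ddf: str = "satterthwaite",
    methods: tuple[str, ...] = METHODS,
    progress: bool = False,
) -> list[RejectionSummary]:
    """Run the full simulate-and-analyze loop for one scenario.

    Returns one :class:`RejectionSummary` per (method, test) combination;
    the per-time-point tests carry the SEM draws alongside the p-values.
    Fully reproducible from ``scenario.base_seed``.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    T = len(params.weeks)
    wk_ids = week_test_ids(params)
    correct_kind = scenario.truth_structure
    hom_kind = HOMOGENEOUS_COUNTERPART[correct_kind]
    gls_methods = [m for m in methods if m.startswith("rma_")]
    kind_of = {"rma_correct": correct_kind, "rma_homogeneous": hom_kind}

    pvals: dict[tuple[str, str], list[float]] = {}
    sems: dict[tuple[str, str], list[float]] = {}
    converged_count = {m: 0 for m in methods}

    iterator = range(scenario.n_reps)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc=scenario.label)
        except ImportError:
            pass

    for rep in iterator:
        values = simulate_arrays(params, scenario, rep)
        ss = _stats_from_arrays(values, params)
        for m in gls_methods:
            fit = RepeatedMeasuresGLS(structure=kind_of[m], ddf=ddf).fit(ss)
            if not fit.converged_:
                continue
            converged_count[m] += 1
            for tid, res in fit.wald_tests().items():
                pvals.setdefault((m, tid), []).append(res.p_value)
            for t in range(T):
                con = fit.contrast_at_time(t)
                pvals.setdefault((m, wk_ids[t]), []).append(con.joint_test.p_value)
                sems.setdefault((m, wk_ids[t]), []).append(
                    next(iter(con.pairwise_sem.values()))
                )
        if "separate_anova" in methods:
            converged_count["separate_anova"] += 1
            for t in range(T):
                res = oneway_f(list(values[:, :, t]))
                pvals.setdefault(("separate_anova", wk_ids[t]), []).append(
                    res.test.p_value
                )
                sems.setdefault(("separate_anova", wk_ids[t]), []).append(
                    res.pairwise_sem
                )

    summaries = []
    for m in methods:
        n_conv = converged_count[m]
        excluded = scenario.n_reps - n_conv
        if excluded > 0.01 * scenario.n_reps:
            warnings.warn(
                f"{scenario.label}/{m}: {excluded} of {scenario.n_reps} replicates "
                "excluded for non-convergence (> 1%)",
                RuntimeWarning,
            )
        test_ids = (
            wk_ids if m == "separate_anova" else OVERALL_TEST_IDS + wk_ids
        )
        for tid in test_ids:
            p = np.asarray(pvals.get((m, tid), []), dtype=float)
            s = sems.get((m, tid))
            summaries.append(
                RejectionSummary(
                    scenario=scenario,
                    method=m,
                    test_id=tid,
                    p_values=p,
                    sem_draws=None if s is None else np.asarray(s, dtype=float),
                    n_converged=n_conv,
                    rejection_rate=proportion_below(p, scenario.alpha),
                )
            )
    return summaries


def summaries_frame(summaries: list[RejectionSummary]):
    """Tidy one-row-per-summary table (for the results CSV)."""
    import pandas as pd

    rows = []
    for s in summaries:
        sc = s.scenario
        rows.append(
            dict(
                scenario_id=sc.label,
                truth_structure=sc.truth_structure,
                hypothesis=sc.hypothesis,
                n=sc.n_per_group,
                rho=sc.rho,
                method=s.method,
                test_id=s.test_id,
                n_converged=s.n_converged,
                rejection_rate=s.rejection_rate,
                mean_sem=float(np.mean(s.sem_draws)) if s.sem_draws is not None else np.nan,
                sd_sem=float(np.std(s.sem_draws, ddof=1))
                if s.sem_draws is not None and len(s.sem_draws) > 1
                else np.nan,
            )
        )
    return pd.DataFrame(rows)
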