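"""Simulation parameters and the scenario grid.

The study design is a 3-arm dietary intervention in growing mice (arms
``HFol-HFol``, ``HFol-RV``, ``RV-RV``) with body weight (grams) measured at
weeks 1, 7, 14, 21 and 28.  Generating means, SEMs and SDs for every
treatment-by-time cell are compiled into the package as a CSV fixture and
loaded into a :class:`ParameterTable`.

Under the *null* hypothesis all arms share a common mean trajectory
(160, 480, 630, 724, 800 g); under the *alternative* each arm keeps its own
extracted mean trajectory.  Per-cell SDs are the same in both hypotheses and
were derived from the source SEMs as ``SD = SEM * sqrt(12)`` (the donor
study's group size), so variances increase markedly over time.

The full factorial of study conditions is 2 generating covariance structures
x 3 group sizes (n = 3, 6, 12) x 4 within-subject correlations
(rho = 0.1, 0.3, 0.6, 0.9) x 2 hypotheses = 48 scenarios, each replicated
1000 times by default.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd

ARM_LABELS: tuple[str, ...] = ("HFol-HFol", "HFol-RV", "RV-RV")
WEEKS: tuple[int, ...] = (1, 7, 14, 21, 28)
N_ARMS = len(ARM_LABELS)
N_TIMES = len(WEEKS)

TRUTH_STRUCTURES: tuple[str, ...] = ("het_cs", "het_ar1")
SAMPLE_SIZES: tuple[int, ...] = (3, 6, 12)
RHO_VALUES: tuple[float, ...] = (0.1, 0.3, 0.6, 0.9)
HYPOTHESES: tuple[str, ...] = ("null", "alternative")

#: group size of the donor study, fixed for the SEM->SD conversion
#: regardless of the simulated n_per_group
SD_CONVERSION_N = 12


def sem_to_sd(sem: float, n: int) -> float:
    """Convert a standard error of the mean to a standard deviation.

    ``SD = SEM * sqrt(n)`` with ``n`` the group size behind the SEM.
    """
    if sem < 0:
        raise ValueError(f"sem must be non-negative, got {sem}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return float(sem) * float(np.sqrt(n))


@dataclasses.dataclass(frozen=True)
class ParameterTable:
    """Generating parameters per treatment arm x time point (grams).

    Arrays are shaped ``(n_arms, n_times)`` with rows ordered as
    :data:`ARM_LABELS` and columns as :data:`WEEKS`.
    """

    null_mean: np.ndarray
    alt_mean: np.ndarray
    sem: np.ndarray
    sd: np.ndarray
    arms: tuple[str, ...] = ARM_LABELS
    weeks: tuple[int, ...] = WEEKS

    def __post_init__(self) -> None:
        shape = (len(self.arms), len(self.weeks))
        for name in ("null_mean", "alt_mean", "sem", "sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            object.__setattr__(self, name, arr)
        if np.any(self.sd <= 0):
            raise ValueError("all SDs must be positive")
        if not np.allclose(self.null_mean, self.null_mean[0], atol=0.0):
            raise ValueError("null means must be shared across arms at each time")

    def arm_index(self, label: str) -> int:
        return self.arms.index(label)

    def week_index(self, week: int) -> int:
        return self.weeks.index(week)

    def means(self, hypothesis: str) -> np.ndarray:
        """Generating mean matrix for a hypothesis ('null' or 'alternative')."""
        if hypothesis == "null":
            return self.null_mean
        if hypothesis == "alternative":
            return self.alt_mean
        raise ValueError(f"unknown hypothesis {hypothesis!r}")

    def arm_sds(self, arm: int | str) -> np.ndarray:
        """Per-time SD vector for one arm (length n_times)."""
        idx = self.arm_index(arm) if isinstance(arm, str) else int(arm)
        return self.sd[idx]

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-cell view (columns as in the CSV fixture)."""
        rows = []
        for t, week in enumerate(self.weeks):
            for g, arm in enumerate(self.arms):
                rows.append(
                    dict(
                        treatment=arm,
                        week=week,
                        mean_null=self.null_mean[g, t],
                        mean_alt=self.alt_mean[g, t],
                        sem=self.sem[g, t],
                        sd=self.sd[g, t],
                    )
                )
        return pd.DataFrame(rows)


def load_table1() -> ParameterTable:
    """Load the compiled generating-parameter table (means, SEMs, SDs)."""
    with resources.files("rmcov.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh)
    null_mean = np.empty((N_ARMS, N_TIMES))
    alt_mean = np.empty((N_ARMS, N_TIMES))
    sem = np.empty((N_ARMS, N_TIMES))
    sd = np.empty((N_ARMS, N_TIMES))
    for _, row in df.iterrows():
        g = ARM_LABELS.index(row["treatment"])
        t = WEEKS.index(int(row["week"]))
        null_mean[g, t] = row["mean_null"]
        alt_mean[g, t] = row["mean_alt"]
        sem[g, t] = row["sem"]
        sd[g, t] = row["sd"]
    return ParameterTable(null_mean=null_mean, alt_mean=alt_mean, sem=sem, sd=sd)


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation factorial.

    Parameters
    ----------
    truth_structure : {'het_cs', 'het_ar1'}
        Generating within-subject covariance structure.
    n_per_group : int
        Subjects per treatment arm.
    rho : float
        Within-subject correlation parameter of the generating structure.
    hypothesis : {'null', 'alternative'}
        Which mean matrix generates the data.
    n_reps : int
        Monte-Carlo replicates.
    base_seed : int
        Root seed; every replicate's stream is derived from it.
    alpha : float
        Rejection level for type I error / power summaries.
    """

    truth_structure: str
    n_per_group: int
    rho: float
    hypothesis: str
    n_reps: int = 1000
    base_seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.truth_structure not in TRUTH_STRUCTURES:
            raise ValueError(f"unknown truth_structure {self.truth_structure!r}")
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def label(self) -> str:
        return (
            f"{self.truth_structure}_{self.hypothesis}"
            f"_n{self.n_per_group}_rho{self.rho:g}"
        )

    def coordinates(self) -> tuple[int, int, int, int]:
        """Integer coordinates identifying the scenario (for seed derivation)."""
        return (
            TRUTH_STRUCTURES.index(self.truth_structure),
            HYPOTHESES.index(self.hypothesis),
            int(self.n_per_group),
            int(round(self.rho * 1_000_000)),
        )


def scenario_grid(n_reps: int = 1000, base_seed: int = 0) -> list[ScenarioConfig]:
    """Enumerate the full 2 x 3 x 4 x 2 factorial of 48 scenarios.

    Order is deterministic (structure, hypothesis, n, rho nested loops) and
    each scenario receives its own derived base seed, so scenarios draw from
    disjoint random streams no matter which subset is run.
    """
    grid: list[ScenarioConfig] = []
    i = 0
    for structure in TRUTH_STRUCTURES:
        for hypothesis in HYPOTHESES:
            for n in SAMPLE_SIZES:
                for rho in RHO_VALUES:
                    derived = int(
                        np.random.SeedSequence(base_seed, spawn_key=(i,)).generate_state(1)[0]
                    )
                    grid.append(
                        ScenarioConfig(
                            truth_structure=structure,
                            n_per_group=n,
                            rho=rho,
                            hypothesis=hypothesis,
                            n_reps=n_reps,
                            base_seed=derived,
                        )
                    )
                    i += 1
    return grid
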