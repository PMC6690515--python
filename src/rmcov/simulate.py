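"""Balanced multivariate-normal repeated-measures data generator.

Each replicate draws, for every treatment arm, ``n_per_group`` independent
T-vectors from a multivariate normal whose mean is that arm's generating
trajectory (null or alternative) and whose covariance is built from the arm's
own per-time SDs with the scenario's structure and rho.  Groups therefore
share means under the null but always keep group-specific covariance scale.

Reproducibility is counter-mode: every replicate gets its own integer seed
derived from ``(base_seed, scenario coordinates, rep_index)`` through
``numpy.random.SeedSequence``, so any single replicate can be regenerated in
isolation, in any order, on any platform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariance import CovarianceSpec, build_covariance
from .params import ParameterTable, ScenarioConfig

DATASET_COLUMNS = ("subject", "treatment", "week", "response")


def rep_seed(base_seed: int, scenario: ScenarioConfig, rep_index: int) -> int:
    """Derive the integer seed for one replicate of one scenario.

    The spawn key is the scenario's integer coordinates plus the replicate
    counter; the returned value is the 128-bit state that SeedSequence
    generates for that key, collision-free for all practical purposes and
    stable across platforms and program invocations.
    """
    if rep_index < 0:
        raise ValueError("rep_index must be non-negative")
    key = scenario.coordinates() + (int(rep_index),)
    state = np.random.SeedSequence(int(base_seed), spawn_key=key).generate_state(
        4, dtype=np.uint32
    )
    out = 0
    for word in state:
        out = (out << 32) | int(word)
    return out


def group_covariances(params: ParameterTable, scenario: ScenarioConfig) -> list[np.ndarray]:
    """Generating T x T covariance for each arm (arm SDs, scenario structure/rho)."""
    T = len(params.weeks)
    covs = []
    for g in range(len(params.arms)):
        spec = CovarianceSpec(
            kind=scenario.truth_structure, sigmas=params.arm_sds(g), rho=scenario.rho
        )
        covs.append(build_covariance(spec, T))
    return covs


def simulate_arrays(
    params: ParameterTable, scenario: ScenarioConfig, rep_index: int
) -> np.ndarray:
    """Draw one replicate as a ``(n_arms, n_per_group, n_times)`` array."""
    if rep_index >= scenario.n_reps:
        raise ValueError(
            f"rep_index {rep_index} out of range for n_reps={scenario.n_reps}"
        )
    rng = np.random.default_rng(rep_seed(scenario.base_seed, scenario, rep_index))
    means = params.means(scenario.hypothesis)
    covs = group_covariances(params, scenario)
    n, T = scenario.n_per_group, len(params.weeks)
    out = np.empty((len(params.arms), n, T))
    for g, cov in enumerate(covs):
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((n, T))
        out[g] = means[g] + z @ chol.T
    return out


def simulate_dataset(
    params: ParameterTable, scenario: ScenarioConfig, rep_index: int
) -> pd.DataFrame:
    """Simulate one balanced long-format replicate.

    Returns a DataFrame with columns ``subject, treatment, week, response``;
    3 arms x n_per_group subjects x 5 weeks rows.  A pure function of
    ``(scenario.base_seed, scenario coordinates, rep_index)``.
    """
    values = simulate_arrays(params, scenario, rep_index)
    G, n, T = values.shape
    rows = {
        "subject": np.repeat(
            [f"g{g}_s{j}" for g in range(G) for j in range(n)], T
        ),
        "treatment": np.repeat([params.arms[g] for g in range(G)], n * T),
        "week": np.tile(np.asarray(params.weeks), G * n),
        "response": values.reshape(-1),
    }
    return pd.DataFrame(rows)


def write_dataset(data: pd.DataFrame, path) -> None:
    """Write a long-format dataset to CSV at full float precision."""
    _validate_columns(data)
    data.to_csv(path, index=False, columns=list(DATASET_COLUMNS))


def read_dataset(path) -> pd.DataFrame:
    """Read a long-format dataset CSV (round-trips :func:`write_dataset`)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _validate_columns(df)
    return df


def _validate_columns(df: pd.DataFrame) -> None:
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
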