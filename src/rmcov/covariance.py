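"""Residual covariance structures for balanced repeated measures.

Four structured forms plus an unstructured escape hatch:

- ``het_cs``  — heterogeneous compound symmetry: per-time SDs sigma_1..sigma_T,
  constant pairwise correlation rho; entry (i, j) = sigma_i * sigma_j * rho.
- ``het_ar1`` — heterogeneous first-order autoregressive: per-time SDs,
  correlation decaying as rho**|j - i| with the *index* distance (time points
  need not be equally spaced in calendar units; lag is positional).
- ``hom_cs`` / ``hom_ar1`` — homogeneous analogues with a single common
  variance sigma2 on the diagonal.
- ``unstructured`` — an explicit symmetric positive-definite matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np

KINDS: tuple[str, ...] = ("het_cs", "het_ar1", "hom_cs", "hom_ar1", "unstructured")
STRUCTURED_KINDS: tuple[str, ...] = KINDS[:4]

#: misspecified (equal-variance) counterpart fitted to each generating structure
HOMOGENEOUS_COUNTERPART: dict[str, str] = {"het_cs": "hom_cs", "het_ar1": "hom_ar1"}


def is_cs(kind: str) -> bool:
    return kind.endswith("_cs")


def is_heterogeneous(kind: str) -> bool:
    return kind.startswith("het_")


def rho_lower_bound(kind: str, T: int) -> float:
    """Lower edge of the positive-definite rho range for a structured kind."""
    return -1.0 / (T - 1) if is_cs(kind) else -1.0


@dataclasses.dataclass(frozen=True)
class CovarianceSpec:
    """A covariance structure kind plus its parameter values.

    Heterogeneous kinds carry ``sigmas`` (length-T positive SD vector);
    homogeneous kinds carry a single ``sigma2`` (positive variance); both carry
    ``rho``.  ``unstructured`` carries ``free_matrix`` only.
    """

    kind: str
    sigmas: np.ndarray | None = None
    sigma2: float | None = None
    rho: float | None = None
    free_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown covariance kind {self.kind!r}")
        if self.sigmas is not None:
            object.__setattr__(self, "sigmas", np.asarray(self.sigmas, dtype=float))
        if self.free_matrix is not None:
            object.__setattr__(self, "free_matrix", np.asarray(self.free_matrix, dtype=float))
        if self.kind == "unstructured":
            if self.free_matrix is None:
                raise ValueError("unstructured spec requires free_matrix")
            if self.sigmas is not None or self.sigma2 is not None or self.rho is not None:
                raise ValueError("unstructured spec carries only free_matrix")
            return
        if self.rho is None:
            raise ValueError(f"{self.kind} spec requires rho")
        if is_heterogeneous(self.kind):
            if self.sigmas is None or self.sigma2 is not None:
                raise ValueError(f"{self.kind} spec requires sigmas and no sigma2")
            if np.any(self.sigmas <= 0):
                raise ValueError("all sigmas must be positive")
        else:
            if self.sigma2 is None or self.sigmas is not None:
                raise ValueError(f"{self.kind} spec requires sigma2 and no sigmas")
            if self.sigma2 <= 0:
                raise ValueError("sigma2 must be positive")

    @property
    def n_times(self) -> int | None:
        if self.sigmas is not None:
            return len(self.sigmas)
        if self.free_matrix is not None:
            return self.free_matrix.shape[0]
        return None


def _correlation_matrix(kind: str, rho: float, T: int) -> np.ndarray:
    if is_cs(kind):
        corr = np.full((T, T), rho)
    else:
        lag = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        corr = rho ** lag
    np.fill_diagonal(corr, 1.0)
    return corr


def build_covariance(
    spec: CovarianceSpec, T: int, *, rho_range: str = "nonnegative"
) -> np.ndarray:
    """Realize a T x T covariance matrix from a spec.

    ``rho_range='nonnegative'`` enforces the simulation's parameter space
    rho in [0, 1); ``rho_range='pd'`` admits the full positive-definite range
    of the structure (used by the fitting machinery, whose REML estimates may
    be slightly negative on null data).
    """
    if spec.kind == "unstructured":
        m = spec.free_matrix
        if m.shape != (T, T):
            raise ValueError(f"free_matrix shape {m.shape} does not match T={T}")
        validate_psd(m)
        return np.array(m, dtype=float)

    rho = float(spec.rho)
    if rho_range == "nonnegative":
        if not 0.0 <= rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {rho}")
    elif rho_range == "pd":
        lo = rho_lower_bound(spec.kind, T)
        if not lo < rho < 1.0:
            raise ValueError(f"rho must be in ({lo:g}, 1) for {spec.kind}, got {rho}")
    else:
        raise ValueError(f"unknown rho_range {rho_range!r}")

    if is_heterogeneous(spec.kind):
        sig = spec.sigmas
        if len(sig) != T:
            raise ValueError(f"sigmas length {len(sig)} does not match T={T}")
    else:
        sig = np.full(T, np.sqrt(spec.sigma2))
    cov = np.outer(sig, sig) * _correlation_matrix(spec.kind, rho, T)
    return cov


def validate_psd(m: np.ndarray, rel_tol: float = 1e-10) -> bool:
    """True iff ``m`` is symmetric positive definite.

    The eigenvalue floor is ``rel_tol`` times the largest diagonal entry;
    asymmetric input raises rather than returning False.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, rtol=1e-10, atol=1e-12 * max(1.0, np.abs(m).max())):
        raise ValueError("matrix is not symmetric")
    tol = rel_tol * float(np.max(np.diag(m)))
    return bool(np.linalg.eigvalsh(m)[0] > tol)
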