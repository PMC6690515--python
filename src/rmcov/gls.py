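"""REML fitting of the saturated treatment-by-time model under structured
residual covariance, with Wald tests and per-time-point contrasts.

Model
-----
For subject ``s`` in arm ``g`` with T repeated measures,

    y_s ~ N(mu_g, Sigma),        subjects independent,

where ``mu_g`` is the arm's cell-mean vector (one free mean per
treatment-by-time cell, G*T parameters) and ``Sigma`` is a T x T residual
covariance common to all subjects, parameterized by one of the structures in
:mod:`rmcov.covariance`.  In a balanced complete design GLS and OLS coincide
for the saturated mean model, so the fitted cell means are the per-cell
sample means for *any* Sigma, and the REML criterion depends on the data only
through the pooled within-group cross-product matrix

    S = sum_s (y_s - ybar_{g(s)}) (y_s - ybar_{g(s)})',

giving the restricted log-likelihood

    l_R(Sigma) = -1/2 [ (N - G) log|Sigma| + tr(Sigma^{-1} S)
                        + sum_g T log n_g + (N - G) T log 2*pi ].

Covariance parameters are estimated by quasi-Newton maximization over an
unconstrained reparameterization (log SDs; scaled logit of rho over the
structure's positive-definite range).  The unstructured fit has the closed
form ``Sigma_hat = S / (N - G)``.

Inference uses Wald F statistics on cell-mean contrasts with denominator
degrees of freedom by the Satterthwaite approximation (default; multi-df
contrasts via the eigenvector-component method), or residual or
between-within conventions.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, pinvh
from sklearn.base import BaseEstimator

from .covariance import (
    KINDS,
    CovarianceSpec,
    build_covariance,
    is_cs,
    is_heterogeneous,
    rho_lower_bound,
)


@dataclasses.dataclass(frozen=True)
class TestResult:
    """A Wald-type F test: statistic, numerator/denominator df, p-value."""

    statistic: float
    df_num: int
    df_den: float
    p_value: float


@dataclasses.dataclass(frozen=True)
class ContrastResult:
    """Treatment contrast at one time point.

    ``joint_test`` is the (G-1)-df F test of equality of all arm means at the
    time point; ``pairwise_sem`` maps each arm pair to the standard error of
    the difference of the two arm means there.
    """

    time_index: int
    joint_test: TestResult
    pairwise_sem: dict[tuple[str, str], float]


@dataclasses.dataclass(frozen=True)
class SufficientStats:
    """Balanced-design sufficient statistics for the saturated GLS model."""

    arms: tuple[str, ...]
    weeks: tuple
    n_per_arm: np.ndarray          # (G,) subjects per arm
    group_means: np.ndarray        # (G, T) per-cell sample means
    S: np.ndarray                  # (T, T) pooled within-group cross-products
    n_subjects: int

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def n_times(self) -> int:
        return len(self.weeks)


def prepare_stats(data: pd.DataFrame) -> SufficientStats:
    """Validate a balanced complete long-format dataset and reduce it.

    Requires columns ``subject, treatment, week, response``; every subject
    must have exactly one response at every week and belong to one arm.
    Row order is irrelevant.
    """
    required = {"subject", "treatment", "week", "response"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"dataset is missing required columns: {sorted(missing)}")
    wide = data.pivot(index="subject", columns="week", values="response")
    if wide.isna().any().any():
        raise ValueError("dataset is not balanced and complete")
    arm_of = data.groupby("subject")["treatment"].agg(lambda s: s.unique())
    if any(len(a) != 1 for a in arm_of):
        raise ValueError("each subject must belong to exactly one arm")
    arm_of = arm_of.map(lambda a: a[0])

    weeks = tuple(sorted(wide.columns))
    wide = wide[list(weeks)]
    arms = tuple(sorted(arm_of.unique()))
    if len(arms) < 2:
        raise ValueError("need at least 2 treatment arms")

    Y = wide.to_numpy(dtype=float)
    codes = arm_of.loc[wide.index].map({a: i for i, a in enumerate(arms)}).to_numpy()

    G, T = len(arms), len(weeks)
    n_per_arm = np.bincount(codes, minlength=G)
    if np.any(n_per_arm < 2):
        raise ValueError("each arm needs at least 2 subjects")
    group_means = np.empty((G, T))
    S = np.zeros((T, T))
    for g in range(G):
        Yg = Y[codes == g]
        group_means[g] = Yg.mean(axis=0)
        R = Yg - group_means[g]
        S += R.T @ R
    scale = max(1.0, float(np.abs(group_means).max()) ** 2)
    if np.trace(S) <= 1e-10 * scale:
        raise ValueError("degenerate data: no within-group variability")
    return SufficientStats(
        arms=arms,
        weeks=weeks,
        n_per_arm=n_per_arm,
        group_means=group_means,
        S=S,
        n_subjects=int(len(Y)),
    )


def _criterion_from_sigma(sigma: np.ndarray, ss: SufficientStats, method: str) -> float:
    """(Restricted) profile log-likelihood at a trial Sigma."""
    N, G, T = ss.n_subjects, ss.n_arms, ss.n_times
    dof = N - G if method == "reml" else N
    try:
        c, low = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular or non-PD covariance") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    quad = float(np.trace(cho_solve((c, low), ss.S)))
    const = dof * T * np.log(2.0 * np.pi)
    if method == "reml":
        const += float(np.sum(T * np.log(ss.n_per_arm)))
    return -0.5 * (dof * logdet + quad + const)


def reml_criterion(
    data: pd.DataFrame | SufficientStats,
    spec: CovarianceSpec,
    method: str = "reml",
) -> float:
    """Restricted (or profile ML) log-likelihood at trial covariance values."""
    ss = data if isinstance(data, SufficientStats) else prepare_stats(data)
    sigma = build_covariance(spec, ss.n_times, rho_range="pd")
    return _criterion_from_sigma(sigma, ss, method)


def _expit(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z)))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


class RepeatedMeasuresGLS(BaseEstimator):
    """GLS/REML fit of a balanced repeated-measures dataset.

    Parameters
    ----------
    structure : {'het_cs', 'het_ar1', 'hom_cs', 'hom_ar1', 'unstructured'}
        Residual covariance structure to fit (pooled across arms).
    method : {'reml', 'ml'}
        Estimation criterion; REML is the default and what the downstream
        simulation summaries use.
    ddf : {'satterthwaite', 'residual', 'between-within'}
        Denominator-df method for Wald F tests.
    max_iter, tol, grad_tol : optimizer controls (criterion change and
        projected-gradient tolerances on the unconstrained scale).
    n_restarts : jittered restarts attempted when the optimizer fails.
    random_state : seed for the restart jitter.

    Fitted attributes (trailing underscore) include ``cell_means_`` (G x T),
    ``Sigma_``, ``cov_spec_``, ``fixed_vcov_`` (GT x GT, arm-major),
    ``loglik_``, ``converged_`` and ``n_iter_``.
    """

    def __init__(
        self,
        structure: str = "het_cs",
        method: str = "reml",
        ddf: str = "satterthwaite",
        max_iter: int = 200,
        tol: float = 1e-8,
        grad_tol: float = 1e-5,
        n_restarts: int = 3,
        random_state: int = 0,
    ):
        self.structure = structure
        self.method = method
        self.ddf = ddf
        self.max_iter = max_iter
        self.tol = tol
        self.grad_tol = grad_tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X: pd.DataFrame | SufficientStats, y=None) -> "RepeatedMeasuresGLS":
        if self.structure not in KINDS:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.method not in ("reml", "ml"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.ddf not in ("satterthwaite", "residual", "between-within"):
            raise ValueError(f"unknown ddf method {self.ddf!r}")
        ss = X if isinstance(X, SufficientStats) else prepare_stats(X)
        self.stats_ = ss
        self.arms_ = ss.arms
        self.weeks_ = ss.weeks
        self.cell_means_ = ss.group_means.copy()

        if self.structure == "unstructured":
            self._fit_unstructured(ss)
        else:
            self._fit_structured(ss)

        # (X' V^-1 X)^-1 for the saturated balanced design: block-diagonal
        # with Sigma_hat / n_g per arm (arm-major ordering of cell means).
        G, T = ss.n_arms, ss.n_times
        V = np.zeros((G * T, G * T))
        for g in range(G):
            V[g * T : (g + 1) * T, g * T : (g + 1) * T] = self.Sigma_ / ss.n_per_arm[g]
        self.fixed_vcov_ = V
        self._dV_cache = None
        self._ucov_cache = None
        return self

    def _fit_unstructured(self, ss: SufficientStats) -> None:
        dof = ss.n_subjects - ss.n_arms if self.method == "reml" else ss.n_subjects
        sigma = ss.S / dof
        if np.linalg.eigvalsh(sigma)[0] <= 0:
            raise ValueError("pooled sample covariance is singular; cannot fit unstructured")
        self.Sigma_ = sigma
        self.cov_spec_ = CovarianceSpec(kind="unstructured", free_matrix=sigma)
        self.loglik_ = _criterion_from_sigma(sigma, ss, self.method)
        self.converged_ = True
        self.n_iter_ = 0

    # unconstrained parameterization -----------------------------------

    def _sigma_from_u(self, u: np.ndarray, T: int) -> np.ndarray:
        lo = rho_lower_bound(self.structure, T)
        rho = lo + (1.0 - lo) * _expit(u[-1])
        if is_heterogeneous(self.structure):
            sig = np.exp(u[:-1])
        else:
            sig = np.full(T, np.exp(u[0]))
        if is_cs(self.structure):
            corr = np.full((T, T), rho)
        else:
            corr = rho ** self._lag(T)
        np.fill_diagonal(corr, 1.0)
        return np.outer(sig, sig) * corr

    @staticmethod
    def _lag(T: int) -> np.ndarray:
        return np.abs(np.subtract.outer(np.arange(T), np.arange(T))).astype(float)

    def _start_values(self, ss: SufficientStats) -> np.ndarray:
        dof = ss.n_subjects - ss.n_arms
        R = ss.S / dof
        sd = np.sqrt(np.diag(R))
        corr = R / np.outer(sd, sd)
        lag1 = float(np.mean(np.diag(corr, k=1)))
        lo = rho_lower_bound(self.structure, ss.n_times)
        rho0 = float(np.clip(lag1, lo + 1e-3, 1.0 - 1e-3))
        z0 = _logit((rho0 - lo) / (1.0 - lo))
        if is_heterogeneous(self.structure):
            return np.append(np.log(sd), z0)
        return np.array([0.5 * np.log(float(np.mean(np.diag(R)))), z0])

    def _fit_structured(self, ss: SufficientStats) -> None:
        T = ss.n_times
        big = 1e12

        def neg(u: np.ndarray) -> float:
            sigma = self._sigma_from_u(u, T)
            try:
                return -_criterion_from_sigma(sigma, ss, self.method)
            except ValueError:
                return big

        u0 = self._start_values(ss)
        rng = np.random.default_rng(self.random_state)
        best = None
        converged = False
        n_iter = 0
        for attempt in range(self.n_restarts + 1):
            start = u0 if attempt == 0 else u0 + rng.normal(scale=0.1 * (1 + attempt), size=u0.shape)
            res = optimize.minimize(
                neg,
                start,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": self.grad_tol},
            )
            if best is None or res.fun < best.fun:
                best = res
                n_iter = int(res.nit)
            # gradient sanity bound scales with the criterion magnitude
            # (finite-difference gradients inherit the criterion's scale)
            grad_bound = 1e-4 * (1.0 + abs(res.fun))
            ok = res.success and np.isfinite(res.fun) and np.max(np.abs(res.jac)) < grad_bound
            if ok:
                best = res
                n_iter = int(res.nit)
                converged = True
                break
        u = best.x
        self.u_ = u
        self.Sigma_ = self._sigma_from_u(u, T)
        lo = rho_lower_bound(self.structure, T)
        rho = float(lo + (1.0 - lo) * _expit(u[-1]))
        if is_heterogeneous(self.structure):
            self.cov_spec_ = CovarianceSpec(
                kind=self.structure, sigmas=np.exp(u[:-1]), rho=rho
            )
        else:
            self.cov_spec_ = CovarianceSpec(
                kind=self.structure, sigma2=float(np.exp(2.0 * u[0])), rho=rho
            )
        self.loglik_ = -float(best.fun)
        self.converged_ = bool(converged)
        self.n_iter_ = n_iter

    # ------------------------------------------------------- Wald inference

    def _check_fitted(self) -> None:
        if not hasattr(self, "Sigma_"):
            raise AttributeError("estimator is not fitted; call fit() first")

    def _cell_index(self, g: int, t: int) -> int:
        return g * self.stats_.n_times + t

    def _contrast_matrices(self) -> dict[str, tuple[np.ndarray, str]]:
        G, T = self.stats_.n_arms, self.stats_.n_times
        p = G * T

        def e(g, t):
            v = np.zeros(p)
            v[self._cell_index(g, t)] = 1.0
            return v

        trt = np.zeros((G - 1, p))
        for i in range(1, G):
            for t in range(T):
                trt[i - 1] += (e(i, t) - e(0, t)) / T
        time = np.zeros((T - 1, p))
        for j in range(1, T):
            for g in range(G):
                time[j - 1] += (e(g, j) - e(g, 0)) / G
        inter = np.zeros(((G - 1) * (T - 1), p))
        r = 0
        for i in range(1, G):
            for j in range(1, T):
                inter[r] = e(i, j) - e(i, 0) - e(0, j) + e(0, 0)
                r += 1
        return {
            "treatment": (trt, "between"),
            "time": (time, "within"),
            "interaction": (inter, "within"),
        }

    def wald_tests(self) -> dict[str, TestResult]:
        """Overall treatment (G-1 df), time (T-1 df) and interaction
        ((G-1)(T-1) df) Wald F tests on the cell means."""
        self._check_fitted()
        return {
            name: self._wald(L, df_type)
            for name, (L, df_type) in self._contrast_matrices().items()
        }

    def contrast_at_time(self, time_index: int) -> ContrastResult:
        """Joint equality test of all arm means at one time point, plus the
        SEMs of all pairwise arm differences there."""
        self._check_fitted()
        ss = self.stats_
        G, T = ss.n_arms, ss.n_times
        if not 0 <= time_index < T:
            raise IndexError(f"time_index {time_index} out of range [0, {T})")
        p = G * T
        L = np.zeros((G - 1, p))
        for i in range(1, G):
            L[i - 1, self._cell_index(i, time_index)] = 1.0
            L[i - 1, self._cell_index(0, time_index)] = -1.0
        joint = self._wald(L, "between")
        var_t = float(self.Sigma_[time_index, time_index])
        sems = {}
        for a, b in itertools.combinations(range(G), 2):
            sems[(ss.arms[a], ss.arms[b])] = float(
                np.sqrt(var_t * (1.0 / ss.n_per_arm[a] + 1.0 / ss.n_per_arm[b]))
            )
        return ContrastResult(time_index=time_index, joint_test=joint, pairwise_sem=sems)

    def pairwise_tests_at_time(self, time_index: int) -> dict[tuple[str, str], TestResult]:
        """Single-df F tests of each pairwise arm difference at a time point."""
        self._check_fitted()
        ss = self.stats_
        G, T = ss.n_arms, ss.n_times
        if not 0 <= time_index < T:
            raise IndexError(f"time_index {time_index} out of range [0, {T})")
        out = {}
        for a, b in itertools.combinations(range(G), 2):
            L = np.zeros((1, G * T))
            L[0, self._cell_index(a, time_index)] = 1.0
            L[0, self._cell_index(b, time_index)] = -1.0
            out[(ss.arms[a], ss.arms[b])] = self._wald(L, "between")
        return out

    def _wald(self, L: np.ndarray, df_type: str) -> TestResult:
        q = L.shape[0]
        if np.linalg.matrix_rank(L) < q:
            raise ValueError("contrast matrix is rank deficient")
        beta = self.cell_means_.reshape(-1)
        M = L @ self.fixed_vcov_ @ L.T
        est = L @ beta
        F = float(est @ np.linalg.solve(M, est)) / q
        F = max(F, 0.0)
        ddf = self._denominator_df(L, df_type)
        p = float(stats.f.sf(F, q, ddf))
        return TestResult(statistic=F, df_num=q, df_den=float(ddf), p_value=p)

    # denominator degrees of freedom -----------------------------------

    def _denominator_df(self, L: np.ndarray, df_type: str) -> float:
        ss = self.stats_
        N, G, T = ss.n_subjects, ss.n_arms, ss.n_times
        residual = float(N * T - G * T)
        if self.ddf == "residual":
            return residual
        if self.ddf == "between-within":
            return float(N - G) if df_type == "between" else float((N - G) * (T - 1))
        if self.structure == "unstructured":
            return residual  # no scalar parameterization to differentiate
        return self._satterthwaite_df(L, fallback=residual)

    def _u_cov(self) -> np.ndarray:
        """Asymptotic covariance of the unconstrained covariance parameters
        (inverse numeric Hessian of the negative criterion at the optimum)."""
        if self._ucov_cache is None:
            ss, u = self.stats_, self.u_
            T = ss.n_times

            def f(v):
                try:
                    return -_criterion_from_sigma(self._sigma_from_u(v, T), ss, self.method)
                except ValueError:
                    return np.inf

            k = len(u)
            h = 1e-4 * (1.0 + np.abs(u))
            H = np.empty((k, k))
            f0 = f(u)
            for i in range(k):
                ei = np.zeros(k)
                ei[i] = h[i]
                H[i, i] = (f(u + ei) + f(u - ei) - 2.0 * f0) / h[i] ** 2
                for j in range(i):
                    ej = np.zeros(k)
                    ej[j] = h[j]
                    H[i, j] = H[j, i] = (
                        f(u + ei + ej) - f(u + ei - ej) - f(u - ei + ej) + f(u - ei - ej)
                    ) / (4.0 * h[i] * h[j])
            self._ucov_cache = pinvh(H)
        return self._ucov_cache

    def _dSigma(self) -> list[np.ndarray]:
        """Central-difference derivatives of Sigma wrt each unconstrained
        parameter, evaluated at the optimum."""
        if self._dV_cache is None:
            u, T = self.u_, self.stats_.n_times
            h = 1e-6 * (1.0 + np.abs(u))
            out = []
            for i in range(len(u)):
                ei = np.zeros(len(u))
                ei[i] = h[i]
                out.append(
                    (self._sigma_from_u(u + ei, T) - self._sigma_from_u(u - ei, T))
                    / (2.0 * h[i])
                )
            self._dV_cache = out
        return self._dV_cache

    def _grad_contrast_var(self, c: np.ndarray) -> np.ndarray:
        """Gradient of c' V_beta c wrt the unconstrained parameters."""
        ss = self.stats_
        T = ss.n_times
        cg = c.reshape(ss.n_arms, T)
        grads = []
        for dS in self._dSigma():
            grads.append(float(np.sum((cg @ dS) * cg / ss.n_per_arm[:, None])))
        return np.array(grads)

    def _satterthwaite_df(self, L: np.ndarray, fallback: float) -> float:
        """Satterthwaite denominator df; multi-df contrasts are decomposed
        into the eigenvectors of L V L' and the per-component dfs combined."""
        A = self._u_cov()
        M = L @ self.fixed_vcov_ @ L.T
        vals, vecs = np.linalg.eigh(M)
        q = L.shape[0]
        nus = []
        for m in range(q):
            d = float(vals[m])
            if d <= 0:
                continue
            c = L.T @ vecs[:, m]
            g = self._grad_contrast_var(c)
            denom = float(g @ A @ g)
            nus.append(2.0 * d * d / denom if denom > 1e-300 else np.inf)
        if len(nus) < q:
            return fallback
        E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
        if E <= q:
            return fallback
        return float(2.0 * E / (E - q))


#: spec-facing alias: a fitted :class:`RepeatedMeasuresGLS` *is* the fit result
FitResult = RepeatedMeasuresGLS


def fit_gls_reml(
    data: pd.DataFrame | SufficientStats, kind: str, **kwargs
) -> RepeatedMeasuresGLS:
    """Fit the saturated cell-means model by REML under a covariance kind."""
    return RepeatedMeasuresGLS(structure=kind, **kwargs).fit(data)


def test_fixed_effects(fit: RepeatedMeasuresGLS) -> dict[str, TestResult]:
    """Overall treatment, time and treatment-by-time Wald F tests."""
    return fit.wald_tests()


def time_point_contrast(fit: RepeatedMeasuresGLS, time_index: int) -> ContrastResult:
    """Joint treatment test and pairwise SEMs at one time point."""
    return fit.contrast_at_time(time_index)
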