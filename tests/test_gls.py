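import numpy as np
import pandas as pd
import pytest

from rmcov import (
    CovarianceSpec,
    RepeatedMeasuresGLS,
    ScenarioConfig,
    fit_gls_reml,
    prepare_stats,
    reml_criterion,
    simulate_arrays,
    simulate_dataset,
    time_point_contrast,
)
from rmcov import test_fixed_effects as fixed_effect_tests
from rmcov.evaluate import _stats_from_arrays

STRUCTURES = ("het_cs", "het_ar1", "hom_cs", "hom_ar1", "unstructured")


def hom_cs_closed_form(ss):
    """Analytic REML optimum for homogeneous compound symmetry.

    In the eigenbasis of the CS matrix the criterion separates into the
    'between' component b = (1'S1/T)/(N-G) and the 'within' component
    a = (tr S - 1'S1/T)/((T-1)(N-G)); sigma2 = ((T-1)a + b)/T and
    rho = (b - a)/(T * sigma2).
    """
    T = ss.n_times
    dof = ss.n_subjects - ss.n_arms
    q = float(np.ones(T) @ ss.S @ np.ones(T)) / T
    b = q / dof
    a = (float(np.trace(ss.S)) - q) / ((T - 1) * dof)
    sigma2 = ((T - 1) * a + b) / T
    rho = (b - a) / (T * sigma2)
    return sigma2, rho


class TestCellMeans:
    @pytest.mark.parametrize("structure", STRUCTURES)
    def test_gls_means_equal_group_means(self, small_dataset, structure):
        """GLS = OLS for the saturated mean model on balanced data."""
        fit = fit_gls_reml(small_dataset, structure)
        direct = (
            small_dataset.groupby(["treatment", "week"])["response"]
            .mean()
            .unstack()
            .to_numpy()
        )
        assert np.allclose(fit.cell_means_, direct, rtol=1e-10)


class TestRemlCriterion:
    def test_unstructured_closed_form_is_the_maximum(self, small_dataset):
        """REML over unstructured Sigma peaks at S/(N-G) exactly."""
        fit = fit_gls_reml(small_dataset, "unstructured")
        ss = fit.stats_
        dof = ss.n_subjects - ss.n_arms
        assert np.allclose(fit.Sigma_, ss.S / dof)
        opt = fit.loglik_
        assert opt == pytest.approx(
            reml_criterion(small_dataset, CovarianceSpec(kind="unstructured", free_matrix=ss.S / dof)),
            abs=1e-6,
        )
        # local perturbations can only lower the criterion
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = rng.normal(scale=0.02, size=(5, 5))
            pert = ss.S / dof + (A + A.T) * np.diag(ss.S / dof).mean() * 0.01
            val = reml_criterion(
                small_dataset, CovarianceSpec(kind="unstructured", free_matrix=pert)
            )
            assert val <= opt + 1e-8

    def test_het_criterion_at_equal_sigmas_equals_hom(self, small_dataset):
        het = CovarianceSpec(kind="het_cs", sigmas=np.full(5, 30.0), rho=0.4)
        hom = CovarianceSpec(kind="hom_cs", sigma2=900.0, rho=0.4)
        assert reml_criterion(small_dataset, het) == pytest.approx(
            reml_criterion(small_dataset, hom), abs=1e-9
        )

    def test_degenerate_zero_residual_data_rejected(self):
        rows = []
        for arm in ("A", "B"):
            for s in range(3):
                for w in (1, 2):
                    rows.append((f"{arm}{s}", arm, w, 10.0 * w))
        df = pd.DataFrame(rows, columns=["subject", "treatment", "week", "response"])
        with pytest.raises(ValueError, match="degenerate"):
            prepare_stats(df)

    @pytest.mark.parametrize("kind", ["het_cs", "het_ar1"])
    def test_optimum_beats_generating_parameters(self, params, small_dataset, kind):
        fit = fit_gls_reml(small_dataset, kind)
        truth = CovarianceSpec(kind=kind, sigmas=params.sd.mean(axis=0), rho=0.6)
        assert fit.loglik_ >= reml_criterion(small_dataset, truth) - 1e-8


class TestNestingAndClosedForms:
    @pytest.mark.parametrize("pair", [("het_cs", "hom_cs"), ("het_ar1", "hom_ar1")])
    def test_het_loglik_dominates_hom(self, small_dataset, null_dataset, pair):
        het, hom = pair
        for df in (small_dataset, null_dataset):
            lh = fit_gls_reml(df, het).loglik_
            ll = fit_gls_reml(df, hom).loglik_
            assert lh >= ll - 1e-6

    def test_unstructured_dominates_all_structured(self, small_dataset):
        lu = fit_gls_reml(small_dataset, "unstructured").loglik_
        for kind in STRUCTURES[:4]:
            assert lu >= fit_gls_reml(small_dataset, kind).loglik_ - 1e-6

    def test_hom_cs_matches_analytic_solution(self, small_dataset):
        fit = fit_gls_reml(small_dataset, "hom_cs")
        sigma2, rho = hom_cs_closed_form(fit.stats_)
        assert fit.cov_spec_.sigma2 == pytest.approx(sigma2, rel=1e-5)
        assert fit.cov_spec_.rho == pytest.approx(rho, abs=1e-5)

    def test_hom_cs_matches_mixedlm_random_intercept(self, small_dataset):
        """Independent oracle: a random-intercept mixed model is exactly
        homogeneous CS with sigma2 = tau2 + sigma_e2 and rho = tau2/sigma2."""
        sm = pytest.importorskip("statsmodels.api")
        df = small_dataset.copy()
        df["cell"] = df["treatment"].astype(str) + ":" + df["week"].astype(str)
        m = sm.MixedLM.from_formula(
            "response ~ C(cell) - 1", groups="subject", data=df
        ).fit(reml=True)
        tau2 = float(m.cov_re.iloc[0, 0])
        sig2e = float(m.scale)
        fit = fit_gls_reml(small_dataset, "hom_cs")
        assert fit.cov_spec_.sigma2 == pytest.approx(tau2 + sig2e, rel=1e-3)
        assert fit.cov_spec_.rho == pytest.approx(tau2 / (tau2 + sig2e), rel=1e-3)


class TestInvariance:
    def test_shift_invariance(self, small_dataset):
        shifted = small_dataset.assign(response=small_dataset["response"] + 500.0)
        f1 = fit_gls_reml(small_dataset, "het_cs")
        f2 = fit_gls_reml(shifted, "het_cs")
        assert np.allclose(f1.Sigma_, f2.Sigma_, rtol=1e-6)
        t1, t2 = f1.wald_tests(), f2.wald_tests()
        for k in t1:
            assert t1[k].statistic == pytest.approx(t2[k].statistic, rel=1e-6)
        c1, c2 = f1.contrast_at_time(2), f2.contrast_at_time(2)
        for pair in c1.pairwise_sem:
            assert c1.pairwise_sem[pair] == pytest.approx(c2.pairwise_sem[pair], rel=1e-6)

    def test_scale_equivariance(self, small_dataset):
        c = 3.0
        scaled = small_dataset.assign(response=small_dataset["response"] * c)
        f1 = fit_gls_reml(small_dataset, "het_ar1")
        f2 = fit_gls_reml(scaled, "het_ar1")
        assert np.allclose(f2.cov_spec_.sigmas, c * f1.cov_spec_.sigmas, rtol=1e-4)
        assert f2.cov_spec_.rho == pytest.approx(f1.cov_spec_.rho, abs=1e-5)
        w1, w2 = f1.wald_tests(), f2.wald_tests()
        for k in w1:
            assert w2[k].statistic == pytest.approx(w1[k].statistic, rel=1e-5)
            assert w2[k].p_value == pytest.approx(w1[k].p_value, rel=1e-4)


class TestWaldTests:
    def test_interaction_rank(self, small_dataset):
        tests = fixed_effect_tests(fit_gls_reml(small_dataset, "het_cs"))
        assert tests["interaction"].df_num == 8
        assert tests["treatment"].df_num == 2
        assert tests["time"].df_num == 4
        for res in tests.values():
            assert 0.0 <= res.p_value <= 1.0
            assert res.df_den > 0

    def test_equal_arm_means_give_zero_treatment_F(self, params):
        """Cloning one arm's responses into all arms forces F = 0, p = 1."""
        sc = ScenarioConfig("het_cs", 6, 0.3, "null", n_reps=2, base_seed=5)
        df = simulate_dataset(params, sc, 0)
        arm0 = df[df.treatment == params.arms[0]]
        clones = []
        for arm in params.arms:
            block = arm0.copy()
            block["treatment"] = arm
            block["subject"] = arm + "_" + block["subject"]
            clones.append(block)
        cloned = pd.concat(clones, ignore_index=True)
        fit = fit_gls_reml(cloned, "hom_cs")
        res = fit.wald_tests()["treatment"]
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        joint = fit.contrast_at_time(3).joint_test
        assert joint.statistic == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("ddf", ["residual", "between-within"])
    def test_conventional_df_methods(self, small_dataset, ddf):
        fit = RepeatedMeasuresGLS(structure="hom_cs", ddf=ddf).fit(small_dataset)
        tests = fit.wald_tests()
        N, G, T = 18, 3, 5
        if ddf == "residual":
            assert tests["treatment"].df_den == N * T - G * T
        else:
            assert tests["treatment"].df_den == N - G
            assert tests["time"].df_den == (N - G) * (T - 1)
            assert fit.contrast_at_time(0).joint_test.df_den == N - G

    def test_satterthwaite_df_reasonable_at_n12(self, null_dataset):
        fit = fit_gls_reml(null_dataset, "het_cs")
        con = fit.contrast_at_time(4)
        # between-subject contrast at one time: df near the 33 between-df
        assert 10 < con.joint_test.df_den < 40

    def test_pairwise_tests_exposed(self, small_dataset):
        fit = fit_gls_reml(small_dataset, "het_cs")
        pw = fit.pairwise_tests_at_time(2)
        assert len(pw) == 3
        for res in pw.values():
            assert res.df_num == 1
            assert 0 <= res.p_value <= 1


class TestContrastSems:
    def test_hom_fit_sem_constant_over_time(self, small_dataset):
        fit = fit_gls_reml(small_dataset, "hom_cs")
        sems = [
            next(iter(fit.contrast_at_time(t).pairwise_sem.values())) for t in range(5)
        ]
        assert np.allclose(sems, sems[0], rtol=1e-12)

    def test_het_fit_sem_closed_form(self, small_dataset):
        """pairwise SEM = sqrt(2 * sigma_t^2 / n) for a pooled structure."""
        fit = fit_gls_reml(small_dataset, "het_cs")
        n = 6
        for t in range(5):
            expected = np.sqrt(2.0 * fit.Sigma_[t, t] / n)
            for sem in fit.contrast_at_time(t).pairwise_sem.values():
                assert sem == pytest.approx(expected, abs=1e-9)

    def test_sem_does_not_depend_on_rho(self, small_dataset):
        """The between-subject difference variance is rho-free: rebuilding
        the fixed-effect covariance with a perturbed rho leaves SEMs put."""
        fit = fit_gls_reml(small_dataset, "het_cs")
        spec = fit.cov_spec_
        from rmcov import build_covariance

        for rho in (0.1, 0.5, 0.8):
            pert = build_covariance(
                CovarianceSpec(kind="het_cs", sigmas=spec.sigmas, rho=rho), 5
            )
            assert np.allclose(np.diag(pert), np.diag(fit.Sigma_))

    def test_time_index_out_of_range(self, small_dataset):
        fit = fit_gls_reml(small_dataset, "het_cs")
        with pytest.raises(IndexError):
            time_point_contrast(fit, 5)


class TestParameterRecovery:
    def test_rho_and_sigma5_recovered(self, params):
        """Monte-Carlo parameter recovery under het_cs truth at n=12."""
        sc = ScenarioConfig(
            "het_cs", 12, 0.6, "null", n_reps=1000, base_seed=314159
        )
        rhos = np.empty(sc.n_reps)
        sig5 = np.empty(sc.n_reps)
        for rep in range(sc.n_reps):
            ss = _stats_from_arrays(simulate_arrays(params, sc, rep), params)
            fit = RepeatedMeasuresGLS(structure="het_cs", ddf="residual").fit(ss)
            rhos[rep] = fit.cov_spec_.rho
            sig5[rep] = fit.cov_spec_.sigmas[4]
        assert abs(rhos.mean() - 0.6) < 0.05
        pooled_wk28_sd = np.sqrt(np.mean(params.sd[:, 4] ** 2))
        assert abs(sig5.mean() - pooled_wk28_sd) / pooled_wk28_sd < 0.05
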