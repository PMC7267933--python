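"""Mixed-model estimation, contrast testing, and their invariances."""

import warnings

import numpy as np
import pytest

from pdmorph import (
    LMEDesign,
    PiecewiseAgeTransform,
    RegionSpec,
    SLOPE_CONTRAST,
    build_design,
    contrast_F_test,
    fit_lme,
    generate_cohort,
    piecewise_age,
    slope_table,
)
from pdmorph.cohort import PdmorphError
from pdmorph.lme import ConvergenceError, _REMLProblem

from conftest import make_table, small_config


class TestPiecewiseAge:
    @pytest.mark.parametrize("age,knot,expected", [(50, 60, 0.0), (60, 60, 0.0), (70, 60, 10.0)])
    def test_knot_values(self, age, knot, expected):
        assert piecewise_age(age, knot) == expected

    def test_transform_object_validates_knot(self):
        with pytest.raises(PdmorphError):
            PiecewiseAgeTransform(knot=100.0)


class TestBuildDesign:
    def _table(self):
        rows = []
        for sid, grp, age, edu in [("C1", "CTRL", 65.0, 12.0), ("P1", "PDN", 70.0, 9.0),
                                   ("Q1", "PDCI", 55.0, 15.0)]:
            for j, t in enumerate([0.0, 1.1]):
                rows.append(dict(subject_id=sid, group=grp, baseline_age=age,
                                 education=edu, visit_index=j, time_from_baseline=t,
                                 vol=100.0 - t))
        return make_table(rows)

    def test_control_baseline_row(self):
        d = build_design(self._table(), "vol")
        row = d.X[(d.subject == "C1") & (d.t == 0.0)][0]
        np.testing.assert_allclose(row, [1, 0, 0, 0, 0, 0, 5.0, 12.0])

    def test_pdn_interaction_row(self):
        d = build_design(self._table(), "vol")
        row = d.X[(d.subject == "P1") & (d.t == 1.1)][0]
        np.testing.assert_allclose(row, [1, 1.1, 1, 1.1, 0, 0, 10.0 + 1.1 * 0, 9.0])

    def test_pdci_rows_use_second_indicator(self):
        d = build_design(self._table(), "vol")
        row = d.X[(d.subject == "Q1") & (d.t == 1.1)][0]
        # age 55 below knot: transformed age 0 under enrollment mode
        np.testing.assert_allclose(row, [1, 1.1, 0, 0, 1, 1.1, 0.0, 15.0])

    def test_always_eight_columns_and_missing_dropped(self):
        t = self._table()
        t.df.loc[0, "vol"] = np.nan
        d = build_design(t, "vol")
        assert d.X.shape == (5, 8)

    def test_visit_age_mode_varies_with_time(self):
        d = build_design(self._table(), "vol", age_mode="visit")
        row = d.X[(d.subject == "P1") & (d.t == 1.1)][0]
        assert row[6] == pytest.approx(11.1)


def _design_from(cfg, seed, region="reg", standardize=False, center_covariates=False):
    tab, truth = generate_cohort(cfg, seed=seed)
    d = build_design(tab, region)
    X, y = d.X.copy(), d.y.copy()
    if center_covariates:
        X[:, 6] -= X[:, 6].mean()
        X[:, 7] -= X[:, 7].mean()
    if standardize:
        y = (y - y.mean()) / y.std()
    return LMEDesign(X=X, y=y, t=d.t, subject=d.subject, region=region), truth


class TestFitLME:
    def test_noiseless_limit_recovers_beta_exactly(self):
        beta = np.array([100.0, -1.0, -2.0, -0.5, -3.0, 0.5, -0.2, 0.05])
        cfg = small_config(n=8, beta=beta, random_cov=np.zeros((2, 2)), residual_sd=0.0)
        d, _ = _design_from(cfg, seed=1)
        fit = fit_lme(d)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-6)

    def test_matches_statsmodels_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        import pandas as pd

        cfg = small_config(n=40, seed=3,
                           random_cov=np.array([[4.0, 0.2], [0.2, 1.0]]),
                           residual_sd=1.0)
        d, _ = _design_from(cfg, seed=4, center_covariates=True)
        fit = fit_lme(d)
        df = pd.DataFrame(d.X, columns=list("abcdefgh"))
        df["y"], df["s"] = d.y, d.subject
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mf = sm.MixedLM(df["y"], df[list("abcdefgh")], groups=df["s"],
                            exog_re=df[["a", "b"]]).fit(reml=True)
        assert mf.converged
        np.testing.assert_allclose(fit.beta, mf.fe_params.values, atol=1e-4)
        np.testing.assert_allclose(fit.psi, mf.cov_re.values, atol=1e-4)
        assert fit.sigma2 == pytest.approx(mf.scale, abs=1e-5)
        assert fit.loglik == pytest.approx(mf.llf, abs=1e-6)

    def test_restricted_loglik_formula_matches_statsmodels_at_same_params(self):
        """The likelihood evaluator itself (not just the optimum) agrees
        with the independent implementation at arbitrary parameters."""
        sm = pytest.importorskip("statsmodels.api")
        import math

        import pandas as pd

        cfg = small_config(n=20, seed=5)
        d, _ = _design_from(cfg, seed=5)
        prob = _REMLProblem(d)
        theta = np.array([1.3, -0.2, 0.4])
        beta, A, rss, logdet, s2 = prob.profile(theta)
        dfree = prob.n_obs - 8
        _, ldA = np.linalg.slogdet(A)
        ours = -0.5 * (dfree * math.log(2 * math.pi) + dfree * math.log(s2)
                       + logdet + ldA + dfree)
        df = pd.DataFrame(d.X, columns=list("abcdefgh"))
        df["y"], df["s"] = d.y, d.subject
        model = sm.MixedLM(df["y"], df[list("abcdefgh")], groups=df["s"],
                           exog_re=df[["a", "b"]])
        model.cov_pen = None  # set by fit(); loglike needs it
        G = prob.theta_to_G(theta)
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        # statsmodels profiles beta and sigma2 out the same way, so its
        # restricted loglik at the same relative covariance is comparable
        params = MixedLMParams.from_components(fe_params=beta, cov_re=G)
        theirs = model.loglike(params)
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_optimum_at_least_as_good_as_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        import pandas as pd

        cfg = small_config(n=40, seed=3)  # near-boundary slope variance
        d, _ = _design_from(cfg, seed=3, standardize=True)
        fit = fit_lme(d)
        df = pd.DataFrame(d.X, columns=list("abcdefgh"))
        df["y"], df["s"] = d.y, d.subject
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mf = sm.MixedLM(df["y"], df[list("abcdefgh")], groups=df["s"],
                            exog_re=df[["a", "b"]]).fit(reml=True)
        assert fit.loglik >= mf.llf - 1e-6

    def test_gls_equals_ols_when_psi_fixed_to_zero(self):
        cfg = small_config(n=15)
        d, _ = _design_from(cfg, seed=9)
        fit = fit_lme(d, fix_theta=[0.0, 0.0, 0.0])
        ols, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
        np.testing.assert_allclose(fit.beta, ols, atol=1e-8)

    def test_single_visit_subjects_error_advises_intercept_mode(self):
        rows = [dict(subject_id=f"S{i}", visit_index=0, time_from_baseline=0.0,
                     baseline_age=60.0 + i, education=10 + (i % 5), vol=100.0 + i)
                for i in range(12)]
        t = make_table(rows)
        d = build_design(t, "vol")
        with pytest.raises(ConvergenceError, match="random_slope=False"):
            fit_lme(d)
        fit = fit_lme(d, random_slope=False)
        # one observation per subject: GLS collapses to OLS
        ols, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    def test_reml_objective_locally_optimal(self):
        cfg = small_config(n=25)
        d, _ = _design_from(cfg, seed=13)
        fit = fit_lme(d)
        prob = fit._problem
        f0 = prob.neg2_reml(fit.theta)
        rng = np.random.default_rng(0)
        for _ in range(20):
            step = rng.normal(0, 0.05, size=3)
            cand = fit.theta + step
            cand[0] = max(cand[0], 0.0)
            cand[2] = max(cand[2], 0.0)
            assert prob.neg2_reml(cand) >= f0 - 1e-7

    def test_slope_recovery_within_monte_carlo_error(self):
        truth_b = np.array([-1.0, -0.5, 0.5])  # beta1, beta3, beta5
        cfg = small_config(n=20)
        est = []
        for r in range(60):
            d, _ = _design_from(cfg, seed=300 + r)
            fit = fit_lme(d)
            est.append([fit.beta[1], fit.beta[3], fit.beta[5]])
        est = np.array(est)
        mcse = est.std(axis=0) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - truth_b) < 3 * mcse)


class TestContrast:
    def test_default_contrast_has_df1_two(self):
        cfg = small_config(n=15)
        d, _ = _design_from(cfg, seed=21)
        ct = contrast_F_test(fit_lme(d))
        assert ct.df1 == 2
        assert np.array_equal(ct.L, SLOPE_CONTRAST)

    def test_noiseless_equal_slopes_give_null_f(self):
        beta = np.array([100.0, -1.0, -2.0, 0.0, -3.0, 0.0, -0.2, 0.05])
        cfg = small_config(n=8, beta=beta, random_cov=np.zeros((2, 2)), residual_sd=0.0)
        d, _ = _design_from(cfg, seed=2)
        ct = contrast_F_test(fit_lme(d))
        assert ct.F < 1e-6 and ct.p == pytest.approx(1.0)

    def test_scale_and_shift_invariance_of_f(self):
        cfg = small_config(n=20)
        d, _ = _design_from(cfg, seed=31)
        f1 = contrast_F_test(fit_lme(d), df_method="residual")
        d2 = LMEDesign(X=d.X, y=-3.0 * d.y + 40.0, t=d.t, subject=d.subject)
        f2 = contrast_F_test(fit_lme(d2), df_method="residual")
        assert f2.F == pytest.approx(f1.F, rel=1e-5)
        assert f2.p == pytest.approx(f1.p, rel=1e-4)

    def test_rank_deficient_contrast_rejected(self):
        cfg = small_config(n=10)
        d, _ = _design_from(cfg, seed=41)
        fit = fit_lme(d)
        L = np.vstack([SLOPE_CONTRAST[0], SLOPE_CONTRAST[0]])
        with pytest.raises(PdmorphError, match="rank"):
            contrast_F_test(fit, L)

    def test_satterthwaite_df_smaller_than_residual(self):
        cfg = small_config(n=20)
        d, _ = _design_from(cfg, seed=51)
        fit = fit_lme(d)
        resid = contrast_F_test(fit, df_method="residual")
        satt = contrast_F_test(fit, df_method="satterthwaite")
        assert satt.df2 < resid.df2
        assert satt.df2 > 2


class TestSlopeTable:
    def test_report_structure_and_thickness_units(self):
        cfg = small_config(n=20, kind="thickness", units="mm",
                           beta=np.array([2.5, -0.028, 0, 0, 0, 0, -0.004, 0.0]),
                           random_cov=np.array([[0.01, 0], [0, 2.5e-5]]),
                           residual_sd=0.02)
        d, _ = _design_from(cfg, seed=61)
        fits = {"reg": fit_lme(d)}
        out = slope_table(fits, units={"reg": "mm"})
        assert len(out) == 1
        row = out.iloc[0]
        # -0.028 mm/y renders as -28 um/y
        assert row["rate_ctrl_um_per_year"] == pytest.approx(row["rate_ctrl"] * 1000)
        assert row["rate_ctrl_um_per_year"] == pytest.approx(-28.0, abs=8.0)
        assert row["DF1"] == 2
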