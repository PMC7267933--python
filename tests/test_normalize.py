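"""Reference normalization, covariate correction, percent deviation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdmorph import (
    NormalizationReference,
    Region,
    apply_covariate_correction,
    correct_table,
    fit_control_covariate_model,
    hemisphere_average,
    normalize_table,
    normalize_to_reference,
    percent_deviation,
)
from pdmorph.normalize import DomainError, SingularityError

from conftest import make_table

ICV_REF = NormalizationReference("ICV", 1459.3)


class TestReferenceNormalization:
    def test_reference_equal_to_mean_is_identity(self):
        assert normalize_to_reference(100.0, 1459.3, ICV_REF) == pytest.approx(100.0)

    def test_smaller_head_scales_up(self):
        # 100 * 1459.3 / 1400
        assert normalize_to_reference(100.0, 1400.0, ICV_REF) == pytest.approx(
            104.2357, abs=1e-4
        )

    def test_zero_maps_to_zero(self):
        assert normalize_to_reference(0.0, 1234.0, ICV_REF) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(DomainError):
            normalize_to_reference(100.0, 0.0, ICV_REF)

    @settings(max_examples=50, deadline=None)
    @given(c=st.floats(0, 100), v=st.floats(0, 1e4), r=st.floats(500, 2500))
    def test_scale_equivariance(self, c, v, r):
        lhs = normalize_to_reference(c * v, r, ICV_REF)
        rhs = c * normalize_to_reference(v, r, ICV_REF)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-9)


def _controls_frame(n=50, g1=-2.0, g2=0.5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        age = rng.uniform(50, 80)
        edu = rng.uniform(8, 20)
        val = 500 + g1 * age + g2 * edu + noise * rng.standard_normal()
        rows.append(dict(subject_id=f"C{i}", group="CTRL", visit_index=0,
                         time_from_baseline=0.0, baseline_age=age, education=edu,
                         vol=val))
    return make_table(rows).baseline()


class TestCovariateCorrection:
    def test_noiseless_slopes_recovered_exactly(self):
        base = _controls_frame(g1=-2.0, g2=0.5)
        model = fit_control_covariate_model(base, "vol", ref_age=66.7, ref_education=14.3)
        assert model.gamma1 == pytest.approx(-2.0, abs=1e-9)
        assert model.gamma2 == pytest.approx(0.5, abs=1e-9)

    def test_noisy_slopes_within_three_analytic_ses(self):
        g1, g2, sd, n = -2.0, 0.5, 5.0, 200
        base = _controls_frame(n=n, g1=g1, g2=g2, noise=sd, seed=1)
        model = fit_control_covariate_model(base, "vol", 66.7, 14.3)
        X = np.column_stack([np.ones(n), base["baseline_age"], base["education"]])
        cov = sd**2 * np.linalg.inv(X.T @ X)
        assert abs(model.gamma1 - g1) < 3 * np.sqrt(cov[1, 1])
        assert abs(model.gamma2 - g2) < 3 * np.sqrt(cov[2, 2])

    def test_underdetermined_design_raises(self):
        base = _controls_frame(n=2)
        with pytest.raises(SingularityError):
            fit_control_covariate_model(base, "vol", 66.7, 14.3)

    def test_subject_at_reference_covariates_unchanged(self):
        model = fit_control_covariate_model(_controls_frame(), "vol", 66.7, 14.3)
        assert apply_covariate_correction(123.4, 66.7, 14.3, model) == pytest.approx(123.4)

    def test_direct_arithmetic(self):
        model = fit_control_covariate_model(_controls_frame(g1=-2.0, g2=0.0), "vol", 66.7, 14.3)
        # two years older than reference with slope -2: value gains +4
        assert apply_covariate_correction(100.0, 68.7, 14.3, model) == pytest.approx(
            104.0, abs=1e-6
        )

    def test_zero_slopes_are_identity(self):
        from pdmorph import CovariateCorrectionModel

        model = CovariateCorrectionModel("vol", 0.0, 0.0, 0.0, 66.7, 14.3, 10, 0.0)
        for v, a, e in [(0.0, 50, 8), (99.9, 80, 20)]:
            assert apply_covariate_correction(v, a, e, model) == v

    def test_correction_exact_on_fitting_population(self):
        """Mean corrected control value equals the model's prediction at
        the reference covariates (the correction recentres controls)."""
        base = _controls_frame(n=80, noise=3.0, seed=4)
        model = fit_control_covariate_model(base, "vol", 66.7, 14.3)
        corrected = apply_covariate_correction(
            base["vol"], base["baseline_age"], base["education"], model
        )
        at_ref = model.gamma0 + model.gamma1 * 66.7 + model.gamma2 * 14.3
        assert corrected.mean() == pytest.approx(at_ref, abs=1e-9)


class TestHemisphereAverage:
    def test_pair_averaged(self):
        out = hemisphere_average({"acc_lh": 2.4, "acc_rh": 2.6})
        assert out["acc"] == pytest.approx(2.5)

    def test_missing_side_gives_missing_and_warns(self):
        with pytest.warns(UserWarning, match="acc"):
            out = hemisphere_average({"acc_lh": 2.4})
        assert np.isnan(out["acc"])

    def test_commutes_with_linear_correction(self):
        model_base = _controls_frame(g1=-1.5, g2=0.3)
        model = fit_control_covariate_model(model_base, "vol", 66.7, 14.3)
        rng = np.random.default_rng(2)
        for _ in range(10):
            lh, rh, age, edu = rng.uniform([1, 1, 50, 8], [3, 3, 80, 20])
            avg_then = apply_covariate_correction(0.5 * (lh + rh), age, edu, model)
            then_avg = 0.5 * (
                apply_covariate_correction(lh, age, edu, model)
                + apply_covariate_correction(rh, age, edu, model)
            )
            assert avg_then == pytest.approx(then_avg, rel=1e-12)


class TestPercentDeviation:
    @pytest.mark.parametrize("g,c,expected", [(97, 100, -3.0), (100, 100, 0.0), (105, 100, 5.0)])
    def test_sign_convention(self, g, c, expected):
        assert percent_deviation(g, c) == pytest.approx(expected)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(DomainError):
            percent_deviation(1.0, 0.0)


class TestTablePipeline:
    def _table(self):
        rows = []
        ages = [58.0, 66.0, 71.0, 63.0, 69.0]
        edus = [12.0, 9.0, 16.0, 11.0, 14.0]
        for i, (grp, icv, mt) in enumerate(
            [("CTRL", 1400.0, 2.4), ("CTRL", 1500.0, 2.6), ("CTRL", 1450.0, 2.5),
             ("PDN", 1550.0, 2.5), ("PDCI", 1350.0, 2.5)]
        ):
            for j, t in enumerate([0.0, 1.0]):
                rows.append(dict(subject_id=f"S{i}", group=grp, icv=icv,
                                 baseline_age=ages[i], education=edus[i],
                                 visit_index=j, time_from_baseline=t,
                                 vol=100.0, th=2.5, mean_thickness=mt))
        regions = {"vol": Region("volume", "cm3"), "th": Region("thickness", "mm")}
        return make_table(rows, regions=regions)

    def test_volumes_normalized_to_cohort_mean_icv(self):
        table = self._table()
        out, refs = normalize_table(table)
        icv_mean = table.baseline()["icv"].mean()
        assert refs["ICV"].cohort_mean == pytest.approx(icv_mean)
        row = out.df[out.df["subject_id"] == "S0"].iloc[0]
        assert row["vol"] == pytest.approx(100.0 * icv_mean / 1400.0)

    def test_thickness_normalized_to_mean_thickness_and_units_kept(self):
        table = self._table()
        out, refs = normalize_table(table)
        mt_mean = table.baseline()["mean_thickness"].mean()
        row = out.df[out.df["subject_id"] == "S0"].iloc[0]
        # dimensionless ratio times cohort mean: still mm-scale thickness
        assert row["th"] == pytest.approx(2.5 * mt_mean / 2.4)
        assert 1.0 < row["th"] < 4.0

    def test_followup_reuses_baseline_subject_reference(self):
        table = self._table()
        table.df.loc[table.df["visit_index"] == 1, "mean_thickness"] = 99.0
        out, _ = normalize_table(table)
        s0 = out.df[out.df["subject_id"] == "S0"]
        assert s0.iloc[0]["th"] == pytest.approx(s0.iloc[1]["th"])

    def test_double_normalization_blocked_by_provenance(self):
        table = self._table()
        out, _ = normalize_table(table)
        with pytest.raises(DomainError, match="already normalized"):
            normalize_table(out)

    def test_correction_requires_normalization_and_is_single_shot(self):
        table = self._table()
        with pytest.raises(DomainError, match="normalize"):
            correct_table(table)
        normalized, _ = normalize_table(table)
        corrected, models = correct_table(normalized)
        assert "vol" in models and "mean_thickness" in models
        with pytest.raises(DomainError, match="already"):
            correct_table(corrected)
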