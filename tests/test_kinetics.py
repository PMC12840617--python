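"""Inhibition kinetics: closed-form Ki, global fits, IC50 and assay arithmetic."""

import numpy as np
import pytest

from peptiforge import (
    KineticsDataset,
    apparent_km,
    apparent_vmax,
    dh_percent,
    fit_ic50,
    fit_inhibition_global,
    fit_michaelis_menten,
    gen_kinetics,
    inhibition_percent,
    ki_competitive,
    ki_noncompetitive,
    lineweaver_burk,
    mw_from_sec,
    protein_content_kjeldahl,
    select_model,
)
from peptiforge.simulate import NoiseModel

KM, VMAX = 0.2684, 1.4428  # uninhibited truth used throughout the simulations


class TestClosedFormKi:
    def test_competitive_doubling_identity(self):
        assert ki_competitive(0.5, 1.0, I=333.0) == pytest.approx(333.0)

    def test_competitive_roundtrip(self):
        ki = ki_competitive(KM, 0.4196, 400.0)
        assert apparent_km(KM, ki, 400.0) == pytest.approx(0.4196, rel=1e-12)

    def test_competitive_requires_km_increase(self):
        with pytest.raises(ValueError):
            ki_competitive(0.5, 0.4, 100.0)

    def test_noncompetitive_halving_identity(self):
        assert ki_noncompetitive(2.0, 1.0, I=77.0) == pytest.approx(77.0)

    def test_noncompetitive_roundtrip(self):
        ki = ki_noncompetitive(VMAX, 0.4580, 400.0)
        assert apparent_vmax(VMAX, ki, 400.0) == pytest.approx(0.4580, rel=1e-12)

    def test_noncompetitive_requires_vmax_decrease(self):
        with pytest.raises(ValueError):
            ki_noncompetitive(1.0, 1.2, 100.0)


class TestMichaelisMenten:
    def test_noiseless_recovery(self):
        d = gen_kinetics("michaelis_menten", KM, VMAX, I_grid=(0.0,), replicates=2)
        fit = fit_michaelis_menten(d.S, d.v)
        assert fit.Km == pytest.approx(KM, rel=1e-6)
        assert fit.Vmax == pytest.approx(VMAX, rel=1e-6)

    def test_half_saturation_at_km(self):
        d = gen_kinetics("michaelis_menten", KM, VMAX, I_grid=(0.0,))
        fit = fit_michaelis_menten(d.S, d.v)
        assert fit.predict(fit.Km) == pytest.approx(fit.Vmax / 2)

    def test_noisy_recovery_median_error_under_ten_percent(self):
        errors = []
        for seed in range(100):
            d = gen_kinetics(
                "michaelis_menten", KM, VMAX, I_grid=(0.0,),
                S_grid=np.geomspace(0.025, 0.4, 12), replicates=2,
                noise=NoiseModel(velocity_cv=0.05), seed=seed,
            )
            fit = fit_michaelis_menten(d.S, d.v)
            errors.append(max(abs(fit.Km - KM) / KM, abs(fit.Vmax - VMAX) / VMAX))
        assert np.median(errors) < 0.10

    def test_requires_three_distinct_substrate_levels(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten([0.1, 0.1, 0.2], [1, 1, 2])


class TestGlobalInhibitionFit:
    def test_noiseless_competitive_selected_and_recovered(self):
        d = gen_kinetics("competitive", KM, VMAX, Ki=709.0)
        fits = fit_inhibition_global(d)
        best = select_model(fits)
        assert best.model == "competitive"
        assert best.Ki == pytest.approx(709.0, rel=1e-6)
        assert best.Km == pytest.approx(KM, rel=1e-6)
        assert best.Vmax == pytest.approx(VMAX, rel=1e-6)

    def test_noiseless_noncompetitive_selected(self):
        d = gen_kinetics("noncompetitive", KM, VMAX, Ki=186.0)
        best = select_model(fit_inhibition_global(d))
        assert best.model == "noncompetitive"
        assert best.Ki == pytest.approx(186.0, rel=1e-6)

    def test_uninhibited_data_reduce_to_michaelis_menten(self):
        d = gen_kinetics("michaelis_menten", KM, VMAX, I_grid=(0.0,))
        fits = fit_inhibition_global(d)
        assert len(fits) == 1 and fits[0].model == "michaelis_menten"

    def test_fits_ordered_by_aicc(self):
        d = gen_kinetics("competitive", KM, VMAX, Ki=709.0, noise=NoiseModel(velocity_cv=0.02), seed=0)
        fits = fit_inhibition_global(d)
        assert [f.aicc for f in fits] == sorted(f.aicc for f in fits)

    def test_missing_uninhibited_level_rejected(self):
        d = gen_kinetics("competitive", KM, VMAX, Ki=709.0)
        with pytest.raises(ValueError, match="I = 0"):
            fit_inhibition_global(KineticsDataset(d.S, d.I + 100.0, d.v))

    def test_global_ki_consistent_with_closed_form(self):
        # On noiseless data the per-level apparent parameters reproduce the
        # global Ki through the closed-form relations.
        d = gen_kinetics("competitive", KM, VMAX, Ki=709.0, I_grid=(0.0, 400.0))
        best = select_model(fit_inhibition_global(d))
        app = fit_michaelis_menten(d.at_level(400.0).S, d.at_level(400.0).v)
        assert ki_competitive(best.Km, app.Km, 400.0) == pytest.approx(best.Ki, rel=1e-6)

        d2 = gen_kinetics("noncompetitive", KM, VMAX, Ki=186.0, I_grid=(0.0, 400.0))
        best2 = select_model(fit_inhibition_global(d2))
        app2 = fit_michaelis_menten(d2.at_level(400.0).S, d2.at_level(400.0).v)
        assert ki_noncompetitive(best2.Vmax, app2.Vmax, 400.0) == pytest.approx(best2.Ki, rel=1e-6)


class TestLineweaverBurk:
    def test_competitive_family_shares_y_intercept(self):
        d = gen_kinetics("competitive", KM, VMAX, Ki=709.0)
        lines = lineweaver_burk(d)
        intercepts = [l.y_intercept for l in lines.values()]
        np.testing.assert_allclose(intercepts, 1.0 / VMAX, rtol=1e-9)

    def test_noncompetitive_family_shares_negative_x_intercept(self):
        d = gen_kinetics("noncompetitive", KM, VMAX, Ki=186.0)
        lines = lineweaver_burk(d)
        x_ints = [l.x_intercept for l in lines.values()]
        np.testing.assert_allclose(x_ints, -1.0 / KM, rtol=1e-9)
        assert all(x < 0 for x in x_ints)

    def test_two_point_line_hand_computed(self):
        # points: (1/S, 1/v) = (1, 1) and (2, 3) -> slope 2, intercept -1
        d = KineticsDataset([1.0, 0.5], [0.0, 0.0], [1.0, 1.0 / 3.0])
        line = lineweaver_burk(d)[0.0]
        assert line.slope == pytest.approx(2.0)
        assert line.y_intercept == pytest.approx(-1.0)
        assert line.x_intercept == pytest.approx(0.5)

    def test_single_point_level_rejected(self):
        with pytest.raises(ValueError):
            lineweaver_burk(KineticsDataset([0.1], [0.0], [1.0]))


class TestInhibitionPercent:
    def test_full_and_zero_inhibition(self):
        assert inhibition_percent(0.0, 0.9) == 100.0
        assert inhibition_percent(0.9, 0.9) == 0.0

    def test_worked_arithmetic(self):
        assert inhibition_percent(0.3, 0.9) == pytest.approx(100 * 2 / 3)

    def test_zero_control_slope_rejected(self):
        with pytest.raises(ValueError):
            inhibition_percent(0.1, 0.0)

    def test_negative_result_warned_not_clamped(self):
        with pytest.warns(UserWarning):
            assert inhibition_percent(1.2, 1.0) == pytest.approx(-20.0)


class TestIc50:
    @staticmethod
    def exact_curve(conc, ic50, hill=1.0):
        return 100.0 / (1.0 + (np.asarray(conc) / ic50) ** hill)

    def test_exact_logistic_recovery(self):
        conc = np.array([50, 100, 250, 500, 1000, 2000], dtype=float)
        fit = fit_ic50(conc, self.exact_curve(conc, 321.5))
        assert fit.ic50 == pytest.approx(321.5, rel=1e-6)
        assert fit.in_range

    def test_fifty_percent_at_fitted_ic50(self):
        conc = np.array([50, 100, 250, 500, 1000, 2000], dtype=float)
        fit = fit_ic50(conc, self.exact_curve(conc, 465.6, hill=1.3))
        assert fit.predict(fit.ic50) == pytest.approx(50.0)

    def test_noisy_median_bias_under_five_percent(self):
        conc = np.array([62.5, 125, 250, 500, 1000, 2000, 4000], dtype=float)
        biases = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            act = self.exact_curve(conc, 321.5) * rng.lognormal(0.0, 0.02, size=conc.size)
            fit = fit_ic50(conc, act)
            biases.append(abs(fit.ic50 - 321.5) / 321.5)
        assert np.median(biases) < 0.05

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            fit_ic50([1, 10, 100], [90, 50, 10])

    def test_non_monotone_response_warns(self):
        conc = [10, 100, 1000, 10000]
        with pytest.warns(UserWarning, match="monotone"):
            fit_ic50(conc, [90, 30, 80, 5])


class TestAssayArithmetic:
    def test_dh_identity_and_zero(self):
        assert dh_percent(0.01, 5.0, 0.2, 0.01, 5.0, 0.2) == pytest.approx(100.0)
        assert dh_percent(0.0, 5.0, 0.2, 0.01, 5.0, 0.2) == 0.0

    def test_dh_worked_case(self):
        # 100 * (0.002*10*0.5) / (0.01*50*0.2) = 10 %
        assert dh_percent(0.002, 10.0, 0.2, 0.01, 50.0, 0.5) == pytest.approx(10.0)

    def test_kjeldahl_blank_equals_sample(self):
        assert protein_content_kjeldahl(5.0, 5.0, 0.1, 0.3, 50.0) == 0.0

    def test_kjeldahl_linear_in_acid_molarity(self):
        x1 = protein_content_kjeldahl(12.0, 2.0, 0.1, 0.3, 50.0)
        x2 = protein_content_kjeldahl(12.0, 2.0, 0.2, 0.3, 50.0)
        assert x2 == pytest.approx(2 * x1)

    def test_kjeldahl_worked_case(self):
        # (10 mL * 0.1 M * 0.014 * 5.7 * 100) / (0.3 g * 0.5) = 53.2 g/100 g
        assert protein_content_kjeldahl(12.0, 2.0, 0.1, 0.3, 50.0) == pytest.approx(53.2, rel=1e-12)

    def test_kjeldahl_blank_above_sample_rejected(self):
        with pytest.raises(ValueError):
            protein_content_kjeldahl(2.0, 5.0, 0.1, 0.3, 50.0)


class TestSecCalibration:
    STANDARDS = [(451.48, 28.0), (6511.0, 22.0), (12500.0, 20.0), (66000.0, 16.0)]

    def test_sample_at_standard_rt_returns_standard_mw(self):
        # exactly log-linear standards: log10(MW) = -0.25*rt + 10
        standards = [(10 ** (10 - 0.25 * rt), rt) for rt in (16, 20, 24, 28)]
        mw, extrapolated = mw_from_sec(standards, 20.0)
        assert mw == pytest.approx(standards[1][0], rel=1e-9)
        assert not extrapolated

    def test_midpoint_of_two_standards_is_geometric_mean(self):
        mw, _ = mw_from_sec([(1000.0, 10.0), (10000.0, 20.0)], 15.0)
        assert mw == pytest.approx(np.sqrt(1000.0 * 10000.0), rel=1e-9)

    def test_four_standards_match_hand_regression(self):
        rt = np.array([s[1] for s in self.STANDARDS])
        logmw = np.log10([s[0] for s in self.STANDARDS])
        a, b = np.polyfit(rt, logmw, 1)
        mw, _ = mw_from_sec(self.STANDARDS, 21.0)
        assert mw == pytest.approx(10 ** (a * 21.0 + b), rel=1e-12)

    def test_extrapolation_flagged(self):
        _, extrapolated = mw_from_sec(self.STANDARDS, 40.0)
        assert extrapolated

    def test_degenerate_standards_rejected(self):
        with pytest.raises(ValueError):
            mw_from_sec([(100.0, 10.0), (200.0, 10.0)], 10.0)


class TestDatasetValidation:
    def test_shape_and_sign_checks(self):
        with pytest.raises(ValueError):
            KineticsDataset([0.1, -0.2], [0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            KineticsDataset([0.1, 0.2], [0.0, -1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            KineticsDataset([0.1, 0.2], [0.0, 0.0], [1.0, 0.0])

    def test_csv_roundtrip(self, tmp_path):
        d = gen_kinetics("competitive", KM, VMAX, Ki=709.0, noise=NoiseModel(velocity_cv=0.02), seed=3)
        path = tmp_path / "kin.csv"
        d.to_dataframe().to_csv(path, index=False)
        back = KineticsDataset.from_csv(path)
        np.testing.assert_allclose(back.v, d.v)
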