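"""PET quantification: normalisation, windowed integrals, metric contracts."""

import numpy as np
import pytest

from viscnet import (
    KineticParams,
    TimeActivityCurve,
    ValidationError,
    compute_systemic_metrics,
    compute_uptake_metrics,
    integrate_window,
    normalize_to_pid_g,
    simulate_tracer_kinetics,
)
from viscnet.simulate import default_roi_volumes_mL


def _tac(times, values, roi="liver"):
    return TimeActivityCurve(np.asarray(times, float), np.asarray(values, float), roi)


def _flat_curves(level=1.0):
    t = np.linspace(0, 60, 121)
    return {
        roi: _tac(t, np.full_like(t, level), roi)
        for roi in ("liver", "visceral_fat", "gut")
    }


class TestNormalize:
    def test_definition_identity(self):
        # activity == dose / body_weight  ->  100 %ID/g everywhere
        t = np.linspace(0, 60, 13)
        tac = _tac(t, np.full_like(t, 3.7 / 25.0))
        out = normalize_to_pid_g(tac, dose_MBq=3.7, body_weight_g=25.0)
        np.testing.assert_allclose(out.activities, 100.0)

    def test_zero_activity_stays_zero(self):
        tac = _tac([0, 30, 60], [0, 0, 0])
        out = normalize_to_pid_g(tac, 3.7, 25.0)
        assert np.all(out.activities == 0)

    def test_linear_in_body_weight(self):
        tac = _tac([0, 30, 60], [0.1, 0.2, 0.05])
        a = normalize_to_pid_g(tac, 3.7, 20.0).activities
        b = normalize_to_pid_g(tac, 3.7, 40.0).activities
        np.testing.assert_allclose(b, 2 * a)

    def test_per_g_dose_convention_omits_body_weight(self):
        tac = _tac([0, 30, 60], [0.1, 0.2, 0.05])
        out = normalize_to_pid_g(tac, 2.0, 25.0, convention="per_g_dose")
        np.testing.assert_allclose(out.activities, 100.0 * tac.activities / 2.0)

    @pytest.mark.parametrize("dose,bw", [(0, 25), (-1, 25), (3.7, 0), (3.7, -5)])
    def test_nonpositive_dose_or_weight_rejected(self, dose, bw):
        tac = _tac([0, 30, 60], [1, 1, 1])
        with pytest.raises(ValidationError):
            normalize_to_pid_g(tac, dose, bw)

    def test_scale_invariance(self):
        """Multiplying dose and all activities by one constant leaves every
        %ID/g value unchanged."""
        t = np.linspace(0, 60, 121)
        act = np.exp(-t / 20.0)
        for c in (3.0, 0.1):
            a = normalize_to_pid_g(_tac(t, act), 3.7, 25.0).activities
            b = normalize_to_pid_g(_tac(t, c * act), c * 3.7, 25.0).activities
            np.testing.assert_allclose(a, b, rtol=1e-12)


class TestIntegrateWindow:
    def test_constant_and_linear(self):
        t = np.linspace(0, 10, 21)
        assert integrate_window(t, np.ones_like(t), 0, 10) == pytest.approx(10.0)
        assert integrate_window(t, t / 10.0, 0, 10) == pytest.approx(5.0)

    def test_exponential_against_closed_form(self):
        t = np.arange(0, 60.0001, 0.1)
        area = integrate_window(t, np.exp(-t), 0, 60)
        assert area == pytest.approx(1 - np.exp(-60), abs=1e-3)

    def test_off_grid_endpoints_interpolated(self):
        # piecewise-linear curve: trapezoid with interpolated endpoints is exact
        t = np.array([0.0, 4.0, 8.0, 12.0])
        v = np.array([0.0, 4.0, 8.0, 12.0])  # v = t
        assert integrate_window(t, v, 3.0, 9.0) == pytest.approx((81 - 9) / 2.0)

    def test_window_additivity(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 60, 121)
        v = rng.random(t.size)
        total = integrate_window(t, v, 0, 60)
        split = integrate_window(t, v, 0, 10) + integrate_window(t, v, 10, 60)
        assert split == pytest.approx(total, rel=1e-12)

    def test_window_outside_support_rejected(self):
        t = np.linspace(0, 60, 61)
        with pytest.raises(ValidationError):
            integrate_window(t, np.ones_like(t), -1, 10)
        with pytest.raises(ValidationError):
            integrate_window(t, np.ones_like(t), 50, 70)
        with pytest.raises(ValidationError):
            integrate_window(t, np.ones_like(t), 10, 10)


class TestUptakeMetrics:
    def test_identical_curves_give_unit_ratio(self):
        m = compute_uptake_metrics(_flat_curves(), glycemia_mmol_L=5.0)
        assert m.vf_over_liver == pytest.approx(1.0)
        assert m.gut_over_liver == pytest.approx(1.0)

    def test_zero_glycemia_zeroes_uptake_and_ratios_missing(self):
        m = compute_uptake_metrics(_flat_curves(), glycemia_mmol_L=0.0)
        assert all(v == 0 for v in m.gu_pre.values())
        assert all(v == 0 for v in m.gu_post.values())
        assert np.isnan(m.vf_over_liver) and np.isnan(m.liver_over_vf)

    def test_ratio_reciprocity(self):
        curves = _flat_curves()
        curves["visceral_fat"] = _tac(curves["liver"].times,
                                      3.0 * curves["liver"].activities,
                                      "visceral_fat")
        m = compute_uptake_metrics(curves, 5.0)
        assert m.vf_over_liver * m.liver_over_vf == pytest.approx(1.0, rel=1e-12)
        assert m.gut_over_liver * m.liver_over_gut == pytest.approx(1.0, rel=1e-12)

    def test_missing_organ_rejected(self):
        curves = _flat_curves()
        del curves["gut"]
        with pytest.raises(ValidationError):
            compute_uptake_metrics(curves, 5.0)

    def test_uptake_matches_simulator_compartment_solution(self):
        """Noise-free quantification agrees with an independent recomputation
        from the analytic compartment amounts within 0.5%."""
        p = KineticParams()
        dose, bw, gly = 3.7, 25.0, 6.0
        volumes = default_roi_volumes_mL(bw)
        sim = simulate_tracer_kinetics(p, dose, volumes_mL=volumes)
        norm = {
            roi: normalize_to_pid_g(sim.tacs[roi], dose, bw)
            for roi in ("liver", "visceral_fat", "gut")
        }
        m = compute_uptake_metrics(norm, gly)

        a = p.k_pa + p.k_pg + p.k_pv + p.k_pl
        b = p.k_bg + p.k_bv + p.k_bl + p.k_loss

        def int_amount(k_pre, k_post, t0, t1):
            # closed-form ∫ tissue(t) dt = k_pre ∫∫P + k_post ∫∫B over [t0, t1]
            tt = np.array([t0, t1])
            iiP = dose * (tt + (np.exp(-a * tt) - 1) / a) / a
            iiB = dose * p.k_pa / (b - a) * (
                (tt + (np.exp(-a * tt) - 1) / a) / a
                - (tt + (np.exp(-b * tt) - 1) / b) / b
            )
            return k_pre * (iiP[1] - iiP[0]) + k_post * (iiB[1] - iiB[0])

        for organ, k_pre, k_post in (
            ("liver", p.k_pl, p.k_bl),
            ("visceral_fat", p.k_pv, p.k_bv),
            ("gut", p.k_pg, p.k_bg),
        ):
            vol = volumes[organ]
            expected_pre = 100 * bw / dose / vol * int_amount(k_pre, k_post, 0, 10) * gly
            expected_post = 100 * bw / dose / vol * int_amount(k_pre, k_post, 10, 60) * gly
            assert m.gu_pre[organ] == pytest.approx(expected_pre, rel=5e-3)
            assert m.gu_post[organ] == pytest.approx(expected_post, rel=5e-3)


class TestSystemicMetrics:
    def test_arithmetic_identity(self):
        # dose 10 MBq over a blood AUC of 2 MBq*min/mL -> clearance 5 mL/min;
        # x glycemia 5 mmol/L / 25 g -> EGP 1 umol/min/g
        t = np.linspace(0, 60, 121)
        blood = _tac(t, np.full_like(t, 2.0 / 60.0), "blood")
        m = compute_systemic_metrics(blood, dose_MBq=10.0, glycemia_mmol_L=5.0,
                                     body_weight_g=25.0)
        assert m.clearance_mL_min == pytest.approx(5.0)
        assert m.egp_umol_min_g == pytest.approx(1.0)

    def test_blood_silent_before_10min_gives_zero_early_fraction(self):
        t = np.linspace(0, 60, 121)
        act = np.where(t <= 10.0, 0.0, 1.0)
        m = compute_systemic_metrics(_tac(t, act, "blood"), 3.7, 5.0, 25.0)
        assert m.blood_fraction_0_10 == pytest.approx(0.0)

    def test_zero_blood_integral_rejected(self):
        t = np.linspace(0, 60, 121)
        with pytest.raises(ValidationError):
            compute_systemic_metrics(_tac(t, np.zeros_like(t), "blood"), 3.7, 5.0, 25.0)

    def test_early_and_late_fractions_sum_to_one(self, default_sim):
        blood = default_sim.tacs["blood"]
        m = compute_systemic_metrics(blood, 3.7, 5.0, 25.0)
        late = (integrate_window(blood.times, blood.activities, 10, 60)
                / integrate_window(blood.times, blood.activities, 0, 60))
        assert m.blood_fraction_0_10 + late == pytest.approx(1.0, rel=1e-12)
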