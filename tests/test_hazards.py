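"""Hazard scaling and calibration against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiocea.curves import NonfatalRatioSchedule, RiskCurve, synth_life_table, synth_risk_curve
from cardiocea.hazards import (
    CalibrationError,
    CalibrationTargets,
    CancerMortalityParams,
    PatientScenario,
    annual_nonfatal_ihd,
    annual_prob_from_cum,
    calibrate,
    cycle_hazards,
    dose_risk_multiplier,
    scaled_annual_ihd_death,
)
from cardiocea.markov import simulate_cohort


def _flat_curve(q=0.001, start=50, end=80):
    n = end - start
    return RiskCurve(np.arange(start, end), np.full(n, q))


def _zero_life(start=50, end=80):
    return synth_life_table(start, end, 1e-300, 0.0)


NO_CANCER = CancerMortalityParams(0.0, 5)
SCHEDULE = NonfatalRatioSchedule()


class TestDoseRiskMultiplier:
    @pytest.mark.parametrize("mhd, rr", [(0.0, 1.0), (5.0, 1.37), (0.5, 1.037), (16.0, 2.184)])
    def test_linear_dose_response(self, mhd, rr):
        assert dose_risk_multiplier(mhd) == pytest.approx(rr)

    def test_affine_in_dose(self):
        # RR(a+b) - RR(a) must equal RR(b) - RR(0) for an affine response
        assert dose_risk_multiplier(7.0) - dose_risk_multiplier(3.0) == pytest.approx(
            dose_risk_multiplier(4.0) - dose_risk_multiplier(0.0)
        )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            dose_risk_multiplier(-0.1)


class TestAnnualProbFromCum:
    def test_five_year_cancer_rate(self):
        assert annual_prob_from_cum(0.06, 5) == pytest.approx(1 - 0.94 ** 0.2, rel=1e-12)
        assert annual_prob_from_cum(0.06, 5) == pytest.approx(0.0122988, abs=5e-7)

    def test_zero_and_identity(self):
        assert annual_prob_from_cum(0.0, 7) == 0.0
        assert annual_prob_from_cum(0.3, 1) == pytest.approx(0.3)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            annual_prob_from_cum(1.0, 5)


class TestScaling:
    def test_neutral_factors_identity(self):
        assert scaled_annual_ihd_death(0.001, 1, 1, 1) == 0.001

    def test_combined_scaling(self):
        assert scaled_annual_ihd_death(0.001, 10, 1.37, 1) == pytest.approx(0.01370)

    def test_clamped_at_ceiling(self):
        assert scaled_annual_ihd_death(0.5, 10, 1.37, 1) == 0.999

    def test_hazard_rate_mode_matches_rate_algebra(self):
        q, factor = 0.01, 3.0
        out = scaled_annual_ihd_death(q, factor, 1, 1, scaling_mode="hazard_rate")
        assert out == pytest.approx(1 - (1 - q) ** factor)
        # modes agree to first order for small probabilities
        assert out == pytest.approx(factor * q, rel=5e-2)

    @pytest.mark.parametrize("age, expected", [(45, 0.005), (72, 0.001)])
    def test_nonfatal_ratio_bands(self, age, expected):
        assert annual_nonfatal_ihd(0.001, age, SCHEDULE, 1.0) == pytest.approx(expected)

    def test_nonfatal_zero_hazard(self):
        assert annual_nonfatal_ihd(0.0, 45, SCHEDULE, 1.0) == 0.0


class TestCalibration:
    def test_closed_form_flat_no_competition(self):
        # flat q=0.001 over 30 y, death target 5%: s = (1 - 0.95**(1/30)) / 0.001
        curve = _flat_curve()
        scenario = PatientScenario(50, photon_mhd=0.0, proton_mhd=0.0)
        targets = CalibrationTargets(0.05, 0.05, strategy_mhd=0.0)
        res = calibrate(curve, _zero_life(), NO_CANCER, SCHEDULE, scenario, targets)
        expected = (1 - 0.95 ** (1 / 30)) / 0.001
        assert res.s_death == pytest.approx(expected, abs=1e-6)
        assert res.s_nonfatal == 0.0
        assert res.achieved_death == pytest.approx(0.05, abs=1e-9)

    def test_bisection_matches_grid_search(self):
        # brute-force minimiser of |achieved - target| over a 1e-4 grid
        curve = _flat_curve(0.002)
        scenario = PatientScenario(50, photon_mhd=0.0, proton_mhd=0.0)
        targets = CalibrationTargets(0.08, 0.08, strategy_mhd=0.0)
        res = calibrate(curve, _zero_life(), NO_CANCER, SCHEDULE, scenario, targets)

        grid = np.arange(0.5, 3.0, 1e-4)
        def achieved(s):
            hz = cycle_hazards(curve, _zero_life(), NO_CANCER, SCHEDULE, scenario, 0.0, s, 0.0)
            return simulate_cohort(hz).cum_ihd_death
        errs = np.array([abs(achieved(s) - 0.08) for s in grid])
        best = grid[int(np.argmin(errs))]
        assert res.s_death == pytest.approx(best, abs=1e-4)

    def test_fixed_point_when_already_matching(self, baseline):
        model, scenario = baseline
        trace = model.trace(scenario, "photon")
        targets = CalibrationTargets(trace.cum_ihd_death, trace.cum_total_ihd, strategy_mhd=5.0)
        cal = model.calibrations["photon"]
        # pre-scale the curve so unit scalars already match the targets
        scaled = RiskCurve(model.curve.ages, model.curve.probs * cal.s_death)
        schedule = NonfatalRatioSchedule(
            bands=tuple((lo, hi, r * cal.s_nonfatal) for lo, hi, r in SCHEDULE.bands)
        )
        res = calibrate(scaled, model.life, model.cancer, schedule, scenario, targets)
        assert res.s_death == pytest.approx(1.0, abs=1e-6)
        assert res.s_nonfatal == pytest.approx(1.0, abs=1e-6)

    def test_oracle_equivalence_product_complement(self):
        # without competing mortality or non-fatal events, the calibrated
        # cumulative must equal the closed-form product complement
        curve = synth_risk_curve(50, 80, 0.03, 2.0)
        scenario = PatientScenario(50, photon_mhd=0.0, proton_mhd=0.0)
        targets = CalibrationTargets(0.06, 0.06, strategy_mhd=0.0)
        res = calibrate(curve, _zero_life(), NO_CANCER, SCHEDULE, scenario, targets)
        scaled = RiskCurve(curve.ages, curve.probs * res.s_death)
        assert scaled.cumulative_incidence(50, 80) == pytest.approx(0.06, abs=1e-9)

    def test_infeasible_target_raises(self):
        curve = _flat_curve(1e-6, 78, 80)
        scenario = PatientScenario(78, photon_mhd=0.0, proton_mhd=0.0)
        targets = CalibrationTargets(0.999, 0.999, strategy_mhd=0.0)
        with pytest.raises(CalibrationError):
            calibrate(curve, _zero_life(78, 80), NO_CANCER, SCHEDULE, scenario, targets)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        death=st.floats(0.005, 0.15),
        total_ratio=st.floats(1.05, 4.0),
        doubling=st.floats(1.0, 4.0),
        start=st.sampled_from([40, 50, 60]),
    )
    def test_calibration_hits_any_feasible_target(self, death, total_ratio, doubling, start):
        curve = synth_risk_curve(start, 80, 0.03, doubling)
        life = synth_life_table(start, 80, 0.0016, 0.082)
        scenario = PatientScenario(start)
        total = min(death * total_ratio, 0.95)
        targets = CalibrationTargets(death, total, strategy_mhd=5.0)
        res = calibrate(curve, life, CancerMortalityParams(), SCHEDULE, scenario, targets)
        assert abs(res.achieved_death - death) < 1e-9
        assert abs(res.achieved_total - total) < 1e-9


class TestCycleHazards:
    def test_cancer_hazard_only_in_window(self):
        curve = _flat_curve()
        hz = cycle_hazards(
            curve, _zero_life(), CancerMortalityParams(0.06, 5), SCHEDULE,
            PatientScenario(50), mhd=5.0,
        )
        assert np.all(hz.p_cancer[:5] == pytest.approx(annual_prob_from_cum(0.06, 5)))
        assert np.all(hz.p_cancer[5:] == 0.0)

    def test_subtract_ihd_from_other(self):
        curve = _flat_curve(0.002)
        life = synth_life_table(50, 80, 0.003, 0.0)
        hz = cycle_hazards(
            curve, life, NO_CANCER, SCHEDULE, PatientScenario(50), mhd=0.0,
            subtract_ihd_from_other=True,
        )
        assert np.all(hz.p_other == pytest.approx(0.001))
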