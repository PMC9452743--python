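"""Cohort engine: transition rows, conservation, accounting, microsim oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiocea.cea import EconParams
from cardiocea.markov import (
    CohortTrace,
    HazardOverflowError,
    HazardSet,
    ModelSettings,
    OutcomeSummary,
    State,
    accumulate,
    build_transition_row,
    microsim_oracle,
    simulate_cohort,
)

ECON = EconParams()
HCC_OFF = ModelSettings(half_cycle_correction=False)
HCC_ON = ModelSettings(half_cycle_correction=True)


def _hazards(n=30, start=50, p_id=0.0, p_nf=0.0, p_ca=0.0, p_ot=0.0):
    full = lambda p: np.full(n, p) if np.isscalar(p) else np.asarray(p)  # noqa: E731
    return HazardSet(start, full(p_id), full(p_nf), full(p_ca), full(p_ot))


@st.composite
def random_hazard_sets(draw):
    n = draw(st.integers(5, 40))
    probs = st.floats(0.0, 0.15)
    arr = lambda: np.array(draw(st.lists(probs, min_size=n, max_size=n)))  # noqa: E731
    return HazardSet(50, arr(), arr(), arr(), arr())


class TestTransitionRow:
    def test_zero_hazards_identity(self):
        row = build_transition_row(State.HEALTHY, 50, 0, 0, 0, 0)
        assert row.tolist() == [1, 0, 0, 0, 0]

    def test_death_rows_absorbing(self):
        for s in (State.IHD_DEATH, State.CANCER_DEATH, State.OTHER_DEATH):
            row = build_transition_row(s, 50, 0.5, 0.5, 0.4, 0.3)
            expected = np.zeros(5)
            expected[s] = 1.0
            assert row.tolist() == expected.tolist()

    def test_healthy_stay_probability(self):
        row = build_transition_row(State.HEALTHY, 50, 0.02, 0.01, 0.012295, 0.003)
        assert row[State.HEALTHY] == pytest.approx(0.954705)
        assert row.sum() == pytest.approx(1.0)

    def test_nonfatal_cannot_return_to_healthy(self):
        row = build_transition_row(State.NONFATAL_IHD, 50, 0.02, 0.99, 0.01, 0.003)
        assert row[State.HEALTHY] == 0.0  # p_nonfatal ignored from NONFATAL_IHD

    def test_overflow_names_age(self):
        with pytest.raises(HazardOverflowError, match="age 63"):
            build_transition_row(State.HEALTHY, 63, 0.5, 0.4, 0.2, 0.1)


class TestCohortTrace:
    def test_zero_hazards_stay_healthy(self):
        trace = simulate_cohort(_hazards())
        assert np.all(trace.occupancy[:, State.HEALTHY] == 1.0)
        trace.validate()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hz=random_hazard_sets())
    def test_conservation_and_monotone_absorption(self, hz):
        trace = simulate_cohort(hz)
        trace.validate(atol=1e-12)  # sums to 1, absorbing non-decreasing, flows consistent

    def test_flows_match_occupancy_increments(self):
        hz = _hazards(p_id=0.01, p_nf=0.02, p_ca=0.005, p_ot=0.003)
        trace = simulate_cohort(hz)
        assert trace.new_ihd_death.sum() == pytest.approx(trace.cum_ihd_death, abs=1e-12)
        assert trace.cum_total_ihd > trace.cum_ihd_death


class TestAccumulate:
    def test_single_healthy_cycle_undiscounted(self):
        trace = simulate_cohort(_hazards(n=1))
        out = accumulate(trace, ECON.with_(discount_rate=0.0), HCC_OFF, one_off_cost=0.0)
        assert out.discounted_qaly == pytest.approx(0.95)

    def test_single_nonfatal_cycle_undiscounted(self):
        occ = np.zeros((2, 5))
        occ[:, State.NONFATAL_IHD] = 1.0
        trace = CohortTrace(50, occ, *(np.zeros(1),) * 4)
        out = accumulate(trace, ECON.with_(discount_rate=0.0), HCC_OFF, one_off_cost=0.0)
        assert out.discounted_qaly == pytest.approx(0.695)

    def test_dead_cohort_costs_radiotherapy_only(self):
        occ = np.zeros((31, 5))
        occ[:, State.OTHER_DEATH] = 1.0
        trace = CohortTrace(50, occ, *(np.zeros(30),) * 4)
        out = accumulate(trace, ECON, HCC_ON, one_off_cost=12_000.0)
        assert out.discounted_cost == 12_000.0
        assert out.discounted_qaly == 0.0

    def test_zero_rate_equals_raw_occupancy_sum(self):
        hz = _hazards(p_id=0.01, p_nf=0.02, p_ot=0.005)
        trace = simulate_cohort(hz)
        out = accumulate(trace, ECON.with_(discount_rate=0.0), HCC_OFF, 0.0)
        raw = (
            0.95 * trace.occupancy[1:, State.HEALTHY].sum()
            + 0.695 * trace.occupancy[1:, State.NONFATAL_IHD].sum()
        )
        assert out.discounted_qaly == pytest.approx(raw, rel=1e-12)

    def test_discounting_strictly_decreases_qaly(self):
        hz = _hazards(p_id=0.01)
        trace = simulate_cohort(hz)
        q0 = accumulate(trace, ECON.with_(discount_rate=0.0), HCC_ON, 0.0).discounted_qaly
        q3 = accumulate(trace, ECON, HCC_ON, 0.0).discounted_qaly
        assert q3 < q0

    def test_half_cycle_correction_averages_boundaries(self):
        # single cycle, half the cohort dies: HCC credits the half-cycle lived
        occ = np.zeros((2, 5))
        occ[0, State.HEALTHY] = 1.0
        occ[1, State.HEALTHY] = 0.5
        occ[1, State.OTHER_DEATH] = 0.5
        trace = CohortTrace(50, occ, np.zeros(1), np.zeros(1), np.zeros(1), np.array([0.5]))
        econ0 = ECON.with_(discount_rate=0.0)
        with_hcc = accumulate(trace, econ0, HCC_ON, 0.0).discounted_qaly
        without = accumulate(trace, econ0, HCC_OFF, 0.0).discounted_qaly
        assert without == pytest.approx(0.95 * 0.5)
        assert with_hcc == pytest.approx(0.95 * 0.75)


class TestMicrosimOracle:
    def test_zero_hazards_everyone_healthy(self):
        res = microsim_oracle(_hazards(n=10), ECON, HCC_ON, 0.0, n_patients=500, seed=1)
        assert np.all(res.occupancy[:, State.HEALTHY] == 1.0)
        assert res.summary.discounted_qaly == pytest.approx(
            accumulate(simulate_cohort(_hazards(n=10)), ECON, HCC_ON, 0.0).discounted_qaly
        )

    def test_same_seed_identical_output(self):
        hz = _hazards(p_id=0.01, p_nf=0.02, p_ca=0.01, p_ot=0.005)
        a = microsim_oracle(hz, ECON, HCC_ON, 50_000.0, n_patients=2_000, seed=7)
        b = microsim_oracle(hz, ECON, HCC_ON, 50_000.0, n_patients=2_000, seed=7)
        assert a.summary == b.summary
        assert np.array_equal(a.occupancy, b.occupancy)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_cohort_trace_on_random_scenarios(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 35))
        hz = _hazards(
            n=n,
            p_id=rng.uniform(0, 0.05, n),
            p_nf=rng.uniform(0, 0.08, n),
            p_ca=rng.uniform(0, 0.02, n),
            p_ot=rng.uniform(0, 0.04, n),
        )
        cohort = accumulate(simulate_cohort(hz), ECON, HCC_ON, 50_000.0)
        res = microsim_oracle(hz, ECON, HCC_ON, 50_000.0, n_patients=20_000, seed=seed + 100)
        for name in ("discounted_cost", "discounted_qaly", "cum_ihd_death", "cum_total_ihd"):
            se = max(res.se[name], 1e-12)
            assert abs(getattr(res.summary, name) - getattr(cohort, name)) < 3 * se


class TestStrategySymmetry:
    def test_equal_doses_and_costs_make_strategies_identical(self, sweep):
        # with a shared calibration, equal MHD and equal radiotherapy cost the
        # two strategies must produce bit-identical outcome summaries
        from dataclasses import replace

        model, scenario = sweep
        scen = replace(scenario, photon_mhd=0.5)
        econ = model.econ.with_(cost_proton=12_000.0)
        a = model.outcome(scen, "proton", econ)
        b = model.outcome(scen, "photon", econ)
        assert a == b
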