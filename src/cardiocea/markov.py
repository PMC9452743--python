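"""Five-state Markov cohort engine with half-cycle-corrected accounting.

States: HEALTHY, NONFATAL_IHD and three absorbing death states (IHD, cancer,
other).  A closed cohort starts 100% HEALTHY at the end of radiotherapy and
is cycled one year at a time to the horizon age.  The engine is deliberately
independent of how the per-cycle hazards were constructed: it consumes a
:class:`HazardSet` of per-cycle transition probabilities and produces a
:class:`CohortTrace` (state occupancy plus incident flows), from which
discounted costs and QALYs are accumulated.

A patient-level microsimulation (:func:`microsim_oracle`) draws individual
trajectories from the same transition rows and serves as an independent
Monte-Carlo check on the cohort algebra.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # EconParams lives in cea.py; accumulate only reads attributes
    from .cea import EconParams

__all__ = [
    "State",
    "ABSORBING_STATES",
    "ModelSettings",
    "HazardSet",
    "HazardOverflowError",
    "CohortTrace",
    "OutcomeSummary",
    "AccumulationCoefficients",
    "build_transition_row",
    "simulate_cohort",
    "accumulation_coefficients",
    "accumulate",
    "microsim_oracle",
    "MicrosimResult",
]


class State(IntEnum):
    HEALTHY = 0
    NONFATAL_IHD = 1
    IHD_DEATH = 2
    CANCER_DEATH = 3
    OTHER_DEATH = 4


ABSORBING_STATES = (State.IHD_DEATH, State.CANCER_DEATH, State.OTHER_DEATH)
N_STATES = len(State)


class HazardOverflowError(ValueError):
    """Competing exit probabilities from an alive state sum to >= 1."""


@dataclass(frozen=True)
class ModelSettings:
    """Cycle bookkeeping: annual cycles, half-cycle correction on by default."""

    cycle_length: float = 1.0
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.cycle_length != 1.0:
            raise ValueError("only 1-year cycles are supported")


@dataclass(frozen=True)
class HazardSet:
    """Per-cycle transition probabilities, indexed by cycle (age start_age + t)."""

    start_age: int
    p_ihd_death: np.ndarray
    p_nonfatal: np.ndarray
    p_cancer: np.ndarray
    p_other: np.ndarray

    def __post_init__(self) -> None:
        n = self.p_ihd_death.size
        for name in ("p_nonfatal", "p_cancer", "p_other"):
            if getattr(self, name).size != n:
                raise ValueError("hazard arrays must have equal length")

    @property
    def n_cycles(self) -> int:
        return int(self.p_ihd_death.size)

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.n_cycles)


def build_transition_row(
    state: State,
    age: int,
    p_ihd_death: float,
    p_nonfatal: float,
    p_cancer: float,
    p_other: float,
) -> np.ndarray:
    """One row of the cycle's transition matrix.

    HEALTHY can move to any other state; NONFATAL_IHD only to the death
    states (no second non-fatal event is modelled); death rows are identity.
    """
    row = np.zeros(N_STATES)
    if state in ABSORBING_STATES:
        row[state] = 1.0
        return row
    for name, p in (
        ("p_ihd_death", p_ihd_death),
        ("p_nonfatal", p_nonfatal),
        ("p_cancer", p_cancer),
        ("p_other", p_other),
    ):
        if not 0 <= p < 1:
            raise HazardOverflowError(f"{name}={p!r} outside [0, 1) at age {age}")
    if state is State.HEALTHY:
        exits = p_nonfatal + p_ihd_death + p_cancer + p_other
        if exits >= 1:
            raise HazardOverflowError(
                f"exit probabilities from HEALTHY sum to {exits} >= 1 at age {age}"
            )
        row[State.NONFATAL_IHD] = p_nonfatal
    else:  # NONFATAL_IHD
        exits = p_ihd_death + p_cancer + p_other
        if exits >= 1:
            raise HazardOverflowError(
                f"exit probabilities from NONFATAL_IHD sum to {exits} >= 1 at age {age}"
            )
    row[State.IHD_DEATH] = p_ihd_death
    row[State.CANCER_DEATH] = p_cancer
    row[State.OTHER_DEATH] = p_other
    row[state] = 1.0 - exits
    return row


def _transition_matrix(hazards: HazardSet, t: int) -> np.ndarray:
    age = int(hazards.start_age + t)
    args = (
        float(hazards.p_ihd_death[t]),
        float(hazards.p_nonfatal[t]),
        float(hazards.p_cancer[t]),
        float(hazards.p_other[t]),
    )
    return np.vstack([build_transition_row(State(s), age, *args) for s in range(N_STATES)])


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy at each cycle boundary plus per-cycle incident flows."""

    start_age: int
    occupancy: np.ndarray  # (n_cycles + 1, 5)
    new_nonfatal: np.ndarray
    new_ihd_death: np.ndarray
    new_cancer_death: np.ndarray
    new_other_death: np.ndarray

    @property
    def n_cycles(self) -> int:
        return int(self.occupancy.shape[0]) - 1

    @property
    def cum_ihd_death(self) -> float:
        return float(self.occupancy[-1, State.IHD_DEATH])

    @property
    def cum_total_ihd(self) -> float:
        """Cumulative IHD burden: deaths plus incident non-fatal events."""
        return self.cum_ihd_death + float(self.new_nonfatal.sum())

    @property
    def cum_cancer_death(self) -> float:
        return float(self.occupancy[-1, State.CANCER_DEATH])

    def cancer_death_by_cycle(self, cycle: int) -> float:
        return float(self.occupancy[cycle, State.CANCER_DEATH])

    def validate(self, atol: float = 1e-12) -> None:
        occ = self.occupancy
        if np.any(occ < -atol):
            raise AssertionError("negative occupancy")
        sums = occ.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > atol):
            raise AssertionError("occupancy does not sum to 1")
        for s in ABSORBING_STATES:
            if np.any(np.diff(occ[:, s]) < -atol):
                raise AssertionError(f"absorbing occupancy of {s.name} decreased")
        for s, flow in (
            (State.IHD_DEATH, self.new_ihd_death),
            (State.CANCER_DEATH, self.new_cancer_death),
            (State.OTHER_DEATH, self.new_other_death),
        ):
            if abs(flow.sum() - occ[-1, s]) > 1e-9:
                raise AssertionError(f"flows into {s.name} do not match final occupancy")

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cycles
        pad = lambda a: np.concatenate([[np.nan], a])  # noqa: E731 - flows start at cycle 1
        return pd.DataFrame(
            {
                "cycle": np.arange(n + 1),
                "age": self.start_age + np.arange(n + 1),
                **{s.name.lower(): self.occupancy[:, s] for s in State},
                "new_nonfatal": pad(self.new_nonfatal),
                "new_ihd_death": pad(self.new_ihd_death),
                "new_cancer_death": pad(self.new_cancer_death),
                "new_other_death": pad(self.new_other_death),
            }
        )


def simulate_cohort(hazards: HazardSet) -> CohortTrace:
    """Run the cohort trace: 100% HEALTHY at t=0, one transition per cycle."""
    n = hazards.n_cycles
    occ = np.zeros((n + 1, N_STATES))
    occ[0, State.HEALTHY] = 1.0
    new_nf = np.zeros(n)
    new_id = np.zeros(n)
    new_cd = np.zeros(n)
    new_od = np.zeros(n)
    for t in range(n):
        P = _transition_matrix(hazards, t)
        h, nf = occ[t, State.HEALTHY], occ[t, State.NONFATAL_IHD]
        new_nf[t] = h * P[State.HEALTHY, State.NONFATAL_IHD]
        new_id[t] = h * P[State.HEALTHY, State.IHD_DEATH] + nf * P[State.NONFATAL_IHD, State.IHD_DEATH]
        new_cd[t] = h * P[State.HEALTHY, State.CANCER_DEATH] + nf * P[State.NONFATAL_IHD, State.CANCER_DEATH]
        new_od[t] = h * P[State.HEALTHY, State.OTHER_DEATH] + nf * P[State.NONFATAL_IHD, State.OTHER_DEATH]
        occ[t + 1] = occ[t] @ P
    return CohortTrace(hazards.start_age, occ, new_nf, new_id, new_cd, new_od)


# ---------------------------------------------------------------------------
# Discounted accumulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccumulationCoefficients:
    """Econ-parameter-free sums extracted from a trace.

    Discounted QALYs and costs are linear in the utilities and unit costs, so
    the trace collapses to five sufficient statistics: discounted healthy
    years ``healthy_years``, discounted non-fatal-IHD years ``nonfatal_years``,
    discounted incident non-fatal flow ``pci_events``, and undiscounted
    alive years ``life_years``.  Both the deterministic accumulator and the
    probabilistic sensitivity analysis evaluate through this object, so they
    cannot drift apart.
    """

    healthy_years: float
    nonfatal_years: float
    pci_events: float
    life_years: float

    def qaly(self, u_healthy, u_nonfatal):
        return u_healthy * self.healthy_years + u_nonfatal * self.nonfatal_years

    def cost(self, one_off, cost_pci, cost_ihd_annual, cost_followup_annual):
        return (
            one_off
            + cost_pci * self.pci_events
            + cost_ihd_annual * self.nonfatal_years
            + cost_followup_annual * (self.healthy_years + self.nonfatal_years)
        )


def _cycle_weights(n: int, discount_rate: float, half_cycle_correction: bool) -> np.ndarray:
    t = np.arange(1, n + 1, dtype=float)
    exponent = t - 0.5 if half_cycle_correction else t
    return (1.0 + discount_rate) ** -exponent


def _effective_occupancy(series: np.ndarray, half_cycle_correction: bool) -> np.ndarray:
    """Per-cycle state membership: trapezoid of the boundary occupancies."""
    if half_cycle_correction:
        return 0.5 * (series[:-1] + series[1:])
    return series[1:]


def accumulation_coefficients(
    trace: CohortTrace, discount_rate: float, settings: ModelSettings
) -> AccumulationCoefficients:
    n = trace.n_cycles
    hcc = settings.half_cycle_correction
    w = _cycle_weights(n, discount_rate, hcc)
    eff_h = _effective_occupancy(trace.occupancy[:, State.HEALTHY], hcc)
    eff_n = _effective_occupancy(trace.occupancy[:, State.NONFATAL_IHD], hcc)
    return AccumulationCoefficients(
        healthy_years=float(w @ eff_h),
        nonfatal_years=float(w @ eff_n),
        pci_events=float(w @ trace.new_nonfatal),
        life_years=float(eff_h.sum() + eff_n.sum()),
    )


@dataclass(frozen=True)
class OutcomeSummary:
    """Discounted cost/QALY of one strategy plus horizon cumulative incidences."""

    discounted_cost: float
    discounted_qaly: float
    life_years: float
    cum_ihd_death: float
    cum_total_ihd: float
    cum_cancer_death: float

    def to_dict(self) -> dict[str, float]:
        return {
            "discounted_cost": self.discounted_cost,
            "discounted_qaly": self.discounted_qaly,
            "life_years": self.life_years,
            "cum_ihd_death": self.cum_ihd_death,
            "cum_total_ihd": self.cum_total_ihd,
            "cum_cancer_death": self.cum_cancer_death,
        }


def accumulate(
    trace: CohortTrace,
    econ: "EconParams",
    settings: ModelSettings,
    one_off_cost: float,
) -> OutcomeSummary:
    """Discounted QALYs and costs for one strategy.

    The one-off radiotherapy cost is booked at t=0 undiscounted; the PCI cost
    attaches to the incident non-fatal flow in its cycle; annual IHD care and
    follow-up accrue with the same per-cycle weights as the QALYs (mid-cycle
    discounting when half-cycle correction is on).
    """
    coeffs = accumulation_coefficients(trace, econ.discount_rate, settings)
    return OutcomeSummary(
        discounted_cost=float(
            coeffs.cost(one_off_cost, econ.cost_pci, econ.cost_ihd_annual, econ.cost_followup_annual)
        ),
        discounted_qaly=float(coeffs.qaly(econ.u_healthy, econ.u_nonfatal)),
        life_years=coeffs.life_years,
        cum_ihd_death=trace.cum_ihd_death,
        cum_total_ihd=trace.cum_total_ihd,
        cum_cancer_death=trace.cum_cancer_death,
    )


# ---------------------------------------------------------------------------
# Patient-level microsimulation oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrosimResult:
    summary: OutcomeSummary
    se: dict[str, float]
    occupancy: np.ndarray  # empirical (n_cycles + 1, 5)


def microsim_oracle(
    hazards: HazardSet,
    econ: "EconParams",
    settings: ModelSettings,
    one_off_cost: float,
    n_patients: int,
    seed: int,
) -> MicrosimResult:
    """Monte-Carlo validation of the cohort algebra.

    Each patient follows categorical draws from the same transition rows the
    cohort trace uses; means of occupancy, cost and QALY converge to the
    cohort values at rate 1/sqrt(n).  Standard errors use the sample SD.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    n_cycles = hazards.n_cycles
    states = np.empty((n_patients, n_cycles + 1), dtype=np.int8)
    states[:, 0] = State.HEALTHY
    for t in range(n_cycles):
        # validate hazards through the same row constructor the cohort uses
        _transition_matrix(hazards, t)
        p_id = hazards.p_ihd_death[t]
        p_nf = hazards.p_nonfatal[t]
        p_cd = hazards.p_cancer[t]
        p_od = hazards.p_other[t]
        u = rng.random(n_patients)
        cur = states[:, t]
        nxt = cur.copy()
        healthy = cur == State.HEALTHY
        # thresholds in state-index order: NONFATAL, IHD_DEATH, CANCER, OTHER
        nxt[healthy & (u < p_nf)] = State.NONFATAL_IHD
        nxt[healthy & (u >= p_nf) & (u < p_nf + p_id)] = State.IHD_DEATH
        nxt[healthy & (u >= p_nf + p_id) & (u < p_nf + p_id + p_cd)] = State.CANCER_DEATH
        nxt[healthy & (u >= p_nf + p_id + p_cd) & (u < p_nf + p_id + p_cd + p_od)] = State.OTHER_DEATH
        nonfatal = cur == State.NONFATAL_IHD
        nxt[nonfatal & (u < p_id)] = State.IHD_DEATH
        nxt[nonfatal & (u >= p_id) & (u < p_id + p_cd)] = State.CANCER_DEATH
        nxt[nonfatal & (u >= p_id + p_cd) & (u < p_id + p_cd + p_od)] = State.OTHER_DEATH
        states[:, t + 1] = nxt

    hcc = settings.half_cycle_correction
    w = _cycle_weights(n_cycles, econ.discount_rate, hcc)
    h_ind = (states == State.HEALTHY).astype(float)
    n_ind = (states == State.NONFATAL_IHD).astype(float)
    eff_h = 0.5 * (h_ind[:, :-1] + h_ind[:, 1:]) if hcc else h_ind[:, 1:]
    eff_n = 0.5 * (n_ind[:, :-1] + n_ind[:, 1:]) if hcc else n_ind[:, 1:]
    new_nf = ((states[:, :-1] == State.HEALTHY) & (states[:, 1:] == State.NONFATAL_IHD)).astype(float)

    qaly_i = econ.u_healthy * (eff_h @ w) + econ.u_nonfatal * (eff_n @ w)
    cost_i = (
        one_off_cost
        + econ.cost_pci * (new_nf @ w)
        + econ.cost_ihd_annual * (eff_n @ w)
        + econ.cost_followup_annual * ((eff_h + eff_n) @ w)
    )
    ly_i = eff_h.sum(axis=1) + eff_n.sum(axis=1)
    ihd_death_i = (states[:, -1] == State.IHD_DEATH).astype(float)
    total_ihd_i = ihd_death_i + new_nf.sum(axis=1)
    cancer_i = (states[:, -1] == State.CANCER_DEATH).astype(float)

    def mean_se(x: np.ndarray) -> tuple[float, float]:
        sd = float(x.std(ddof=1)) if n_patients > 1 else 0.0
        return float(x.mean()), sd / np.sqrt(n_patients)

    stats = {
        "discounted_cost": mean_se(cost_i),
        "discounted_qaly": mean_se(qaly_i),
        "life_years": mean_se(ly_i),
        "cum_ihd_death": mean_se(ihd_death_i),
        "cum_total_ihd": mean_se(total_ihd_i),
        "cum_cancer_death": mean_se(cancer_i),
    }
    summary = OutcomeSummary(**{k: v[0] for k, v in stats.items()})
    se = {k: v[1] for k, v in stats.items()}
    occupancy = np.stack([(states == s).mean(axis=0) for s in State], axis=1)
    return MicrosimResult(summary=summary, se=se, occupancy=occupancy)
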