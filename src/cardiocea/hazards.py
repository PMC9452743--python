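"""Per-cycle hazard construction and calibration to cumulative targets.

The baseline annual IHD-death probability q(a) is scaled by three factors:

* a dose-response relative risk RR = 1 + 0.074 * MHD (a 7.4% excess relative
  risk per Gy of mean heart dose, from the population-based dose-response
  for major coronary events after breast irradiation);
* a preexisting-risk multiplier m for cardiac-risk-factor burden, the
  no-risk-factor curve acting as the base;
* a calibration scalar s_death pinning the cohort's cumulative IHD-death
  incidence at the horizon to a stated target.

Non-fatal IHD incidence is tied to the scaled death hazard through an
age-banded ratio with its own calibration scalar s_nonfatal, pinned to the
cumulative *total* IHD target (deaths + incident non-fatal events).

Calibration runs the full cohort model inside a bracketed 1-D root search
per scalar; the two searches decouple because the per-cycle death hazards
are identical from the HEALTHY and NONFATAL_IHD states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .curves import LifeTable, NonfatalRatioSchedule, RiskCurve
from .markov import HazardSet, simulate_cohort

__all__ = [
    "PatientScenario",
    "CancerMortalityParams",
    "CalibrationTargets",
    "CalibrationResult",
    "CalibrationError",
    "DEFAULT_ERR_PER_GY",
    "PROB_CLAMP",
    "dose_risk_multiplier",
    "annual_prob_from_cum",
    "scaled_annual_ihd_death",
    "annual_nonfatal_ihd",
    "cycle_hazards",
    "calibrate",
]

DEFAULT_ERR_PER_GY = 0.074
#: Upper clamp applied to any scaled annual probability.
PROB_CLAMP = 0.999
SCALING_MODES = ("linear_prob", "hazard_rate")


class CalibrationError(RuntimeError):
    """No calibration scalar in the search bracket reaches the target."""


@dataclass(frozen=True)
class PatientScenario:
    """One comparison: a patient age, the two strategy doses, and risk level."""

    start_age: int
    photon_mhd: float = 5.0
    proton_mhd: float = 0.5
    preexisting_multiplier: float = 1.0
    horizon_age: int = 80
    enforce_dose_bounds: bool = True

    def __post_init__(self) -> None:
        if self.start_age >= self.horizon_age:
            raise ValueError("start_age must be below horizon_age")
        if self.preexisting_multiplier < 0:
            raise ValueError("preexisting_multiplier must be nonnegative")
        if self.enforce_dose_bounds and not (
            0 <= self.proton_mhd <= self.photon_mhd <= 16
        ):
            raise ValueError(
                "expected 0 <= proton_mhd <= photon_mhd <= 16 Gy "
                "(set enforce_dose_bounds=False to override)"
            )

    @property
    def n_cycles(self) -> int:
        return self.horizon_age - self.start_age


@dataclass(frozen=True)
class CancerMortalityParams:
    """Background cancer mortality: a cumulative rate over an initial window."""

    five_year_cum: float = 0.06
    window_years: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.five_year_cum < 1:
            raise ValueError("five_year_cum must lie in [0, 1)")
        if self.window_years < 1:
            raise ValueError("window_years must be >= 1")

    @property
    def annual_prob(self) -> float:
        return annual_prob_from_cum(self.five_year_cum, self.window_years)


@dataclass(frozen=True)
class CalibrationTargets:
    """Cumulative incidences at the horizon the calibrated model must hit."""

    cum_ihd_death_to_horizon: float
    cum_total_ihd_to_horizon: float
    strategy_mhd: float

    def __post_init__(self) -> None:
        d, t = self.cum_ihd_death_to_horizon, self.cum_total_ihd_to_horizon
        if not (0 < d < 1 and 0 < t < 1):
            raise ValueError("cumulative targets must lie in (0, 1)")
        if t < d:
            raise ValueError("total IHD target cannot be below the IHD-death target")
        if self.strategy_mhd < 0:
            raise ValueError("strategy_mhd must be nonnegative")


@dataclass(frozen=True)
class CalibrationResult:
    s_death: float
    s_nonfatal: float
    achieved_death: float
    achieved_total: float
    iterations: int


def dose_risk_multiplier(mhd: float, err_per_gy: float = DEFAULT_ERR_PER_GY) -> float:
    """Linear dose-response relative risk RR = 1 + err_per_gy * MHD."""
    if mhd < 0:
        raise ValueError("mean heart dose must be nonnegative")
    return 1.0 + err_per_gy * mhd


def annual_prob_from_cum(cum: float, years: int) -> float:
    """Constant annual probability with cumulative incidence ``cum`` over ``years``."""
    if not 0 <= cum < 1:
        raise ValueError("cumulative probability must lie in [0, 1)")
    if years < 1:
        raise ValueError("years must be >= 1")
    return 1.0 - (1.0 - cum) ** (1.0 / years)


def scaled_annual_ihd_death(q, m=1.0, rr=1.0, s_death=1.0, scaling_mode="linear_prob"):
    """Annual IHD-death probability after risk-multiplier, dose and calibration scaling.

    ``linear_prob`` multiplies the annual probability directly (the default;
    the dose-response is stated as linear in risk); ``hazard_rate`` applies
    the combined factor on the hazard-rate scale, 1 - (1-q)**(m*rr*s).  Both
    clamp at 0.999.  Accepts scalars or numpy arrays.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or m < 0 or rr < 0 or s_death < 0:
        raise ValueError("inputs must be nonnegative")
    factor = m * rr * s_death
    if scaling_mode == "linear_prob":
        out = factor * q
    elif scaling_mode == "hazard_rate":
        out = 1.0 - (1.0 - q) ** factor
    else:
        raise ValueError(f"unknown scaling_mode {scaling_mode!r}; expected one of {SCALING_MODES}")
    out = np.minimum(out, PROB_CLAMP)
    return float(out) if out.ndim == 0 else out


def annual_nonfatal_ihd(q_death_scaled, age, schedule: NonfatalRatioSchedule, s_nonfatal=1.0):
    """Annual non-fatal IHD probability: age-banded ratio times the scaled death hazard."""
    q = np.asarray(q_death_scaled, dtype=float)
    if np.any(q < 0) or s_nonfatal < 0:
        raise ValueError("inputs must be nonnegative")
    ratio = schedule.ratio_at(age)
    out = np.minimum(ratio * s_nonfatal * q, PROB_CLAMP)
    return float(out) if out.ndim == 0 else out


def cycle_hazards(
    curve: RiskCurve,
    life: LifeTable,
    cancer: CancerMortalityParams,
    schedule: NonfatalRatioSchedule,
    scenario: PatientScenario,
    mhd: float,
    s_death: float = 1.0,
    s_nonfatal: float = 1.0,
    *,
    err_per_gy: float = DEFAULT_ERR_PER_GY,
    scaling_mode: str = "linear_prob",
    subtract_ihd_from_other: bool = False,
) -> HazardSet:
    """Assemble the per-cycle transition probabilities for one strategy arm."""
    start, horizon = scenario.start_age, scenario.horizon_age
    q_base = curve.probs_between(start, horizon)
    rr = dose_risk_multiplier(mhd, err_per_gy)
    m = scenario.preexisting_multiplier
    p_id = scaled_annual_ihd_death(q_base, m, rr, s_death, scaling_mode)
    p_nf = np.array(
        [
            annual_nonfatal_ihd(p_id[i], start + i, schedule, s_nonfatal)
            for i in range(horizon - start)
        ]
    )
    p_ca = np.where(np.arange(horizon - start) < cancer.window_years, cancer.annual_prob, 0.0)
    p_ot = life.probs_between(start, horizon)
    if subtract_ihd_from_other:
        p_ot = np.maximum(p_ot - q_base, 0.0)
    return HazardSet(start, p_id, p_nf, p_ca, p_ot)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

_BRACKET_LIMITS = (1e-6, 1e3)


def _bracketed_root(objective, target: float, what: str, tol: float) -> tuple[float, int]:
    """Root of objective(s) = target for an increasing objective on s > 0."""
    evals = 0

    def f(s: float) -> float:
        nonlocal evals
        evals += 1
        return objective(s) - target

    lo, hi_limit = _BRACKET_LIMITS
    f_lo = f(lo)
    if f_lo > 0:
        raise CalibrationError(
            f"{what}: target {target} below the model floor at scalar {lo}"
        )
    hi = 1.0
    f_hi = f(hi)
    while f_hi < 0 and hi < hi_limit:
        hi = min(hi * 4.0, hi_limit)
        try:
            f_hi = f(hi)
        except Exception as exc:  # hazard overflow: bracket has left feasibility
            raise CalibrationError(
                f"{what}: target {target} infeasible (hazards overflow before "
                f"reaching it; scalar {hi})"
            ) from exc
    if f_hi < 0:
        raise CalibrationError(
            f"{what}: target {target} unreachable within scalar bracket "
            f"[{lo}, {hi_limit}]"
        )
    # monotonicity of the objective across the bracket, asserted before the search
    mid = np.sqrt(lo * hi)
    f_mid = f(mid)
    if not (f_lo - 1e-12 <= f_mid <= f_hi + 1e-12):
        raise CalibrationError(f"{what}: objective is not monotone on [{lo}, {hi}]")
    root, res = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200, full_output=True)
    if abs(f(root)) >= tol:
        raise CalibrationError(
            f"{what}: converged scalar {root} misses target by {f(root):.3e} (tol {tol})"
        )
    return float(root), evals + res.iterations


def calibrate(
    curve: RiskCurve,
    life: LifeTable,
    cancer: CancerMortalityParams,
    schedule: NonfatalRatioSchedule,
    scenario: PatientScenario,
    targets: CalibrationTargets,
    *,
    err_per_gy: float = DEFAULT_ERR_PER_GY,
    scaling_mode: str = "linear_prob",
    subtract_ihd_from_other: bool = False,
    tol: float = 1e-9,
) -> CalibrationResult:
    """Two sequential 1-D root searches pinning cumulative incidences.

    First s_death is solved so the cohort's cumulative IHD-death occupancy at
    the horizon equals the death target; then, holding s_death, s_nonfatal is
    solved so deaths plus incident non-fatal events equal the total target.
    Calibration runs at the dose ``targets.strategy_mhd`` with the scenario's
    risk multiplier in place, so the scalars absorb everything else.
    """

    def run(s_death: float, s_nonfatal: float):
        hz = cycle_hazards(
            curve,
            life,
            cancer,
            schedule,
            scenario,
            targets.strategy_mhd,
            s_death,
            s_nonfatal,
            err_per_gy=err_per_gy,
            scaling_mode=scaling_mode,
            subtract_ihd_from_other=subtract_ihd_from_other,
        )
        return simulate_cohort(hz)

    s_death, it1 = _bracketed_root(
        lambda s: run(s, 0.0).cum_ihd_death,
        targets.cum_ihd_death_to_horizon,
        "IHD-death calibration",
        tol,
    )
    achieved_death = run(s_death, 0.0).cum_ihd_death
    if targets.cum_total_ihd_to_horizon < achieved_death - tol:
        raise CalibrationError(
            "total-IHD target lies below the calibrated death incidence"
        )
    if targets.cum_total_ihd_to_horizon <= achieved_death + tol:
        # degenerate: no non-fatal events needed
        return CalibrationResult(
            s_death=s_death,
            s_nonfatal=0.0,
            achieved_death=achieved_death,
            achieved_total=run(s_death, 0.0).cum_total_ihd,
            iterations=it1,
        )
    s_nonfatal, it2 = _bracketed_root(
        lambda s: run(s_death, s).cum_total_ihd,
        targets.cum_total_ihd_to_horizon,
        "total-IHD calibration",
        tol,
    )
    achieved_total = run(s_death, s_nonfatal).cum_total_ihd
    return CalibrationResult(
        s_death=s_death,
        s_nonfatal=s_nonfatal,
        achieved_death=achieved_death,
        achieved_total=achieved_total,
        iterations=it1 + it2,
    )
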