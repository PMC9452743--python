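"""Minimum cost-effective photon dose thresholds and risk-stratified grids.

For a patient at a given age and preexisting cardiac risk level, protons
become cost-effective once the photon mean heart dose (MHD) they would
otherwise receive is high enough.  The minimum such dose — the smallest
integer MHD in [1, 16] Gy at which the proton-vs-photon net monetary benefit
at the chosen willingness-to-pay turns nonnegative — is found by a root
search on the continuous dose axis (the benefit is monotone increasing in
dose, which is asserted) and then ceiled to the reported integer grid.

Grids cross ages x risk multipliers x proton costs x WTP thresholds; each
cell is categorised green (threshold <= 5 Gy, the clinically common photon
dose range), yellow (6-16 Gy) or gray (not cost-effective within 16 Gy).
A named cardiac-risk-factor stratum joins the "cost-effective group" when
its threshold is <= 5 Gy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.optimize import brentq

from .curves import StrataTable, strata_multiplier
from .hazards import PatientScenario
from .model import DEFAULT_WTPS, DecisionModel

__all__ = [
    "ThresholdQuery",
    "ThresholdGrid",
    "MonotonicityError",
    "threshold_mhd",
    "integer_scan",
    "build_grid",
    "crf_group_decision",
    "categorize",
    "implied_risk_ratio",
    "DEFAULT_PROTON_COSTS",
]

DEFAULT_PROTON_COSTS = (50_000.0, 40_000.0, 30_000.0, 20_000.0)
DEFAULT_AGES = (40, 50, 60)
DEFAULT_MULTIPLIERS = tuple(range(1, 13))


class MonotonicityError(RuntimeError):
    """Net monetary benefit is not increasing across the dose bracket."""


@dataclass(frozen=True)
class ThresholdQuery:
    start_age: int
    preexisting_multiplier: float
    proton_cost: float
    wtp: float
    mhd_range: tuple[float, float] = (1.0, 16.0)

    def __post_init__(self) -> None:
        if self.wtp <= 0:
            raise ValueError("wtp must be positive")
        lo, hi = self.mhd_range
        if not 0 <= lo < hi <= 16:
            raise ValueError("mhd_range must lie within [0, 16]")


def _nmb(model: DecisionModel, query: ThresholdQuery, mhd: float) -> float:
    scenario = PatientScenario(
        start_age=query.start_age,
        photon_mhd=mhd,
        preexisting_multiplier=query.preexisting_multiplier,
    )
    econ = model.econ.with_(cost_proton=query.proton_cost)
    proton, photon, _ = model.compare(scenario, econ=econ, wtps=(query.wtp,))
    d_qaly = proton.discounted_qaly - photon.discounted_qaly
    d_cost = proton.discounted_cost - photon.discounted_cost
    return query.wtp * d_qaly - d_cost


def threshold_mhd(model: DecisionModel, query: ThresholdQuery) -> int | None:
    """Smallest integer photon MHD at which protons are cost-effective.

    Root-finds the continuous net-monetary-benefit crossing on
    ``query.mhd_range`` and ceils it to the integer grid; returns None when
    even the top of the range is not cost-effective.  Integer-grid agreement
    with an exhaustive scan is enforced by a local verification step.
    """
    lo, hi = query.mhd_range
    f_lo = _nmb(model, query, lo)
    f_hi = _nmb(model, query, hi)
    if f_hi < f_lo - 1e-9:
        raise MonotonicityError(
            f"net monetary benefit decreases from {f_lo} at {lo} Gy to {f_hi} at {hi} Gy"
        )
    if f_hi < 0:
        return None
    int_lo, int_hi = math.ceil(lo), math.floor(hi)
    if f_lo >= 0:
        return int_lo
    root = brentq(lambda x: _nmb(model, query, x), lo, hi, xtol=1e-6)
    cand = max(int_lo, math.ceil(root - 1e-9))
    while cand <= int_hi and _nmb(model, query, cand) < 0:
        cand += 1
    while cand - 1 >= int_lo and _nmb(model, query, cand - 1) >= 0:
        cand -= 1
    return cand if cand <= int_hi else None


def integer_scan(model: DecisionModel, query: ThresholdQuery) -> int | None:
    """Brute-force oracle: first integer dose in the range with NMB >= 0."""
    lo, hi = math.ceil(query.mhd_range[0]), math.floor(query.mhd_range[1])
    for mhd in range(lo, hi + 1):
        if _nmb(model, query, float(mhd)) >= 0:
            return mhd
    return None


def categorize(threshold: int | None) -> str:
    """Fig-style colour rule: green <= 5 Gy, yellow 6-16 Gy, gray = never."""
    if threshold is None:
        return "gray"
    return "green" if threshold <= 5 else "yellow"


def implied_risk_ratio(model: DecisionModel, start_age: int, multiplier: float) -> float:
    """Lifetime-risk ratio implied by a hazard multiplier.

    The risk axis scales annual hazards; because cumulative incidence is
    sub-linear in the hazard, the implied ratio of lifetime total-IHD risk
    (vs. the same patient at multiplier 1) is reported alongside so grids can
    be read on either axis.
    """
    def cum(m: float) -> float:
        scenario = PatientScenario(
            start_age=start_age, photon_mhd=0.5, proton_mhd=0.5, preexisting_multiplier=m
        )
        return model.trace(scenario, "proton").cum_total_ihd

    return cum(multiplier) / cum(1.0)


@dataclass(frozen=True)
class ThresholdGrid:
    """Threshold and colour category per (age, multiplier, proton cost, WTP)."""

    cells: dict[tuple[int, float, float, float], tuple[int | None, str]]
    ages: tuple[int, ...]
    multipliers: tuple[float, ...]
    proton_costs: tuple[float, ...]
    wtps: tuple[float, ...]
    implied_ratios: dict[tuple[int, float], float]

    def threshold(self, age: int, multiplier: float, proton_cost: float, wtp: float) -> int | None:
        return self.cells[(age, multiplier, proton_cost, wtp)][0]

    def category(self, age: int, multiplier: float, proton_cost: float, wtp: float) -> str:
        return self.cells[(age, multiplier, proton_cost, wtp)][1]

    def __len__(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (age, m, cost, wtp), (thr, cat) in self.cells.items():
            rows.append(
                {
                    "age": age,
                    "risk_multiplier": m,
                    "implied_lifetime_risk_ratio": self.implied_ratios[(age, m)],
                    "proton_cost": cost,
                    "wtp": wtp,
                    "threshold_gy": thr,
                    "category": cat,
                }
            )
        return pd.DataFrame(rows)


def build_grid(
    model: DecisionModel,
    ages: tuple[int, ...] = DEFAULT_AGES,
    multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS,
    proton_costs: tuple[float, ...] = DEFAULT_PROTON_COSTS,
    wtps: tuple[float, ...] = DEFAULT_WTPS,
) -> ThresholdGrid:
    """Full cross-product of threshold queries.

    The model must be calibrated in zero-dose mode so one calibration serves
    every age, dose and multiplier.
    """
    cells = {}
    implied = {}
    for age in ages:
        for m in multipliers:
            implied[(age, float(m))] = implied_risk_ratio(model, age, float(m))
            for cost in proton_costs:
                for wtp in wtps:
                    q = ThresholdQuery(age, float(m), float(cost), float(wtp))
                    thr = threshold_mhd(model, q)
                    cells[(age, float(m), float(cost), float(wtp))] = (thr, categorize(thr))
    return ThresholdGrid(
        cells=cells,
        ages=tuple(ages),
        multipliers=tuple(float(m) for m in multipliers),
        proton_costs=tuple(float(c) for c in proton_costs),
        wtps=tuple(float(w) for w in wtps),
        implied_ratios=implied,
    )


def crf_group_decision(
    model: DecisionModel,
    strata: StrataTable | None = None,
    ages: tuple[int, ...] = DEFAULT_AGES,
    proton_costs: tuple[float, ...] = DEFAULT_PROTON_COSTS,
    wtps: tuple[float, ...] = DEFAULT_WTPS,
    max_group_mhd: int = 5,
) -> pd.DataFrame:
    """Cost-effective-group membership per named CRF stratum.

    Each stratum maps to a hazard multiplier via its lifetime risk relative
    to the reference (no-risk-factor) stratum at the same index age; the
    stratum joins the group when the minimum cost-effective photon MHD is
    <= ``max_group_mhd`` Gy (boundary inclusive).
    """
    strata = strata if strata is not None else model.strata
    if strata is None:
        raise ValueError("no strata table available")
    rows = []
    for age in ages:
        for stratum in strata.strata(age):
            m = strata_multiplier(strata, stratum, age)
            for cost in proton_costs:
                for wtp in wtps:
                    q = ThresholdQuery(age, m, float(cost), float(wtp))
                    thr = threshold_mhd(model, q)
                    rows.append(
                        {
                            "age": age,
                            "stratum": stratum,
                            "risk_multiplier": m,
                            "proton_cost": float(cost),
                            "wtp": float(wtp),
                            "threshold_gy": thr,
                            "cost_effective_group": thr is not None and thr <= max_group_mhd,
                        }
                    )
    return pd.DataFrame(rows)
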