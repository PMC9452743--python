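"""Cost-effectiveness analytics: ICER, probabilistic and one-way sensitivity.

The incremental cost-effectiveness ratio compares the proton strategy with
the photon strategy: ICER = (C_proton - C_photon) / (E_proton - E_photon) in
dollars per quality-adjusted life-year.  Decisions at a willingness-to-pay
threshold lambda use the net-monetary-benefit rule lambda*dE - dC >= 0, which
handles every quadrant of the cost-effectiveness plane (including dominance)
without dividing by a small dE.

The probabilistic sensitivity analysis resamples every unit cost from a
uniform distribution and every utility from a beta distribution
(method-of-moments shapes), re-pricing the fixed cohort traces each
iteration; the one-way (tornado) analysis moves one parameter at a time to
the bounds of its 90% interval.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .markov import OutcomeSummary

if TYPE_CHECKING:
    from .hazards import PatientScenario
    from .model import DecisionModel

__all__ = [
    "EconParams",
    "CEAResult",
    "PSASettings",
    "PSAResult",
    "TornadoEntry",
    "icer",
    "run_psa",
    "tornado",
    "beta_shapes",
    "COST_PARAMS",
    "UTILITY_PARAMS",
]

COST_PARAMS = ("cost_proton", "cost_photon", "cost_pci", "cost_ihd_annual", "cost_followup_annual")
UTILITY_PARAMS = ("u_healthy", "u_nonfatal")


@dataclass(frozen=True)
class EconParams:
    """Unit costs ($), health-state utilities, and the annual discount rate."""

    cost_proton: float = 50_000.0
    cost_photon: float = 12_000.0
    cost_pci: float = 10_000.0
    cost_ihd_annual: float = 2_000.0
    cost_followup_annual: float = 1_000.0
    u_healthy: float = 0.95
    u_nonfatal: float = 0.695
    u_death: float = 0.0
    discount_rate: float = 0.03

    def __post_init__(self) -> None:
        for name in COST_PARAMS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in (*UTILITY_PARAMS, "u_death"):
            u = getattr(self, name)
            if not 0 <= u <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.u_death != 0:
            raise ValueError("u_death is fixed at 0")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be nonnegative")

    def with_(self, **overrides) -> "EconParams":
        return replace(self, **overrides)


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison (proton minus photon) with WTP verdicts."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str  # "icer" | "dominant" | "dominated" | "undefined" | "equivalent"
    cost_effective_at: dict[float, bool]

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "label": self.label,
            "cost_effective_at": {str(k): v for k, v in self.cost_effective_at.items()},
        }


def icer(
    proton: OutcomeSummary,
    photon: OutcomeSummary,
    wtps: tuple[float, ...] = (37_653.0, 50_000.0, 100_000.0),
) -> CEAResult:
    """Incremental cost-effectiveness of protons over photons.

    The ratio is reported when dE > 0; dominance labels follow standard CEA
    conventions.  Cost-effectiveness at each WTP uses net monetary benefit,
    so a dominant comparison is cost-effective at any threshold.
    """
    d_cost = proton.discounted_cost - photon.discounted_cost
    d_qaly = proton.discounted_qaly - photon.discounted_qaly
    if d_qaly > 0 and d_cost <= 0:
        value, label = None, "dominant"
    elif d_qaly < 0 and d_cost >= 0:
        value, label = None, "dominated"
    elif d_qaly == 0:
        value, label = (None, "equivalent") if d_cost == 0 else (None, "undefined")
    else:
        value, label = d_cost / d_qaly, "icer"
    verdicts = {float(w): bool(w * d_qaly - d_cost >= 0) for w in wtps}
    if label == "dominated":
        verdicts = {w: False for w in verdicts}
    return CEAResult(d_cost, d_qaly, value, label, verdicts)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSASettings:
    """Sampling plan: uniform costs (+/- a fraction), beta utilities (SD as a
    fraction of the mean).  The half-width fraction is configuration; 0.2875
    reproduces a proton-cost 90% interval of about (37,063; 62,938) around
    $50,000."""

    n_iterations: int = 50_000
    seed: int = 0
    cost_halfwidth_frac: float = 0.25
    utility_beta_se_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 <= self.cost_halfwidth_frac < 1:
            raise ValueError("cost_halfwidth_frac must lie in [0, 1)")
        if not 0 <= self.utility_beta_se_frac < 1:
            raise ValueError("utility_beta_se_frac must lie in [0, 1)")


def beta_shapes(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta shape parameters for a given mean and SD."""
    if not 0 < mean < 1:
        raise ValueError("beta mean must lie in (0, 1)")
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    if nu <= 0:
        raise ValueError(
            f"sd {sd} too large for a beta distribution with mean {mean}"
        )
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class PSAResult:
    samples: pd.DataFrame  # iteration, each sampled parameter, delta_cost, delta_qaly, icer
    param_ci: dict[str, tuple[float, float]]
    output_ci: dict[str, tuple[float, float]]
    base: CEAResult


def run_psa(
    model: "DecisionModel",
    scenario: "PatientScenario",
    settings: PSASettings,
    wtps: tuple[float, ...] = (37_653.0, 50_000.0, 100_000.0),
) -> PSAResult:
    """Joint cost/utility uncertainty analysis on fixed cohort traces.

    The traces (hence dE's occupancy basis and the event flows) do not depend
    on economic parameters, so each iteration re-prices the two fixed traces
    with freshly drawn costs and utilities.  90% intervals are the empirical
    5th/95th percentiles.  Identical seeds give identical tables.
    """
    rng = np.random.default_rng(settings.seed)
    n = settings.n_iterations
    econ = model.econ
    cp = model.coefficients(scenario, "proton")
    cph = model.coefficients(scenario, "photon")

    draws: dict[str, np.ndarray] = {}
    for name in COST_PARAMS:
        base = getattr(econ, name)
        w = settings.cost_halfwidth_frac * base
        draws[name] = rng.uniform(base - w, base + w, size=n) if w > 0 else np.full(n, base)
    for name in UTILITY_PARAMS:
        base = getattr(econ, name)
        sd = settings.utility_beta_se_frac * base
        if sd > 0:
            a, b = beta_shapes(base, sd)
            u = rng.beta(a, b, size=n)
            np.clip(u, 0.0, 1.0, out=u)  # beta respects [0,1]; clip is a safety net
        else:
            u = np.full(n, base)
        draws[name] = u

    d_qaly = cp.qaly(draws["u_healthy"], draws["u_nonfatal"]) - cph.qaly(
        draws["u_healthy"], draws["u_nonfatal"]
    )
    d_cost = cp.cost(
        draws["cost_proton"], draws["cost_pci"], draws["cost_ihd_annual"], draws["cost_followup_annual"]
    ) - cph.cost(
        draws["cost_photon"], draws["cost_pci"], draws["cost_ihd_annual"], draws["cost_followup_annual"]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = np.where(d_qaly != 0, d_cost / d_qaly, np.nan)

    samples = pd.DataFrame({"iteration": np.arange(n), **draws})
    samples["delta_cost"] = d_cost
    samples["delta_qaly"] = d_qaly
    samples["icer"] = icers

    def ci(x: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(x, 5)), float(np.percentile(x, 95)))

    param_ci = {name: ci(draws[name]) for name in (*COST_PARAMS, *UTILITY_PARAMS)}
    output_ci = {"delta_cost": ci(d_cost), "delta_qaly": ci(d_qaly), "icer": ci(icers)}
    _, _, base = model.compare(scenario, wtps=wtps)
    return PSAResult(samples=samples, param_ci=param_ci, output_ci=output_ci, base=base)


# ---------------------------------------------------------------------------
# Tornado (one-way) sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    span: float


def _raw_icer(model: "DecisionModel", scenario: "PatientScenario", econ: EconParams) -> float:
    proton, photon, _ = model.compare(scenario, econ=econ)
    return (proton.discounted_cost - photon.discounted_cost) / (
        proton.discounted_qaly - photon.discounted_qaly
    )


def tornado(
    model: "DecisionModel",
    scenario: "PatientScenario",
    param_cis: dict[str, tuple[float, float]],
) -> list[TornadoEntry]:
    """One-at-a-time ICER sensitivity over each parameter's interval.

    ``param_cis`` maps economic parameter names to (low, high) bounds —
    typically the PSA's empirical 90% intervals.  Entries come back sorted
    by descending ICER span.
    """
    valid = {f.name for f in fields(EconParams)}
    entries = []
    for name, (lo, hi) in param_cis.items():
        if name not in valid:
            raise KeyError(f"unknown economic parameter {name!r}")
        at_lo = _raw_icer(model, scenario, model.econ.with_(**{name: lo}))
        at_hi = _raw_icer(model, scenario, model.econ.with_(**{name: hi}))
        entries.append(
            TornadoEntry(name, lo, hi, at_lo, at_hi, span=abs(at_hi - at_lo))
        )
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])
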