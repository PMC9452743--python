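"""Model inputs: baseline IHD risk curves, life tables, and risk-factor strata.

The decision model runs on three tabular inputs:

* an age-indexed annual probability of death from ischemic heart disease
  (IHD) for a non-irradiated woman without cardiac risk factors — the
  hazard backbone every dose/risk scaling acts on;
* an all-cause female life table supplying the competing "other death"
  probability per attained age;
* a table of lifetime IHD risk (to age 80) by cardiac-risk-factor (CRF)
  stratum, used to translate a named stratum (e.g. "diabetes") into a
  multiplier on the no-CRF baseline hazard.

Each input can be read from a plain CSV or generated synthetically with a
controlled shape, so the full pipeline is testable without any external
download.  A fourth small input, the age-banded ratio of non-fatal to fatal
IHD lifetime risk, is a fixed schedule with a literature-derived default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CurveValidationError",
    "InfeasibleTargetError",
    "RiskCurve",
    "LifeTable",
    "StrataTable",
    "NonfatalRatioSchedule",
    "REFERENCE_STRATUM",
    "read_risk_curve",
    "read_life_table",
    "read_strata_table",
    "synth_risk_curve",
    "synth_life_table",
    "synth_strata_table",
    "strata_multiplier",
]


class CurveValidationError(ValueError):
    """An input table violates a structural invariant (gap, range, column)."""


class InfeasibleTargetError(ValueError):
    """A synthetic-curve cumulative target cannot be met with probabilities < 1."""


REFERENCE_STRATUM = "all-optimal"


def _check_contiguous(ages: np.ndarray, what: str) -> None:
    if ages.ndim != 1 or ages.size == 0:
        raise CurveValidationError(f"{what}: needs at least one row")
    diffs = np.diff(ages)
    if np.any(diffs != 1):
        i = int(np.argmax(diffs != 1))
        raise CurveValidationError(
            f"{what}: ages must be strictly increasing and contiguous; "
            f"gap between age {ages[i]} (row {i + 1}) and age {ages[i + 1]} (row {i + 2})"
        )


@dataclass(frozen=True)
class RiskCurve:
    """Annual baseline IHD-death probability per attained age.

    ``ages`` are contiguous integer years; ``probs[i]`` is the probability of
    dying from IHD during the year starting at ``ages[i]``, each in [0, 1).
    """

    ages: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != ages.shape:
            raise CurveValidationError("risk curve: ages and probs must align")
        _check_contiguous(ages, "risk curve")
        bad = (probs < 0) | (probs >= 1)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise CurveValidationError(
                f"risk curve: probability {probs[i]!r} out of [0, 1) at age {ages[i]} (row {i + 1})"
            )
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "probs", probs)

    def __len__(self) -> int:
        return int(self.ages.size)

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    @property
    def end_age(self) -> int:
        """One past the last covered age (curve covers [start_age, end_age))."""
        return int(self.ages[-1]) + 1

    def prob_at(self, age: int) -> float:
        if not self.start_age <= age < self.end_age:
            raise CurveValidationError(
                f"risk curve: age {age} outside covered range [{self.start_age}, {self.end_age})"
            )
        return float(self.probs[int(age) - self.start_age])

    def probs_between(self, start_age: int, end_age: int) -> np.ndarray:
        """Annual probabilities for attained ages ``start_age .. end_age - 1``."""
        if not (self.start_age <= start_age < end_age <= self.end_age):
            raise CurveValidationError(
                f"risk curve: [{start_age}, {end_age}) not within "
                f"[{self.start_age}, {self.end_age})"
            )
        lo = start_age - self.start_age
        return self.probs[lo : lo + (end_age - start_age)].copy()

    def cumulative_incidence(self, start_age: int, end_age: int) -> float:
        """Competing-risk-free cumulative incidence 1 - prod(1 - q) over [start, end)."""
        q = self.probs_between(start_age, end_age)
        return float(1.0 - np.prod(1.0 - q))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "annual_ihd_death_prob": self.probs})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RiskCurve):
            return NotImplemented
        return np.array_equal(self.ages, other.ages) and np.array_equal(self.probs, other.probs)


@dataclass(frozen=True)
class LifeTable:
    """All-cause annual death probability qx per attained age."""

    ages: np.ndarray
    qx: np.ndarray
    population_label: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if qx.shape != ages.shape:
            raise CurveValidationError("life table: ages and qx must align")
        _check_contiguous(ages, "life table")
        bad = (qx < 0) | (qx > 1)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise CurveValidationError(
                f"life table: qx {qx[i]!r} out of [0, 1] at age {ages[i]} (row {i + 1})"
            )
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    def __len__(self) -> int:
        return int(self.ages.size)

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    @property
    def end_age(self) -> int:
        return int(self.ages[-1]) + 1

    def prob_at(self, age: int) -> float:
        if not self.start_age <= age < self.end_age:
            raise CurveValidationError(
                f"life table: age {age} outside covered range [{self.start_age}, {self.end_age})"
            )
        return float(self.qx[int(age) - self.start_age])

    def probs_between(self, start_age: int, end_age: int) -> np.ndarray:
        if not (self.start_age <= start_age < end_age <= self.end_age):
            raise CurveValidationError(
                f"life table: [{start_age}, {end_age}) not within "
                f"[{self.start_age}, {self.end_age})"
            )
        lo = start_age - self.start_age
        return self.qx[lo : lo + (end_age - start_age)].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LifeTable):
            return NotImplemented
        return (
            np.array_equal(self.ages, other.ages)
            and np.array_equal(self.qx, other.qx)
            and self.population_label == other.population_label
        )


@dataclass(frozen=True)
class StrataTable:
    """Lifetime IHD risk (to age 80) by cardiac-risk-factor stratum.

    Every index age present must include a reference row (the all-optimal /
    no-CRF stratum) against which risk multipliers are formed.
    """

    table: pd.DataFrame  # columns: stratum, index_age, lifetime_risk
    reference_stratum: str = REFERENCE_STRATUM

    def __post_init__(self) -> None:
        required = {"stratum", "index_age", "lifetime_risk"}
        missing = required - set(self.table.columns)
        if missing:
            raise CurveValidationError(f"strata table: missing column(s) {sorted(missing)}")
        risks = self.table["lifetime_risk"].to_numpy(dtype=float)
        bad = (risks <= 0) | (risks >= 1)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise CurveValidationError(
                f"strata table: lifetime risk {risks[i]!r} out of (0, 1) at row {i + 1}"
            )
        for age in self.table["index_age"].unique():
            sub = self.table[self.table["index_age"] == age]
            if self.reference_stratum not in set(sub["stratum"]):
                raise CurveValidationError(
                    f"strata table: no reference stratum {self.reference_stratum!r} "
                    f"for index age {age}"
                )

    def index_ages(self) -> list[int]:
        return sorted(int(a) for a in self.table["index_age"].unique())

    def strata(self, index_age: int) -> list[str]:
        sub = self.table[self.table["index_age"] == index_age]
        return list(sub["stratum"])

    def lifetime_risk(self, stratum: str, index_age: int) -> float:
        sub = self.table[
            (self.table["index_age"] == index_age) & (self.table["stratum"] == stratum)
        ]
        if sub.empty:
            raise LookupError(
                f"strata table: no stratum {stratum!r} at index age {index_age}"
            )
        return float(sub["lifetime_risk"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def strata_multiplier(table: StrataTable, stratum: str, index_age: int) -> float:
    """Preexisting-risk multiplier m = lifetime risk of stratum / reference risk."""
    ref = table.lifetime_risk(table.reference_stratum, index_age)
    return table.lifetime_risk(stratum, index_age) / ref


@dataclass(frozen=True)
class NonfatalRatioSchedule:
    """Age-banded ratio of non-fatal IHD incidence to IHD death.

    Bands are half-open ``[lo, hi)`` intervals partitioning [0, inf).  The
    default schedule (5x below 50, 4x in the fifties, 2x in the sixties,
    1x from 70 on) reflects the declining survivability of ischemic events
    with age in the epidemiological source data.
    """

    bands: tuple[tuple[float, float, float], ...] = (
        (0.0, 50.0, 5.0),
        (50.0, 60.0, 4.0),
        (60.0, 70.0, 2.0),
        (70.0, math.inf, 1.0),
    )

    def __post_init__(self) -> None:
        lo0 = self.bands[0][0]
        if lo0 != 0.0:
            raise CurveValidationError("ratio schedule must start at age 0")
        prev_hi = lo0
        for lo, hi, ratio in self.bands:
            if lo != prev_hi or hi <= lo:
                raise CurveValidationError("ratio schedule bands must partition [0, inf)")
            if ratio <= 0:
                raise CurveValidationError("ratio schedule ratios must be positive")
            prev_hi = hi
        if prev_hi != math.inf:
            raise CurveValidationError("ratio schedule must extend to infinity")

    def ratio_at(self, age: float) -> float:
        for lo, hi, ratio in self.bands:
            if lo <= age < hi:
                return ratio
        raise LookupError(f"no ratio band covers age {age}")  # pragma: no cover

    def ratios_between(self, start_age: int, end_age: int) -> np.ndarray:
        return np.array([self.ratio_at(a) for a in range(start_age, end_age)])


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, columns: dict[str, str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise CurveValidationError(f"{what}: cannot read {path}: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise CurveValidationError(
            f"{what}: missing column(s) {sorted(missing)} in {path} "
            f"(found {list(df.columns)})"
        )
    for col, kind in columns.items():
        coerced = pd.to_numeric(df[col], errors="coerce") if kind != "str" else df[col]
        if kind != "str" and coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 1
            raise CurveValidationError(
                f"{what}: non-numeric value {df[col].iloc[row - 1]!r} "
                f"in column {col!r} at data row {row}"
            )
        df[col] = coerced
    return df


def read_risk_curve(path: str | Path) -> RiskCurve:
    """Read an (age, annual_ihd_death_prob) CSV into a validated RiskCurve."""
    df = _read_table(path, {"age": "int", "annual_ihd_death_prob": "float"}, "risk curve")
    return RiskCurve(df["age"].to_numpy(), df["annual_ihd_death_prob"].to_numpy())


def read_life_table(path: str | Path, population_label: str = "") -> LifeTable:
    """Read an (age, qx) CSV into a validated LifeTable."""
    df = _read_table(path, {"age": "int", "qx": "float"}, "life table")
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy(), population_label)


def read_strata_table(path: str | Path, reference_stratum: str = REFERENCE_STRATUM) -> StrataTable:
    """Read a (stratum, index_age, lifetime_risk) CSV into a StrataTable."""
    df = _read_table(
        path,
        {"stratum": "str", "index_age": "int", "lifetime_risk": "float"},
        "strata table",
    )
    df["index_age"] = df["index_age"].astype(int)
    return StrataTable(df[["stratum", "index_age", "lifetime_risk"]], reference_stratum)


# ---------------------------------------------------------------------------
# Synthetic generators
# ---------------------------------------------------------------------------

def synth_risk_curve(
    start_age: int,
    end_age: int,
    cum_death_target: float,
    doubling_per_decade: float = 2.0,
) -> RiskCurve:
    """Exponential-in-age annual IHD-death curve pinned to a cumulative target.

    The annual probability follows ``q(a) = k * d**((a - start_age)/10)`` with
    ``d = doubling_per_decade``; ``k`` is solved so that the competing-risk-free
    cumulative incidence ``1 - prod(1 - q)`` over [start_age, end_age) equals
    ``cum_death_target`` to within 1e-10.  ``d = 1`` gives a flat curve,
    ``d = 2`` the canonical doubling-per-decade shape of IHD mortality.
    Annual probabilities are capped at 0.999 (matching the hazard clamp used
    downstream), so targets requiring a near-certain annual event are
    rejected as infeasible.
    """
    if not 0 <= cum_death_target < 1:
        raise ValueError("cum_death_target must lie in [0, 1)")
    if not start_age < end_age <= 80:
        raise ValueError("need start_age < end_age <= 80")
    if doubling_per_decade <= 0:
        raise ValueError("doubling_per_decade must be positive")
    ages = np.arange(start_age, end_age)
    if cum_death_target == 0:
        return RiskCurve(ages, np.zeros(ages.size))
    w = doubling_per_decade ** ((ages - start_age) / 10.0)

    def cum(k: float) -> float:
        return 1.0 - float(np.prod(1.0 - k * w))

    k_max = 0.999 / float(w.max())
    if cum(k_max) < cum_death_target:
        raise InfeasibleTargetError(
            f"cumulative target {cum_death_target} unreachable: would require an "
            f"annual probability above 0.999"
        )
    k = brentq(lambda x: cum(x) - cum_death_target, 0.0, k_max, maxiter=200)
    # Newton polish: brentq's floating bracket can stop a few ulps short.
    for _ in range(5):
        err = cum(k) - cum_death_target
        if abs(err) < 1e-14:
            break
        surv = np.prod(1.0 - k * w)
        deriv = surv * np.sum(w / (1.0 - k * w))
        k -= err / deriv
    curve = RiskCurve(ages, k * w)
    achieved = curve.cumulative_incidence(start_age, end_age)
    if abs(achieved - cum_death_target) >= 1e-10:  # pragma: no cover - defensive
        raise InfeasibleTargetError(
            f"root refinement failed: achieved {achieved}, target {cum_death_target}"
        )
    return curve


def synth_life_table(
    start_age: int,
    end_age: int,
    gompertz_a: float,
    gompertz_b: float,
    population_label: str = "synthetic Gompertz female life table",
) -> LifeTable:
    """Gompertz-shaped life table: qx(a) = min(a0 * exp(b*(a - start_age)), 1)."""
    if gompertz_a <= 0:
        raise ValueError("gompertz_a must be positive")
    if gompertz_b < 0:
        raise ValueError("gompertz_b must be nonnegative")
    ages = np.arange(start_age, end_age)
    qx = np.minimum(gompertz_a * np.exp(gompertz_b * (ages - start_age)), 1.0)
    return LifeTable(ages, qx, population_label)


#: Lifetime IHD risk to age 80 for 50-year-old women by CRF stratum.
#: The all-optimal, overall, >=2-major-CRF and diabetes values are the
#: published Framingham Heart Study figures (8.2%, 20.5%, 40.2%, 57.3% as a
#: lower bound); the remaining single-factor strata are synthetic fill-ins
#: chosen to respect the published qualitative ordering
#: (smoker < cholesterol >= 240 < >=2 CRFs < grade II-III hypertension < diabetes).
DEFAULT_STRATA: tuple[tuple[str, float], ...] = (
    (REFERENCE_STRATUM, 0.082),
    ("overall", 0.205),
    ("smoker", 0.210),
    ("cholesterol>=240", 0.280),
    (">=2 major CRFs", 0.402),
    ("hypertension II-III", 0.500),
    ("diabetes", 0.573),
)


def synth_strata_table(index_ages: tuple[int, ...] = (40, 50, 60)) -> StrataTable:
    """Synthetic CRF strata table.

    Anchored on the Framingham 50-year-old female lifetime risks; the same
    risk set is reused for every requested index age (a synthetic
    simplification — real lifetime risks decline slightly with index age).
    """
    rows = [
        {"stratum": s, "index_age": age, "lifetime_risk": r}
        for age in index_ages
        for s, r in DEFAULT_STRATA
    ]
    return StrataTable(pd.DataFrame(rows))
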