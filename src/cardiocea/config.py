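"""Run configuration: a validated YAML/JSON schema mapped onto the model.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently running the defaults.  ``build_model`` turns a validated config into
a calibrated :class:`~cardiocea.model.DecisionModel` plus the scenario it
describes; inputs come from user CSVs when paths are given, otherwise from
the synthetic generators.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .cea import EconParams, PSASettings
from .curves import (
    read_life_table,
    read_risk_curve,
    read_strata_table,
    synth_life_table,
    synth_risk_curve,
    synth_strata_table,
)
from .hazards import CalibrationTargets, CancerMortalityParams, PatientScenario
from .markov import ModelSettings
from .model import DecisionModel

__all__ = ["RunConfig", "ConfigError", "load_config", "build_model", "config_hash"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScenarioConfig(_Strict):
    age: int = 50
    photon_mhd: float = 5.0
    proton_mhd: float = 0.5
    risk_multiplier: float = 1.0
    horizon_age: int = 80


class EconomicsConfig(_Strict):
    cost_proton: float = 50_000.0
    cost_photon: float = 12_000.0
    cost_pci: float = 10_000.0
    cost_ihd_annual: float = 2_000.0
    cost_followup_annual: float = 1_000.0
    u_healthy: float = 0.95
    u_nonfatal: float = 0.695
    discount_rate: float = 0.03


class TargetConfig(_Strict):
    death: float
    total: float
    mhd: float


class TargetsConfig(_Strict):
    proton: TargetConfig = TargetConfig(death=0.020, total=0.046, mhd=0.5)
    photon: TargetConfig = TargetConfig(death=0.027, total=0.061, mhd=5.0)


class ModelConfig(_Strict):
    err_per_gy: float = 0.074
    scaling_mode: Literal["linear_prob", "hazard_rate"] = "linear_prob"
    calibration_mode: Literal["per_strategy", "at_zero_dose"] = "per_strategy"
    tol: float = 1e-9
    half_cycle_correction: bool = True
    cancer_five_year_cum: float = 0.06
    cancer_window_years: int = 5
    subtract_ihd_from_other: bool = False


class SyntheticConfig(_Strict):
    curve_start: int = 40
    curve_end: int = 80
    curve_cum_death: float = 0.03
    doubling_per_decade: float = 2.0
    gompertz_a: float = 0.0016
    gompertz_b: float = 0.082


class InputsConfig(_Strict):
    risk_curve_csv: str | None = None
    life_table_csv: str | None = None
    strata_csv: str | None = None
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)


class PSAConfig(_Strict):
    n_iterations: int = 50_000
    cost_halfwidth_frac: float = 0.25
    utility_beta_se_frac: float = 0.10


class GridConfig(_Strict):
    ages: list[int] = Field(default_factory=lambda: [40, 50, 60])
    multipliers: list[float] = Field(default_factory=lambda: [float(m) for m in range(1, 13)])
    proton_costs: list[float] = Field(
        default_factory=lambda: [50_000.0, 40_000.0, 30_000.0, 20_000.0]
    )


class RunConfig(_Strict):
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    economics: EconomicsConfig = Field(default_factory=EconomicsConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    targets: TargetsConfig = Field(default_factory=TargetsConfig)
    inputs: InputsConfig = Field(default_factory=InputsConfig)
    psa: PSAConfig = Field(default_factory=PSAConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    wtps: list[float] = Field(default_factory=lambda: [37_653.0, 50_000.0, 100_000.0])
    seed: int = 20_220_825


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML (or JSON — valid YAML) config; ``overrides`` are deep-merged."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
            data = loaded
    for key, value in (overrides or {}).items():
        section, _, leaf = key.partition(".")
        if leaf:
            data.setdefault(section, {})[leaf] = value
        else:
            data[section] = value
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def build_model(config: RunConfig) -> tuple[DecisionModel, PatientScenario]:
    """Instantiate inputs, wire the bundle, and calibrate per the config."""
    syn = config.inputs.synthetic
    curve = (
        read_risk_curve(config.inputs.risk_curve_csv)
        if config.inputs.risk_curve_csv
        else synth_risk_curve(
            syn.curve_start, syn.curve_end, syn.curve_cum_death, syn.doubling_per_decade
        )
    )
    life = (
        read_life_table(config.inputs.life_table_csv)
        if config.inputs.life_table_csv
        else synth_life_table(syn.curve_start, syn.curve_end, syn.gompertz_a, syn.gompertz_b)
    )
    strata = (
        read_strata_table(config.inputs.strata_csv)
        if config.inputs.strata_csv
        else synth_strata_table()
    )
    mc = config.model
    model = DecisionModel(
        curve=curve,
        life=life,
        cancer=CancerMortalityParams(mc.cancer_five_year_cum, mc.cancer_window_years),
        settings=ModelSettings(half_cycle_correction=mc.half_cycle_correction),
        econ=EconParams(**config.economics.model_dump()),
        strata=strata,
        err_per_gy=mc.err_per_gy,
        scaling_mode=mc.scaling_mode,
        subtract_ihd_from_other=mc.subtract_ihd_from_other,
        tol=mc.tol,
    )
    sc = config.scenario
    scenario = PatientScenario(
        start_age=sc.age,
        photon_mhd=sc.photon_mhd,
        proton_mhd=sc.proton_mhd,
        preexisting_multiplier=sc.risk_multiplier,
        horizon_age=sc.horizon_age,
    )
    t = config.targets
    if mc.calibration_mode == "per_strategy":
        model.calibrate_per_strategy(
            scenario,
            CalibrationTargets(t.proton.death, t.proton.total, t.proton.mhd),
            CalibrationTargets(t.photon.death, t.photon.total, t.photon.mhd),
        )
    else:
        model.calibrate_at_zero_dose(
            scenario, CalibrationTargets(t.proton.death, t.proton.total, t.proton.mhd)
        )
    return model, scenario


def psa_settings(config: RunConfig) -> PSASettings:
    return PSASettings(
        n_iterations=config.psa.n_iterations,
        seed=config.seed,
        cost_halfwidth_frac=config.psa.cost_halfwidth_frac,
        utility_beta_se_frac=config.psa.utility_beta_se_frac,
    )
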