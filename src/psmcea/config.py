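"""Validated analysis configuration and YAML round-trip.

The whole analysis — survival parameters, clock, economics, sensitivity
settings — is a single :class:`AnalysisConfig`.  Validation is strict:
unknown keys are rejected (typo safety) and every numeric field is checked
against its domain, so a malformed file fails loudly with the field name.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "SurvivalParamsCfg",
    "DrugComponentCfg",
    "RegimenCfg",
    "AdverseEventCfg",
    "StrategyCfg",
    "PatientCfg",
    "PSACfg",
    "AnalysisConfig",
    "load_config",
    "save_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SurvivalParamsCfg(_Strict):
    family: str = "log-logistic"
    shape: float = Field(gt=0)
    scale: float = Field(gt=0)


class DrugComponentCfg(_Strict):
    name: str
    dose: float = Field(ge=0, description="mg per kg / per m2 / flat, per administration")
    basis: Literal["per_kg", "per_m2", "flat"]
    unit_size_mg: float = Field(gt=0)
    unit_price_usd: float = Field(ge=0)
    administrations_per_cycle: int = Field(ge=1, default=1)
    max_cycles: Optional[int] = Field(default=None, ge=0)


class RegimenCfg(_Strict):
    components: list[DrugComponentCfg]
    max_treatment_cycles: Optional[int] = Field(default=None, ge=0)


class AdverseEventCfg(_Strict):
    name: str
    incidence: float = Field(ge=0, le=1)
    one_time_cost_usd: float = Field(ge=0)
    disutility: float = Field(ge=0, le=1)
    disutility_duration_cycles: int = Field(ge=0, default=1)


class StrategyCfg(_Strict):
    name: str
    os: SurvivalParamsCfg
    pfs: SurvivalParamsCfg
    regimen: RegimenCfg
    adverse_events: list[AdverseEventCfg]
    subsequent_therapy_fraction: float = Field(ge=0, le=1)
    subsequent_cost_per_cycle_usd: float = Field(ge=0)
    subsequent_duration_cycles: int = Field(ge=0, default=6)
    bsc_cost_per_cycle_usd: float = Field(ge=0)
    followup_cost_per_cycle_usd: float = Field(ge=0)
    labs_cost_per_cycle_usd: float = Field(ge=0)
    ct_cost_per_cycle_usd: float = Field(ge=0)
    u_pfs: float = Field(ge=0, le=1)
    u_pd: float = Field(ge=0, le=1)


class PatientCfg(_Strict):
    weight_kg: float = Field(gt=0)
    body_surface_area_m2: float = Field(gt=0)
    male_fraction: float = Field(ge=0, le=1)


class PSACfg(_Strict):
    n_iterations: int = Field(ge=1, default=1000)
    seed: int = Field(ge=0, default=12345)


class AnalysisConfig(_Strict):
    """Complete configuration of one population's analysis."""

    population: str
    horizon_years: float = Field(gt=0, default=10.0)
    cycle_length_days: float = Field(gt=0, default=21.0)
    discount_rate: float = Field(ge=0, lt=1)
    wtp_usd_per_qaly: float = Field(ge=0)
    half_cycle_correction: bool = True
    vial_rounding: Literal["round_up", "exact_mg"] = "round_up"
    treatment_cap_mode: Literal["median_duration", "until_progression"] = "median_duration"
    owsa_range_fraction: float = Field(gt=0, lt=1, default=0.25)
    psa: PSACfg = PSACfg()
    patient: PatientCfg
    intervention: StrategyCfg
    comparator: StrategyCfg

    @model_validator(mode="after")
    def _distinct_names(self) -> "AnalysisConfig":
        if self.intervention.name == self.comparator.name:
            raise ValueError("intervention and comparator must have distinct names")
        return self


def load_config(path) -> AnalysisConfig:
    """Read and validate a YAML analysis configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return AnalysisConfig.model_validate(raw)


def save_config(config: AnalysisConfig, path) -> None:
    """Write a configuration to YAML such that load_config round-trips."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
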