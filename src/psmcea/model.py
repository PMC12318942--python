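"""End-to-end model evaluation from a validated configuration.

This is the glue between the declarative :class:`~psmcea.config.AnalysisConfig`
and the computational modules: it materialises survival models, the time
grid and strategy bundles, builds both arms' traces, accrues costs and
QALYs, and returns the incremental comparison.  Sensitivity analyses reuse
:func:`evaluate_config` on perturbed copies of the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import AnalysisConfig, StrategyCfg
from .economics import (
    AdverseEvent,
    AEProfile,
    ArmResult,
    CEResult,
    DrugComponent,
    DrugRegimen,
    PatientProfile,
    StrategyInputs,
    compare,
    evaluate_arm,
)
from .engine import StateTrace, TimeGrid, build_trace
from .survival import ParametricSurvival

__all__ = ["BaseCaseResult", "strategy_inputs_from_config", "evaluate_config", "run_base_case"]


def _survival_model(cfg) -> ParametricSurvival:
    return ParametricSurvival(family=cfg.family, shape=cfg.shape, scale=cfg.scale)


def strategy_inputs_from_config(
    strat: StrategyCfg, config: AnalysisConfig
) -> StrategyInputs:
    """Materialise one arm's economic bundle, honouring the calibration flags."""
    until_progression = config.treatment_cap_mode == "until_progression"
    components = tuple(
        DrugComponent(
            name=c.name,
            dose=c.dose,
            basis=c.basis,
            unit_size_mg=c.unit_size_mg,
            unit_price_usd=c.unit_price_usd,
            administrations_per_cycle=c.administrations_per_cycle,
            max_cycles=None if until_progression else c.max_cycles,
        )
        for c in strat.regimen.components
    )
    regimen = DrugRegimen(
        components=components,
        vial_rounding=config.vial_rounding,
        max_treatment_cycles=None
        if until_progression
        else strat.regimen.max_treatment_cycles,
    )
    ae = AEProfile(
        events=tuple(
            AdverseEvent(
                name=e.name,
                incidence=e.incidence,
                one_time_cost_usd=e.one_time_cost_usd,
                disutility=e.disutility,
                disutility_duration_cycles=e.disutility_duration_cycles,
            )
            for e in strat.adverse_events
        )
    )
    return StrategyInputs(
        name=strat.name,
        regimen=regimen,
        ae=ae,
        subsequent_therapy_fraction=strat.subsequent_therapy_fraction,
        subsequent_cost_per_cycle_usd=strat.subsequent_cost_per_cycle_usd,
        subsequent_duration_cycles=strat.subsequent_duration_cycles,
        bsc_cost_per_cycle_usd=strat.bsc_cost_per_cycle_usd,
        followup_cost_per_cycle_usd=strat.followup_cost_per_cycle_usd,
        labs_cost_per_cycle_usd=strat.labs_cost_per_cycle_usd,
        ct_cost_per_cycle_usd=strat.ct_cost_per_cycle_usd,
        u_pfs=strat.u_pfs,
        u_pd=strat.u_pd,
    )


@dataclass
class BaseCaseResult:
    """Everything the base case produces: traces, arm totals, comparison."""

    config: AnalysisConfig
    intervention_trace: StateTrace
    comparator_trace: StateTrace
    intervention: ArmResult
    comparator: ArmResult
    ce: CEResult


def _evaluate_strategy(
    strat: StrategyCfg, config: AnalysisConfig, grid: TimeGrid, profile: PatientProfile
) -> tuple[StateTrace, ArmResult]:
    trace = build_trace(
        os_model=_survival_model(strat.os),
        pfs_model=_survival_model(strat.pfs),
        grid=grid,
        half_cycle_correction=config.half_cycle_correction,
        annual_discount_rate=config.discount_rate,
    )
    inputs = strategy_inputs_from_config(strat, config)
    return trace, evaluate_arm(trace, inputs, profile)


def evaluate_config(config: AnalysisConfig) -> CEResult:
    """Run both arms and return the incremental comparison only."""
    return run_base_case(config).ce


def run_base_case(config: AnalysisConfig) -> BaseCaseResult:
    """Full deterministic evaluation of a configuration."""
    grid = TimeGrid(
        cycle_length_days=config.cycle_length_days,
        horizon_years=config.horizon_years,
    )
    profile = PatientProfile(
        weight_kg=config.patient.weight_kg,
        body_surface_area_m2=config.patient.body_surface_area_m2,
        male_fraction=config.patient.male_fraction,
    )
    itrace, iarm = _evaluate_strategy(config.intervention, config, grid, profile)
    ctrace, carm = _evaluate_strategy(config.comparator, config, grid, profile)
    ce = compare(iarm, carm, wtp=config.wtp_usd_per_qaly)
    return BaseCaseResult(
        config=config,
        intervention_trace=itrace,
        comparator_trace=ctrace,
        intervention=iarm,
        comparator=carm,
        ce=ce,
    )
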