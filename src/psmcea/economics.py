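"""Cost and QALY accrual over a partitioned-survival trace.

One strategy (treatment arm) is described by a :class:`StrategyInputs`
bundle: the drug regimen with its dosing rules, the grade >=3 adverse-event
profile, downstream-care rules (subsequent chemotherapy, best supportive
care), per-cycle monitoring costs, and the two health-state utilities.
Accrual walks the per-cycle occupancy of a :class:`~psmcea.engine.StateTrace`
and discounts every term at its cycle's accrual time.

Accrual conventions (each is a deliberate modelling choice, see the methods
note for rationale):

- drug acquisition accrues on PFS occupancy, per component, up to that
  component's treatment-duration cap (median trial treatment duration by
  default; uncapped in "until progression" mode);
- adverse-event management costs are charged once at model start as
  incidence-weighted one-off costs, with matching one-off utility decrements
  over a configurable number of cycles;
- monitoring (follow-up, laboratory, CT) accrues on all alive occupancy;
- subsequent chemotherapy is a fixed-length course taken up by a fixed
  fraction of progressors, tracked by convolving new PD entrants with the
  course window; best supportive care covers PD occupancy not on it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import StateTrace, life_years

__all__ = [
    "DosingBasis",
    "VialRounding",
    "DrugComponent",
    "DrugRegimen",
    "PatientProfile",
    "AdverseEvent",
    "AEProfile",
    "StrategyInputs",
    "CostBreakdown",
    "ArmResult",
    "CEResult",
    "drug_cost_per_cycle",
    "accrue_costs",
    "accrue_qalys",
    "evaluate_arm",
    "compare",
]


class DosingBasis(str, enum.Enum):
    PER_KG = "per_kg"
    PER_M2 = "per_m2"
    FLAT = "flat"


class VialRounding(str, enum.Enum):
    ROUND_UP = "round_up"  # whole vials, wastage discarded
    EXACT_MG = "exact_mg"  # fractional vials, no wastage


@dataclass(frozen=True)
class DrugComponent:
    """One drug in a regimen with its dose rule and unit price."""

    name: str
    dose: float  # mg per kg, mg per m2, or mg flat, per administration
    basis: DosingBasis
    unit_size_mg: float
    unit_price_usd: float
    administrations_per_cycle: int = 1
    max_cycles: Optional[int] = None  # treatment-duration cap, None = uncapped

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", DosingBasis(self.basis))
        if self.unit_size_mg <= 0:
            raise ValueError(f"{self.name}: unit size must be > 0")
        if self.unit_price_usd < 0 or self.dose < 0:
            raise ValueError(f"{self.name}: dose and price must be >= 0")
        if self.administrations_per_cycle < 1:
            raise ValueError(f"{self.name}: administrations_per_cycle must be >= 1")


@dataclass(frozen=True)
class DrugRegimen:
    components: tuple[DrugComponent, ...]
    vial_rounding: VialRounding = VialRounding.ROUND_UP
    max_treatment_cycles: Optional[int] = None  # regimen-wide cap on top of per-drug caps

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "vial_rounding", VialRounding(self.vial_rounding))


@dataclass(frozen=True)
class PatientProfile:
    """Cohort-average body metrics driving chemotherapy dosing."""

    weight_kg: float
    body_surface_area_m2: float
    male_fraction: float

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.body_surface_area_m2 <= 0:
            raise ValueError("weight and body surface area must be > 0")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must be in [0, 1]")


@dataclass(frozen=True)
class AdverseEvent:
    """A grade >=3 adverse event: incidence, one-off cost, utility decrement."""

    name: str
    incidence: float
    one_time_cost_usd: float
    disutility: float
    disutility_duration_cycles: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.incidence <= 1.0):
            raise ValueError(f"{self.name}: incidence must be in [0, 1]")
        if not (0.0 <= self.disutility <= 1.0):
            raise ValueError(f"{self.name}: disutility must be in [0, 1]")
        if self.one_time_cost_usd < 0:
            raise ValueError(f"{self.name}: cost must be >= 0")


@dataclass(frozen=True)
class AEProfile:
    events: tuple[AdverseEvent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class StrategyInputs:
    """Full economic description of one treatment arm."""

    name: str
    regimen: DrugRegimen
    ae: AEProfile
    subsequent_therapy_fraction: float
    subsequent_cost_per_cycle_usd: float
    subsequent_duration_cycles: int
    bsc_cost_per_cycle_usd: float
    followup_cost_per_cycle_usd: float
    labs_cost_per_cycle_usd: float
    ct_cost_per_cycle_usd: float
    u_pfs: float
    u_pd: float

    def __post_init__(self) -> None:
        for nm in ("u_pfs", "u_pd", "subsequent_therapy_fraction"):
            v = getattr(self, nm)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{nm} must be in [0, 1], got {v}")
        for nm in (
            "subsequent_cost_per_cycle_usd",
            "bsc_cost_per_cycle_usd",
            "followup_cost_per_cycle_usd",
            "labs_cost_per_cycle_usd",
            "ct_cost_per_cycle_usd",
        ):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if self.subsequent_duration_cycles < 0:
            raise ValueError("subsequent_duration_cycles must be >= 0")
        if self.u_pd > self.u_pfs:
            import warnings

            warnings.warn(
                f"{self.name}: u_pd ({self.u_pd}) exceeds u_pfs ({self.u_pfs})",
                stacklevel=2,
            )


def _component_dose_mg(comp: DrugComponent, profile: PatientProfile) -> float:
    if comp.basis is DosingBasis.PER_KG:
        return comp.dose * profile.weight_kg
    if comp.basis is DosingBasis.PER_M2:
        return comp.dose * profile.body_surface_area_m2
    return comp.dose


def component_cost_per_cycle(
    comp: DrugComponent, profile: PatientProfile, rounding: VialRounding
) -> float:
    """Acquisition cost of one component for one full cycle on treatment."""
    dose = _component_dose_mg(comp, profile)
    if rounding is VialRounding.ROUND_UP:
        units: float = math.ceil(dose / comp.unit_size_mg - 1e-9)
    else:
        units = dose / comp.unit_size_mg
    return units * comp.unit_price_usd * comp.administrations_per_cycle


def drug_cost_per_cycle(regimen: DrugRegimen, profile: PatientProfile) -> float:
    """Full-regimen acquisition cost per cycle, ignoring duration caps."""
    return sum(
        component_cost_per_cycle(c, profile, regimen.vial_rounding)
        for c in regimen.components
    )


@dataclass
class CostBreakdown:
    drug: float = 0.0
    adverse_events: float = 0.0
    subsequent_therapy: float = 0.0
    bsc: float = 0.0
    followup: float = 0.0
    labs: float = 0.0
    ct: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.drug
            + self.adverse_events
            + self.subsequent_therapy
            + self.bsc
            + self.followup
            + self.labs
            + self.ct
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "drug", "adverse_events", "subsequent_therapy",
            "bsc", "followup", "labs", "ct")}
        d["total"] = self.total
        return d


def _pd_entrants(trace: StateTrace) -> np.ndarray:
    """Per-cycle new progressors, approximated by the decline of the PFS curve.

    In a partitioned model deaths cannot be attributed to a source state, so
    every PFS exit is treated as a progression; this slightly overstates the
    progressing fraction when death from PFS is common.
    """
    pfs = trace.pfs
    entrants = np.empty_like(pfs)
    entrants[0] = max(0.0, 1.0 - pfs[0])
    entrants[1:] = np.maximum(0.0, pfs[:-1] - pfs[1:])
    return entrants


def _subsequent_occupancy(trace: StateTrace, strategy: StrategyInputs) -> np.ndarray:
    """Occupancy receiving subsequent chemotherapy at each cycle.

    A fraction of each cycle's new progressors takes a fixed-length course;
    the on-treatment pool at cycle k is the windowed sum of recent entrants,
    capped by the PD occupancy actually alive.
    """
    d = strategy.subsequent_duration_cycles
    if d == 0 or strategy.subsequent_therapy_fraction == 0.0:
        return np.zeros_like(trace.pd)
    entrants = _pd_entrants(trace) * strategy.subsequent_therapy_fraction
    window = np.ones(d)
    on_course = np.convolve(entrants, window)[: entrants.size]
    return np.minimum(on_course, trace.pd)


def accrue_costs(
    trace: StateTrace, strategy: StrategyInputs, profile: PatientProfile
) -> CostBreakdown:
    """Discounted total cost of one arm, by category."""
    grid = trace.grid
    df = trace.discount_factors
    bd = CostBreakdown()

    overall_cap = strategy.regimen.max_treatment_cycles
    for comp in strategy.regimen.components:
        per_cycle = component_cost_per_cycle(
            comp, profile, strategy.regimen.vial_rounding
        )
        cap = grid.n_cycles
        if comp.max_cycles is not None:
            cap = min(cap, comp.max_cycles)
        if overall_cap is not None:
            cap = min(cap, overall_cap)
        bd.drug += per_cycle * float(np.sum(trace.pfs[:cap] * df[:cap]))

    # one-off AE management at model start (undiscounted: t = 0)
    bd.adverse_events = sum(
        e.incidence * e.one_time_cost_usd for e in strategy.ae.events
    )

    alive_df = float(np.sum(trace.alive * df))
    bd.followup = strategy.followup_cost_per_cycle_usd * alive_df
    bd.labs = strategy.labs_cost_per_cycle_usd * alive_df
    bd.ct = strategy.ct_cost_per_cycle_usd * alive_df

    on_sub = _subsequent_occupancy(trace, strategy)
    bd.subsequent_therapy = strategy.subsequent_cost_per_cycle_usd * float(
        np.sum(on_sub * df)
    )
    bd.bsc = strategy.bsc_cost_per_cycle_usd * float(
        np.sum((trace.pd - on_sub) * df)
    )
    return bd


def accrue_qalys(trace: StateTrace, strategy: StrategyInputs) -> float:
    """Discounted QALYs of one arm, including adverse-event disutility."""
    cyc_years = trace.grid.cycle_length_years
    df = trace.discount_factors
    base = float(
        np.sum((trace.pfs * strategy.u_pfs + trace.pd * strategy.u_pd) * cyc_years * df)
    )
    ae_loss = 0.0
    for e in strategy.ae.events:
        k = min(e.disutility_duration_cycles, trace.grid.n_cycles)
        ae_loss += e.incidence * e.disutility * cyc_years * float(np.sum(df[:k]))
    return max(0.0, base - ae_loss)


@dataclass
class ArmResult:
    """Discounted totals for one strategy arm."""

    name: str
    cost_breakdown: CostBreakdown
    total_cost: float
    qalys: float
    life_years: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "total_cost_usd": self.total_cost,
            "qalys": self.qalys,
            "life_years": self.life_years,
            "cost_breakdown": self.cost_breakdown.to_dict(),
        }


def evaluate_arm(
    trace: StateTrace, strategy: StrategyInputs, profile: PatientProfile
) -> ArmResult:
    bd = accrue_costs(trace, strategy, profile)
    return ArmResult(
        name=strategy.name,
        cost_breakdown=bd,
        total_cost=bd.total,
        qalys=accrue_qalys(trace, strategy),
        life_years=life_years(trace, discounted=True),
    )


@dataclass
class CEResult:
    """Incremental comparison of an intervention arm against a comparator."""

    intervention: ArmResult
    comparator: ArmResult
    wtp: float
    incremental_cost: float = field(init=False)
    incremental_qalys: float = field(init=False)
    icer: Optional[float] = field(init=False)
    label: str = field(init=False)  # "icer", "dominant", "dominated", "undefined"
    cost_effective: bool = field(init=False)

    def __post_init__(self) -> None:
        dc = self.intervention.total_cost - self.comparator.total_cost
        de = self.intervention.qalys - self.comparator.qalys
        self.incremental_cost = dc
        self.incremental_qalys = de
        if de == 0.0:
            self.icer = None
            self.label = "undefined" if dc != 0.0 else "equivalent"
            self.cost_effective = dc <= 0.0
        elif de > 0 and dc <= 0:
            self.icer = dc / de
            self.label = "dominant"
            self.cost_effective = True
        elif de < 0 and dc >= 0:
            self.icer = dc / de
            self.label = "dominated"
            self.cost_effective = False
        else:
            self.icer = dc / de
            self.label = "icer"
            self.cost_effective = de > 0 and self.icer <= self.wtp

    @property
    def net_monetary_benefit(self) -> float:
        return self.wtp * self.incremental_qalys - self.incremental_cost

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention.to_dict(),
            "comparator": self.comparator.to_dict(),
            "wtp_usd_per_qaly": self.wtp,
            "incremental_cost_usd": self.incremental_cost,
            "incremental_qalys": self.incremental_qalys,
            "icer_usd_per_qaly": self.icer,
            "label": self.label,
            "cost_effective": self.cost_effective,
            "net_monetary_benefit_usd": self.net_monetary_benefit,
        }


def compare(intervention: ArmResult, comparator: ArmResult, wtp: float) -> CEResult:
    """Incremental cost, incremental QALYs, ICER and dominance labelling."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return CEResult(intervention=intervention, comparator=comparator, wtp=wtp)
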