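"""Built-in analysis configurations for the two trial populations.

All numeric inputs of the published analysis are transcribed here:
log-logistic OS/PFS parameters refitted from the COMPASSION-15 trial's
reconstructed survival curves (all-randomized population and the PD-L1
CPS >= 5 subgroup), 2025 Chinese median drug prices (YAOZHI platform,
RMB converted at 7.12 RMB/USD), grade >=3 adverse-event incidences and
management costs, downstream-care costs, health-state utilities, and the
Chinese willingness-to-pay threshold of three times per-capita GDP
(40,343.68 USD/QALY).

Dosing follows the trial protocol: cadonilimab 10 mg/kg IV every 3 weeks;
CAPOX = capecitabine 1,000 mg/m2 orally twice daily on days 1-14 plus
oxaliplatin 130 mg/m2 IV on day 1 of each 3-week cycle.  Treatment-duration
caps translate the median treatment durations (cadonilimab 5.62 months,
CAPOX 4.17/4.14 months) into whole 3-week cycles.
"""

from __future__ import annotations

from .config import (
    AdverseEventCfg,
    AnalysisConfig,
    DrugComponentCfg,
    PatientCfg,
    PSACfg,
    RegimenCfg,
    StrategyCfg,
    SurvivalParamsCfg,
)

__all__ = ["POPULATIONS", "make_paper_fixture"]

POPULATIONS = ("all_randomized", "cps_ge5")

WTP_USD_PER_QALY = 40_343.68  # 3x Chinese per-capita GDP, 2024

# cohort body metrics: trial male fraction 78.4%, mean weights 69.6 kg (men)
# and 59.0 kg (women); BSA 1.72 m2
_MALE_FRACTION = 0.784
_WEIGHT_KG = _MALE_FRACTION * 69.6 + (1.0 - _MALE_FRACTION) * 59.0  # 67.31 kg
_BSA_M2 = 1.72

# log-logistic (shape gamma, scale lambda), t in months
_SURVIVAL = {
    "all_randomized": {
        "cadonilimab": {"os": (1.54, 0.013), "pfs": (1.71, 0.028)},
        "chemotherapy": {"os": (1.92, 0.010), "pfs": (2.29, 0.024)},
    },
    "cps_ge5": {
        "cadonilimab": {"os": (1.77, 0.0087), "pfs": (1.80, 0.024)},
        "chemotherapy": {"os": (1.94, 0.0096), "pfs": (2.22, 0.028)},
    },
}

# grade >=3 adverse events: (incidence per arm), one-off management cost,
# utility decrement applied for one cycle at model start
_AE_TABLE = [
    # name, cado incidence, chemo incidence, cost USD, disutility
    ("decreased_platelet_count", 0.285, 0.605, 1505.92, 0.65),
    ("decreased_neutrophil_count", 0.151, 0.493, 115.01, 0.20),
    ("decreased_white_blood_cell_count", 0.072, 0.470, 467.86, 0.20),
    ("anemia", 0.102, 0.434, 468.19, 0.07),
]

# median treatment durations in 3-week cycles (5.62 / 4.17 / 4.14 months)
_CADONILIMAB_MAX_CYCLES = 8
_CAPOX_MAX_CYCLES = 6

_U_PFS = 0.80
_U_PD = 0.58

_SUBSEQUENT_FRACTION = {"cadonilimab": 0.344, "chemotherapy": 0.479}
_SUBSEQUENT_COST_PER_CYCLE = 184.44  # paclitaxel + cisplatin course
_SUBSEQUENT_DURATION_CYCLES = 6
_BSC_COST_PER_CYCLE = 248.00
_FOLLOWUP_COST_PER_CYCLE = 55.60
_LABS_COST_PER_CYCLE = 92.50
_CT_COST_PER_CYCLE = 105.90


def _capox_components() -> list[DrugComponentCfg]:
    return [
        DrugComponentCfg(
            name="capecitabine",
            dose=1000.0,
            basis="per_m2",
            unit_size_mg=500.0,
            unit_price_usd=0.32,
            administrations_per_cycle=28,  # twice daily, days 1-14
            max_cycles=_CAPOX_MAX_CYCLES,
        ),
        DrugComponentCfg(
            name="oxaliplatin",
            dose=130.0,
            basis="per_m2",
            unit_size_mg=50.0,
            unit_price_usd=7.56,
            administrations_per_cycle=1,  # day 1
            max_cycles=_CAPOX_MAX_CYCLES,
        ),
    ]


def _strategy(name: str, population: str) -> StrategyCfg:
    os_p = _SURVIVAL[population][name]["os"]
    pfs_p = _SURVIVAL[population][name]["pfs"]
    incidence_col = 1 if name == "cadonilimab" else 2
    components = _capox_components()
    if name == "cadonilimab":
        components.insert(
            0,
            DrugComponentCfg(
                name="cadonilimab",
                dose=10.0,
                basis="per_kg",
                unit_size_mg=125.0,
                unit_price_usd=866.01,
                administrations_per_cycle=1,
                max_cycles=_CADONILIMAB_MAX_CYCLES,
            ),
        )
    return StrategyCfg(
        name=name,
        os=SurvivalParamsCfg(family="log-logistic", shape=os_p[0], scale=os_p[1]),
        pfs=SurvivalParamsCfg(family="log-logistic", shape=pfs_p[0], scale=pfs_p[1]),
        regimen=RegimenCfg(components=components),
        adverse_events=[
            AdverseEventCfg(
                name=row[0],
                incidence=row[incidence_col],
                one_time_cost_usd=row[3],
                disutility=row[4],
                disutility_duration_cycles=1,
            )
            for row in _AE_TABLE
        ],
        subsequent_therapy_fraction=_SUBSEQUENT_FRACTION[name],
        subsequent_cost_per_cycle_usd=_SUBSEQUENT_COST_PER_CYCLE,
        subsequent_duration_cycles=_SUBSEQUENT_DURATION_CYCLES,
        bsc_cost_per_cycle_usd=_BSC_COST_PER_CYCLE,
        followup_cost_per_cycle_usd=_FOLLOWUP_COST_PER_CYCLE,
        labs_cost_per_cycle_usd=_LABS_COST_PER_CYCLE,
        ct_cost_per_cycle_usd=_CT_COST_PER_CYCLE,
        u_pfs=_U_PFS,
        u_pd=_U_PD,
    )


def make_paper_fixture(population: str = "all_randomized") -> AnalysisConfig:
    """Complete base-case configuration for one trial population.

    ``population`` is ``"all_randomized"`` or ``"cps_ge5"`` (PD-L1 combined
    positive score >= 5 subgroup).  The two populations differ only in their
    survival parameters; every economic input is shared.
    """
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}; expected one of {POPULATIONS}")
    return AnalysisConfig(
        population=population,
        horizon_years=10.0,
        cycle_length_days=21.0,
        discount_rate=0.05,
        wtp_usd_per_qaly=WTP_USD_PER_QALY,
        half_cycle_correction=True,
        vial_rounding="round_up",
        treatment_cap_mode="median_duration",
        owsa_range_fraction=0.25,
        psa=PSACfg(n_iterations=1000, seed=12345),
        patient=PatientCfg(
            weight_kg=_WEIGHT_KG,
            body_surface_area_m2=_BSA_M2,
            male_fraction=_MALE_FRACTION,
        ),
        intervention=_strategy("cadonilimab", population),
        comparator=_strategy("chemotherapy", population),
    )
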