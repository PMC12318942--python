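"""Deterministic (tornado) and probabilistic sensitivity analysis.

The parameter registry enumerates every economic input that the published
price/utility table varies: per-arm grade >=3 adverse-event incidences
(Beta), drug unit prices and all per-cycle/one-off costs (Gamma),
health-state utilities and adverse-event disutilities (Beta), body surface
area and the discount rate.  Survival shape/scale parameters are *not*
sampled — no distributions are reported for them.

One-way analysis perturbs each parameter to base*(1 -/+ range_fraction)
(default +/-25%) with everything else at base, recording the ICER at both
ends.  Probabilistic analysis draws all parameters jointly and
independently from distributions calibrated by method of moments, reading
the +/-25% range as a 95% interval (sd = (high - low) / (2 * 1.96)), and
applies the net-monetary-benefit rule NMB = WTP * dE - dC >= 0, which
handles negative incremental effects without ICER sign ambiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .economics import CEResult
from .model import evaluate_config

__all__ = [
    "ParameterSpec",
    "TornadoEntry",
    "OWSAResult",
    "PSAResult",
    "build_parameter_specs",
    "calibrate_distribution",
    "run_owsa",
    "run_psa",
    "build_ceac",
]

_MAX_RESAMPLE = 1000


@dataclass
class ParameterSpec:
    """One scalar model input eligible for sensitivity analysis.

    ``setter`` writes a value into (a deep copy of) an
    :class:`AnalysisConfig`; ``unit_interval`` marks parameters whose valid
    domain is [0, 1] (probabilities, utilities, rates) so out-of-domain
    draws can be rejected and resampled.
    """

    name: str
    base: float
    setter: Callable[[AnalysisConfig, float], None]
    distribution: Literal["beta", "gamma", "fixed"]
    low: Optional[float] = None
    high: Optional[float] = None
    unit_interval: bool = False

    def with_range(self, fraction: float) -> "ParameterSpec":
        if self.low is None:
            self.low = self.base * (1.0 - fraction)
        if self.high is None:
            self.high = self.base * (1.0 + fraction)
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: require low <= base <= high")
        return self


def calibrate_distribution(spec: ParameterSpec) -> dict:
    """Method-of-moments distribution parameters for one spec.

    The (low, high) range is read as a 95% interval, sd = (high-low)/3.92.
    Gamma: shape = (mu/sd)^2, scale = sd^2/mu.  Beta: alpha = mu*nu,
    beta = (1-mu)*nu with nu = mu(1-mu)/sd^2 - 1.  Either way the
    distribution mean equals the base value exactly.  A zero-width range
    (or a degenerate beta) collapses to a fixed parameter.
    """
    mu = spec.base
    sd = (spec.high - spec.low) / (2.0 * 1.96)
    if sd == 0.0 or spec.distribution == "fixed":
        return {"kind": "fixed", "value": mu}
    if spec.distribution == "gamma":
        if mu <= 0:
            raise ValueError(f"{spec.name}: gamma requires a positive base value")
        return {"kind": "gamma", "shape": (mu / sd) ** 2, "scale": sd * sd / mu}
    if spec.distribution == "beta":
        if not (0.0 < mu < 1.0):
            raise ValueError(f"{spec.name}: beta requires base in (0, 1)")
        nu = mu * (1.0 - mu) / (sd * sd) - 1.0
        if nu <= 0:  # variance too large for a beta: treat as fixed
            return {"kind": "fixed", "value": mu}
        return {"kind": "beta", "alpha": mu * nu, "beta": (1.0 - mu) * nu}
    raise ValueError(f"{spec.name}: unknown distribution {spec.distribution}")


def _set_both_arms(attr: str) -> Callable[[AnalysisConfig, float], None]:
    def setter(cfg: AnalysisConfig, v: float) -> None:
        setattr(cfg.intervention, attr, v)
        setattr(cfg.comparator, attr, v)

    return setter


def _set_drug_price(drug: str) -> Callable[[AnalysisConfig, float], None]:
    def setter(cfg: AnalysisConfig, v: float) -> None:
        for strat in (cfg.intervention, cfg.comparator):
            for comp in strat.regimen.components:
                if comp.name == drug:
                    comp.unit_price_usd = v

    return setter


def _set_ae(arm_attr: str, event: str, field_name: str):
    def setter(cfg: AnalysisConfig, v: float) -> None:
        strat = getattr(cfg, arm_attr)
        for e in strat.adverse_events:
            if e.name == event:
                setattr(e, field_name, v)

    return setter


def _set_ae_both(event: str, field_name: str):
    def setter(cfg: AnalysisConfig, v: float) -> None:
        for strat in (cfg.intervention, cfg.comparator):
            for e in strat.adverse_events:
                if e.name == event:
                    setattr(e, field_name, v)

    return setter


def _set_global(attr: str, sub: Optional[str] = None):
    def setter(cfg: AnalysisConfig, v: float) -> None:
        target = getattr(cfg, sub) if sub else cfg
        setattr(target, attr, v)

    return setter


def build_parameter_specs(config: AnalysisConfig) -> list[ParameterSpec]:
    """Enumerate the sampled/perturbed parameters of a configuration.

    Order is deterministic, which fixes the PSA draw sequence for a seed.
    """
    frac = config.owsa_range_fraction
    specs: list[ParameterSpec] = []

    for arm_attr in ("intervention", "comparator"):
        strat = getattr(config, arm_attr)
        for e in strat.adverse_events:
            specs.append(
                ParameterSpec(
                    name=f"ae_incidence:{strat.name}:{e.name}",
                    base=e.incidence,
                    setter=_set_ae(arm_attr, e.name, "incidence"),
                    distribution="beta",
                    unit_interval=True,
                )
            )

    seen: set[str] = set()
    for strat in (config.intervention, config.comparator):
        for comp in strat.regimen.components:
            if comp.name not in seen:
                seen.add(comp.name)
                specs.append(
                    ParameterSpec(
                        name=f"drug_price:{comp.name}",
                        base=comp.unit_price_usd,
                        setter=_set_drug_price(comp.name),
                        distribution="gamma",
                    )
                )

    seen = set()
    for strat in (config.intervention, config.comparator):
        for e in strat.adverse_events:
            if e.name not in seen:
                seen.add(e.name)
                specs.append(
                    ParameterSpec(
                        name=f"ae_cost:{e.name}",
                        base=e.one_time_cost_usd,
                        setter=_set_ae_both(e.name, "one_time_cost_usd"),
                        distribution="gamma",
                    )
                )
                specs.append(
                    ParameterSpec(
                        name=f"ae_disutility:{e.name}",
                        base=e.disutility,
                        setter=_set_ae_both(e.name, "disutility"),
                        distribution="beta",
                        unit_interval=True,
                    )
                )

    for attr, dist in (
        ("subsequent_cost_per_cycle_usd", "gamma"),
        ("bsc_cost_per_cycle_usd", "gamma"),
        ("followup_cost_per_cycle_usd", "gamma"),
        ("labs_cost_per_cycle_usd", "gamma"),
        ("ct_cost_per_cycle_usd", "gamma"),
        ("u_pfs", "beta"),
        ("u_pd", "beta"),
    ):
        specs.append(
            ParameterSpec(
                name=attr.replace("_usd", "").replace("u_", "utility_"),
                base=getattr(config.intervention, attr),
                setter=_set_both_arms(attr),
                distribution=dist,  # type: ignore[arg-type]
                unit_interval=dist == "beta",
            )
        )

    # body surface area exceeds 1, so a beta law cannot represent it;
    # sampled as gamma instead (flagged in the methods note)
    specs.append(
        ParameterSpec(
            name="body_surface_area_m2",
            base=config.patient.body_surface_area_m2,
            setter=_set_global("body_surface_area_m2", "patient"),
            distribution="gamma",
        )
    )
    specs.append(
        ParameterSpec(
            name="discount_rate",
            base=config.discount_rate,
            setter=_set_global("discount_rate"),
            distribution="beta",
            unit_interval=True,
        )
    )

    return [s.with_range(frac) for s in specs]


def _evaluate_with(config: AnalysisConfig, overrides: dict[str, float],
                   specs_by_name: dict[str, ParameterSpec]) -> CEResult:
    cfg = config.model_copy(deep=True)
    for name, value in overrides.items():
        specs_by_name[name].setter(cfg, value)
    return evaluate_config(cfg)


@dataclass
class TornadoEntry:
    parameter: str
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]
    undefined: bool = False
    spread: float = field(init=False)

    def __post_init__(self) -> None:
        if self.icer_at_low is None or self.icer_at_high is None:
            self.undefined = True
            self.spread = float("nan")
        else:
            self.spread = abs(self.icer_at_high - self.icer_at_low)


@dataclass
class OWSAResult:
    base: CEResult
    entries: list[TornadoEntry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": [e.parameter for e in self.entries],
                "icer_at_low": [e.icer_at_low for e in self.entries],
                "icer_at_high": [e.icer_at_high for e in self.entries],
                "spread": [e.spread for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_owsa(
    config: AnalysisConfig, specs: Optional[Sequence[ParameterSpec]] = None
) -> OWSAResult:
    """One-way sensitivity analysis over every registered parameter.

    Each parameter is set to its low and high end with all others at base
    (two full model evaluations per parameter).  Entries come back sorted by
    ICER spread, widest first; parameters whose perturbation removes the
    incremental effect are flagged undefined and sort last.
    """
    if specs is None:
        specs = build_parameter_specs(config)
    by_name = {s.name: s for s in specs}
    base = evaluate_config(config)
    entries = []
    for s in specs:
        lo = _evaluate_with(config, {s.name: s.low}, by_name)
        hi = _evaluate_with(config, {s.name: s.high}, by_name)
        entries.append(TornadoEntry(s.name, lo.icer, hi.icer))
    entries.sort(key=lambda e: (e.undefined, -e.spread if not e.undefined else 0.0))
    return OWSAResult(base=base, entries=entries)


_DEFAULT_WTP_GRID = tuple(float(w) for w in range(0, 100_001, 2_500))


@dataclass
class PSAResult:
    """Monte Carlo parameter-uncertainty analysis output."""

    n_iterations: int
    seed: int
    wtp: float
    cost_intervention: np.ndarray
    qaly_intervention: np.ndarray
    cost_comparator: np.ndarray
    qaly_comparator: np.ndarray
    n_rejected_draws: int
    ceac: list[tuple[float, float]] = field(default_factory=list)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_intervention - self.cost_comparator

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qaly_intervention - self.qaly_comparator

    def prob_cost_effective(self, wtp: float) -> float:
        nmb = wtp * self.delta_qalys - self.delta_cost
        return float(np.mean(nmb >= 0.0))

    @property
    def prob_ce_at_wtp(self) -> float:
        return self.prob_cost_effective(self.wtp)

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "cost_intervention": self.cost_intervention,
                "qaly_intervention": self.qaly_intervention,
                "cost_comparator": self.cost_comparator,
                "qaly_comparator": self.qaly_comparator,
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
            }
        )

    def draws_to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} n_iterations={self.n_iterations}\n")
            self.draws_frame().to_csv(fh, index=False)

    def ceac_to_csv(self, path) -> None:
        pd.DataFrame(self.ceac, columns=["wtp", "probability"]).to_csv(
            path, index=False
        )


def _draw(rng: np.random.Generator, spec: ParameterSpec, params: dict) -> tuple[float, int]:
    """One draw from a calibrated distribution; rejection count returned."""
    rejected = 0
    for _ in range(_MAX_RESAMPLE):
        if params["kind"] == "fixed":
            return params["value"], rejected
        if params["kind"] == "gamma":
            v = rng.gamma(params["shape"], params["scale"])
        else:
            v = rng.beta(params["alpha"], params["beta"])
        if spec.unit_interval and not (0.0 <= v <= 1.0):
            rejected += 1
            continue
        return float(v), rejected
    raise RuntimeError(f"{spec.name}: resampling limit exceeded")


def run_psa(
    config: AnalysisConfig,
    n_iterations: Optional[int] = None,
    seed: Optional[int] = None,
    wtp_grid: Sequence[float] = _DEFAULT_WTP_GRID,
    specs: Optional[Sequence[ParameterSpec]] = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis via joint independent sampling.

    Per iteration every registered parameter is drawn once from its
    calibrated distribution, the full model is evaluated for both arms, and
    the (cost, QALY) pair per arm is recorded.  Reproducible for a given
    seed; defaults for iteration count and seed come from the config.
    """
    n = n_iterations if n_iterations is not None else config.psa.n_iterations
    seed = seed if seed is not None else config.psa.seed
    if specs is None:
        specs = build_parameter_specs(config)
    by_name = {s.name: s for s in specs}
    calibrated = [(s, calibrate_distribution(s)) for s in specs]

    rng = np.random.default_rng(seed)
    ci = np.empty(n)
    qi = np.empty(n)
    cc = np.empty(n)
    qc = np.empty(n)
    n_rejected = 0
    for it in range(n):
        overrides: dict[str, float] = {}
        for spec, params in calibrated:
            v, rej = _draw(rng, spec, params)
            n_rejected += rej
            overrides[spec.name] = v
        with warnings.catch_warnings():
            # independent utility draws occasionally invert u_pfs >= u_pd;
            # that is expected sampling behaviour, not a configuration fault
            warnings.filterwarnings("ignore", message=".*u_pd.*exceeds u_pfs.*")
            ce = _evaluate_with(config, overrides, by_name)
        ci[it] = ce.intervention.total_cost
        qi[it] = ce.intervention.qalys
        cc[it] = ce.comparator.total_cost
        qc[it] = ce.comparator.qalys

    result = PSAResult(
        n_iterations=n,
        seed=seed,
        wtp=config.wtp_usd_per_qaly,
        cost_intervention=ci,
        qaly_intervention=qi,
        cost_comparator=cc,
        qaly_comparator=qc,
        n_rejected_draws=n_rejected,
    )
    result.ceac = build_ceac(result, wtp_grid)
    return result


def build_ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve over a WTP grid.

    Uses the same net-monetary-benefit rule as the scalar acceptance
    probability; at WTP = 0 the probability reduces to the fraction of
    cost-saving draws.
    """
    grid = list(wtp_grid)
    if not grid:
        raise ValueError("wtp_grid must be non-empty")
    return [(float(w), psa.prob_cost_effective(float(w))) for w in grid]
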