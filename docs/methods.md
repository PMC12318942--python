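# Methods

## Model structure

A partitioned survival model (PSM) with three mutually exclusive states —
progression-free (PFS), progressed disease (PD), death — evaluated on a
discrete clock of 21-day cycles. State occupancy is read directly off the
two survival curves: `pfs(t) = S_PFS(t)`, `dead(t) = 1 − S_OS(t)`,
`pd(t) = S_OS(t) − S_PFS(t)`. There are no transition rates, tunnel states
or individual-level simulation; the PSM assumption is that the two curves
jointly determine occupancy without modelling the PFS→PD→death pathway
explicitly. If digitisation noise makes the PFS curve cross above the OS
curve, PD is clamped at zero (PFS is tied to OS so occupancy still sums to
one); clamped cycles are counted and a warning flag is set when more than
5% of cycles are affected.

- Cycle length: 21 days, matching the every-3-weeks administration
  schedule. Horizon: 10 years → `ceil(10 × 365.25 / 21) = 174` cycles.
- Half-cycle correction: on by default. Occupancy for accrual is evaluated
  at cycle midpoints, making per-cycle accrual a midpoint quadrature of the
  survival integral (the refinement test shows < 1% deviation from a
  10,000-point trapezoid integral at 21-day cycles).
- Discounting: 5%/year, continuous-in-time form `(1 + r)^(−t)` evaluated at
  each cycle's accrual time. At 5% this is within rounding of annual-step
  discounting; the smooth form is used because it is exact on a 21-day
  grid.

## Survival extrapolation

The log-logistic family is written in the rate form `S(t) = 1/(1 + λ t^γ)`
with **t in months** (λ multiplies `t^γ`, not `(λt)^γ`). The month
convention is a deliberate commitment, carried explicitly on the model
type: the implied medians of the fixture parameters
(`(1/λ)^(1/γ)` ≈ 8.1/5.1 months PFS and 16.8/11.0 months OS per arm in the
all-randomized population) track the trial medians, which no other unit
does.

Five comparison families (exponential, Weibull, log-normal, Gompertz,
gamma) exist to exercise information-criterion model selection; their
parametrisations are the conventional survival-analysis forms documented
on `Family`. Fitting maximises the right-censored log-likelihood
`Σ_events log f(t) + Σ_censored log S(t)` in log-parameter space
(Nelder-Mead, parameter tolerance 1e-8) from three deterministic starts;
the scale start is solved so each started model matches the observed event
median, and the Gompertz shape starts scale with `1/t_median` because that
shape is a hazard growth *rate*, not an O(1) power. Optimiser failure
yields `converged = False`, never an exception; non-converged fits rank
last. Density/survival evaluations go through the matching `scipy.stats`
distributions; `lifelines` is used in the test suite as an independent
cross-check of the log-logistic MLE, never as the implementation. Ranking
is by AIC, ties broken by BIC then family name — a documented,
deterministic order.

## Economics

Costing conventions, each exposed as data or a flag so alternatives can be
explored:

- **Dosing.** Cadonilimab 10 mg/kg on day 1; capecitabine 1,000 mg/m²
  twice daily on days 1–14 (28 administrations/cycle); oxaliplatin
  130 mg/m² on day 1. Cohort weight is the sex-weighted mean
  `0.784 × 69.6 + 0.216 × 59.0 ≈ 67.31 kg`; BSA 1.72 m².
- **Vial rounding.** `round_up` by default (whole vials, wastage
  discarded — usual hospital dispensing); `exact_mg` charges fractional
  vials for calibration comparisons.
- **Treatment duration.** Drug acquisition accrues on PFS occupancy up to
  per-component caps translating the median treatment durations into
  cycles (cadonilimab 5.62 months ≈ 8 cycles; CAPOX ≈ 6 cycles both arms).
  Weighting an "until progression" rule by PFS occupancy would overstate
  acquisition cost because the trial's median time on treatment is far
  shorter than modelled PFS; the uncapped mode remains available as
  `treatment_cap_mode: until_progression`. The cap is per component
  (cadonilimab and CAPOX stop at different times), a slight generalisation
  of a single regimen-wide cap, which is also still supported.
- **Adverse events.** The four grade ≥3 events reported for both arms
  (decreased platelet/neutrophil/white-cell counts, anemia) are charged
  once at model start as incidence-weighted one-off costs, with matching
  utility *decrements* for one cycle. The published table labels the AE
  values (0.65, 0.20, 0.20, 0.07) as utilities, but values like 0.07 are
  implausible as absolute health-state utilities and are interpreted as
  decrements. All four events are costed, including the one below the 10%
  incidence cut in one arm, because all four are priced in the source
  table.
- **Downstream care.** A fixed fraction of progressors (34.4% / 47.9% per
  arm) receives subsequent chemotherapy (paclitaxel + cisplatin-equivalent,
  184.44 USD/cycle) for a 6-cycle course; course occupancy is obtained by
  convolving new PD entrants (the per-cycle decline of the PFS curve —
  deaths from PFS cannot be attributed in a PSM, so every PFS exit counts
  as a progression) with the course window, capped by PD occupancy. Best
  supportive care (248.00 USD/cycle, read as per-cycle since no period is
  stated) covers PD occupancy not on subsequent therapy. Follow-up, labs
  and CT accrue on all alive occupancy (whether monitoring should stop at
  progression is unstated; "all alive" is the conservative reading).
- QALYs: `Σ (pfs·u_PFS + pd·u_PD) × cycle_years × discount`, minus the AE
  decrement burden. The category breakdown sums to the total exactly, and
  ICER·ΔE reproduces ΔC to 1e-6 relative — both are tested invariants.
  Equal-effect comparisons are labelled (`equivalent`/`undefined`) rather
  than propagating a division by zero, and dominance is labelled instead
  of reporting a negative ICER.

## Sensitivity analysis

- One-way: each registered parameter moved to base×0.75 and base×1.25 with
  all others at base (exactly two model evaluations per parameter), sorted
  by ICER spread. A parameter whose perturbation eliminates the
  incremental effect is flagged undefined, not fatal.
- Probabilistic: 1,000 iterations by default; every registered parameter
  drawn jointly and independently per iteration — Beta for probabilities,
  utilities and the discount rate; Gamma for costs. Distributions are
  calibrated by method of moments with the ±25% range read as a 95%
  interval (`sd = (high − low)/3.92`), so every distribution's mean equals
  its base value exactly. Body surface area is listed with a Beta law in
  the source table but exceeds 1, so it is sampled as Gamma instead.
  Survival parameters (γ, λ) are not sampled: no distributions are
  reported for them. No correlation structure is imposed (none is
  reported); independent utility draws therefore occasionally invert
  u_PFS ≥ u_PD, which is expected sampling behaviour. Draws outside a
  parameter's valid domain would be rejected and resampled (counted in the
  result); with Beta/Gamma laws on their natural domains this is a
  safeguard, not a frequent event.
- Cost-effectiveness uses the net monetary benefit rule
  `NMB = WTP·ΔE − ΔC ≥ 0`, which handles negative ΔE without ICER sign
  ambiguity; the CEAC applies the same rule across a WTP grid, so the CEAC
  value at the configured WTP equals the scalar acceptance probability by
  construction. Given a seed, the PSA is reproducible byte-for-byte.

## Synthetic data

`simulate_ipd` draws event times by inverse-CDF sampling from a known
model and censors them with an independent uniform window whose upper
bound is bisected to hit a target censoring fraction (administrative
truncation at the follow-up limit; unreachable targets warn with the
achieved fraction). `simulate_digitized_curve` emulates reading (time, S)
pairs off a printed Kaplan-Meier figure: Gaussian reading noise, clipping
to [0, 1], an exactly-read anchor point S(0) = 1, and re-monotonisation by
running minimum. These generators emulate *clean* reconstruction — no
at-risk-table anchoring, no interval censoring, no correlated digitisation
error — so passing recovery tests demonstrates correctness of the fitting
machinery, not robustness to every artefact of real curve reconstruction.

## Known limitation: the published inputs do not reproduce the published outputs

The fixtures transcribe the published parameter table verbatim, and the
engine implements the printed survival form faithfully. Under those
inputs, however, the published base-case results cannot be recovered, for
reasons intrinsic to the inputs rather than to any calibration flag:

1. The chemotherapy-arm OS parameters (γ = 1.92, λ = 0.010; months) imply
   an *infinite-horizon, undiscounted* mean survival of
   `(1/λ)^(1/γ) · (π/γ)/sin(π/γ) ≈ 18 months`, which caps that arm's
   QALYs near 1.2 even before discounting — below the published 1.49
   discounted QALYs. No occupancy or discounting convention can bridge
   this.
2. The CPS ≥ 5 cadonilimab curves lie below the all-randomized
   cadonilimab curves at every time point, yet the published analysis
   reports *more* QALYs for the subgroup (3.05 vs 2.57). With common
   utilities this ordering is impossible for any model driven by the
   printed parameters.
3. The published 10-year mortalities (67%/93%) imply mutually
   inconsistent time scalings of the printed parameters.

The likely explanation is that the original model ran on digitised
survival-curve tables over the follow-up window (with parametric
extrapolation only beyond it), or on parameters other than the printed
ones. Those curve tables are not published, so this package treats the
printed formula and parameters as authoritative and reports what they
actually imply. The acceptance tests encode the published values at face
value and are left failing where the inputs cannot reproduce them; the
flags (half-cycle correction, vial rounding, treatment caps, monitoring
scope) change costs by far less than the gap and change occupancy not at
all.

## Problem sizes

Default runs use 174 cycles (10 years), 348 for the 20-year scenario;
PSA: 1,000 iterations, replicated over 10 seeds where a mean probability
is reported; parameter-recovery checks: n = 5,000 subjects, 20% censoring,
20 seeds.
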