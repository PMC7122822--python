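# Methods

This note documents the model implemented in `gridfish`, the choices made
where the design was genuinely open, what the synthetic study system does
and does not emulate, and the known limitations.

## Model structure and process order

The simulator advances an age-structured abundance array `N[a, i]` (age ×
planning unit) on a monthly clock. Within a month the engine applies, in
this order:

1. **Spawning month (May) only:** spawner influx, then recruitment.
2. **Mortality and catch.** Baranov catch is computed from the
   start-of-month abundance and the same `F·Sel_a + M/12` used for
   survival, so the biomass decline in a PU before movement exactly equals
   catch plus natural deaths (asserted to 1e-9 in tests).
3. **Dispersal.** Emigrants `ω·m_i·N` leave PU *i* and split evenly among
   its rook neighbours. The update is mass-conserving by construction: each
   PU's emigrants are divided by *its own* neighbour count. (A naive
   reading of the movement sum without that division creates fish; the
   even-split rule is the only interpretation consistent with mass
   balance, which is enforced as a hard test.)
4. **November only:** all-ages outflux.
5. **January only:** age advancement into the plus group.
6. **Effort reallocation** for the next month from this month's CPUE.

Recruitment uses the spawning biomass *after* the influx, since the influx
represents spawners arriving to spawn; `S` is read at the start of the
step, before that month's mortality.

### Rates and units

* Annual natural mortality `M` (yr⁻¹) is divided by 12 for the monthly
  step. Annual fishing effort is handled by the fleet budget below.
* Recruitment is density-based: spawning biomass is converted to kg/km²
  per PU, the Beverton–Holt map applied, and the recruit density rescaled
  by PU area. This makes the spawner-recruit parameters (α = 0.14,
  β = 6.674·10⁻⁵, estimated on per-area values) independent of cell size.
* The influx (61.33 %) multiplies the current *mature* stock
  (ages ≥ maturity age, default 1) and distributes the immigrants over PUs
  proportionally to the current month's fitted HSI. The baseline of this
  rate is ambiguous in principle (resident stock vs an external pool);
  resident-stock multiplication is the default and the weights argument of
  `seasonal_influx` exposes alternatives.
* The outflux (53.51 %) scales every age × PU cell.

## Habitat-driven movement

Each PU's monthly HSI series is fitted with a single annual harmonic,
`HSI(t) = mean + A·sin(2πt/12 + φ)`, by ordinary least squares on the
linearized sin/cos design — no starting values, global optimum within the
family, and a constant series cleanly yields amplitude 0. The basic
movement rate is the fitted curve reflected over y = 0.5 and lagged:

    m(t) = clamp(1 − HSI_fit(t − lag), 0, 1).

* **Lag** defaults to 1 month (a delayed behavioural response on the
  model's own clock); it is configurable per movement field.
* **Clamping** is applied after reflection, so fitted values outside
  [0, 1] (possible for sparse or extreme series) produce movement rates
  saturated at 0 or 1 rather than errors.
* Higher harmonics are deliberately excluded: seasonality is the signal of
  interest and a 12-month sinusoid keeps the parameterization identifiable
  from as few as 3 observed months.

## Fleet model

Effort is expressed directly as fishing mortality at full selectivity
(catchability 1). The annual budget is
`F_T = F_base (1 + n_c/n_o)(1 + PU_c/PU_o)`: closures redistribute rather
than remove pressure. The engine divides `F_T` equally over the year's
open months and splits each month's budget over open PUs with weights
`(CPUE_i·x_i)^v`. Conventions, all of which matter only at edges:

* CPUE is defined as 0 where F = 0 (closed or unfished PUs).
* Closed PUs receive zero effort even at v = 0 (the openness mask
  dominates the zeroth power).
* When every open PU has zero weight — the first month, or the month after
  a seasonal closure, when the previous month's CPUE is identically
  zero — effort is spread uniformly over open PUs.
* A year with `F_annual = 0` allocates nothing, which also permits
  fully-protected domains; positive effort with no open PU is a
  configuration error.
* Reallocation is monthly, using the previous month's CPUE (the
  information lag fishers actually face); an annual cadence would be a
  one-line change but monthly is the default.

## Stochasticity

Three multiplicative lognormal error sources, all LN(0, 0.2) by default:
recruitment (one draw per year, shared across PUs), movement rates (per PU
per month, clamped back into [0, 1]), and the aggregation exponent *v*
(per month; where the fisher-knowledge error enters is not uniquely
determined — perturbing *v* is the default choice because the error is a
statement about knowledge of CPUE, which *v* encodes). Replicate RNG
streams are spawned deterministically from one master seed.

Note that only recruitment error moves *total* biomass: movement noise
conserves mass and effort noise only redistributes catch. With the default
parameters recruitment contributes little biomass, so ensemble bands on
totals are narrow; per-PU series vary much more.

## Calibration

The movement coefficient ω and aggregation factor v are estimated by
minimizing the sum over survey years of squared differences between
observed and simulated September per-PU biomass after Δ-distribution
standardization: z-scores of log biomass over the PUs positive in *both*
surfaces (pairwise deletion; zeros carry no log-scale pattern
information). The engine runs deterministically (all σ = 0) during
calibration. The optimizer is an iterated zooming grid search — a coarse
grid over ω ∈ [0, 1], v ∈ [0, 3] followed by refinements centred on the
incumbent — which is derivative-free, reproducible, and monotone in the
incumbent objective. Ties break toward smaller ω, then smaller v, and a
grid whose evaluations are all equal triggers a flat-objective warning.

**Identifiability.** On the default synthetic system, ω is well
identified: dispersal moves a first-order fraction of every PU's stock
each month, so the September surface responds strongly. *v* is not: the
September survey falls in the first open month after the June–August
closure (when the allocation has reset to uniform), the May influx
redistributes 61 % of the mature stock along habitat each year, and
dispersal diffuses what fleet imprint remains — so the objective is
nearly flat in *v* and observation noise dominates. Parameter-recovery
experiments recover ω within ±0.05 under LN(0, 0.2) observation noise,
while v̂ is noise-driven. Calibrating *v* in practice requires data that
observe the *fleet* (effort or catch distributions), not an annual
biomass snapshot; this is a property of the survey design, not of the
optimizer, and the corresponding recovery test documents it by failing
on the v half.

## Economics

Revenue discounts the monthly catch stream at `r/12` with t counted from
1. The establishment and maintenance cost power laws are evaluated with
the reserve area in km² and returned in dollars; maintenance is linear in
the implementation horizon. The cost laws are used undiscounted, matching
their published empirical form; revenue-vs-cost NPV is computed per
revenue quantile of the ensemble. On the small synthetic system NPVs are
negative — a 10×10 toy fishery's revenue cannot carry real-world MPA
maintenance costs — the table's mechanics, not its sign, are the point.

## Synthetic study system

The fixture generator emulates the structure of a coastal trawl-fishery
study: a 10×10 lattice of 9 km² planning units (large enough for
boundary/interior adjacency heterogeneity, small enough for sub-second
runs), spatially smooth sinusoid parameters for HSI built from
low-frequency random cosine surfaces, an initial stock of 10⁶ kg placed
proportionally to January habitat, block or top-habitat reserves scaled
from the reference schedule (158→209 of 4815 PUs, and a 60-PU
alternative), and September "survey" surfaces generated by the model
itself with multiplicative lognormal noise.

Choices worth flagging:

* **HSI contrast.** Mean suitability spans [0.05, 0.95] across the
  domain. Habitat maps of real coastal systems span essentially the full
  unsuitable-to-optimal range, and the log-scale survey comparison is
  only informative when the biomass surface varies on the log scale; a
  low-contrast field would make the standardized comparison
  noise-dominated.
* **Weight-at-age** is a synthetic stand-in, `W_a = 0.01·(a+1)^1.5` kg
  (ages 0–5 with a plus group), since no weight schedule accompanies the
  other reference parameters. Selectivity defaults to 1 at all ages.
  Under these weights recruitment replaces little biomass, so the default
  system declines over the seven years — the wintering outflux exceeds
  the spawning influx plus recruitment. That is a property of the
  stand-in schedule, not of the engine.
* What passing tests on this system show: the mechanics (conservation,
  accounting, ordering, calibration behaviour) are correct. What they do
  not show: that the default parameters describe any real stock —
  hindcasting a real fishery requires its survey layers.

## Numerical details

* Dispersal uses a dense column-stochastic redistribution matrix built
  once per domain; isolated PUs keep their fish.
* The Baranov 0/0 case (no mortality at all) is defined as zero catch.
* Quantile summaries use the empirical quantiles of the replicate matrix;
  with all σ = 0 every quantile collapses onto the deterministic run.
* Degenerate inputs are errors, not silent repairs: fewer than 3 months
  for a sinusoid fit, fewer than 2 positive values (or zero log-variance)
  for standardization, a fully closed fishery with positive effort.

## Limitations

* Single species, single fleet; no larval dynamics; natural mortality and
  movement do not vary with age or size.
* No emigration across the domain boundary except the November outflux;
  boundary PUs simply have fewer neighbours.
* The fleet aggregation factor is weakly identified from annual biomass
  surveys (see Calibration above).
* Coordinates are opaque map units; no projections or shapefile support.
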