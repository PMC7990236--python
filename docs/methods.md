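# Methods

This note documents the model equations as implemented, the parameter
choices that matter, what the synthetic forcing emulates (and does not), and
the numerical decisions a user should know before trusting a run.

## Model structure and assumptions

The watershed is discretized into five sub-watersheds (EAQ, Rustlers, Copper
→ ME → LT; LT's outlet is the watershed terminus). Each sub-watershed is
three well-mixed boxes of water — vadose zone, groundwater, stream — and
each box carries NH4+, NO3− and DON pools in mol. Key assumptions inherited
from the box-model design:

- **Lumped kinetics.** Rates represent sub-watershed totals; processes that
  are locally exclusive in reality (e.g. denitrification in saturated
  patches during the growing season) run concurrently at the box scale.
- **Dissolved N only.** Particulate organic N, gas speciation (N₂ vs N₂O),
  DNRA and sorption are out of scope.
- **Hydrology is forcing, not state.** Storage volumes and the two net
  boundary fluxes are inputs; the inter-compartment flows are recovered by
  closing each box's water balance analytically (exact inversion, verified
  by re-integration in the tests). The model never solves flow physics.
- **Hourly step, daily parameters.** Rate constants are day⁻¹ and are not
  meant to resolve diel cycles; the hourly step (Δt = 1/24 day) exists for
  hydrologic fidelity and integration accuracy.

### Advective coupling and dimensional corrections

Three printed-form conventions common to this model family are implemented
in their dimensionally consistent versions:

1. Vadose advection uses the concentration form `Q_s·N/V_s` (flow ×
   concentration), consistent with the residence-time forms `N/τ` used for
   interflow and groundwater discharge.
2. The land-cover-weighted vadose rate constants (nitrification,
   mineralization, denitrification) carry no area factor: a day⁻¹ constant
   multiplies a pool mass directly. The area factor is retained in the
   maximum-uptake expression, where it converts an areal rate
   (mol m⁻² day⁻¹) into mol day⁻¹.
3. Stream-to-groundwater recharge transports N at the stream concentration,
   `(N_r/V_r)·Q_g`.

One further choice is forced by mass conservation: when the vadose outflow
is negative (upward flow from groundwater), the vadose zone gains N at the
*groundwater* concentration `|Q_s|·N_g/V_g` — exactly what the groundwater
box loses. Valuing the gain at the vadose concentration (as a literal
reading of the vadose advection term would imply) silently creates or
destroys mass; with the consistent form the whole-system ledger closes to
floating-point precision.

### Temperature responses

- Soil: α = ϑ_s^((T_soil−5)/2) with ϑ_s = 12, multiplying uptake maxima and
  vadose rate constants. This response is extremely steep: α ≈ 500 at 10 °C
  and ≈ 1.3×10⁸ at 20 °C. It is implemented verbatim (ϑ_s configurable); a
  runtime warning fires when α exceeds 10⁶, and the synthetic forcing keeps
  soil temperatures ≤ 20 °C. Under warm soils the vadose inorganic pools
  become stiff relative to the hourly step — see the limiter below.
- Stream: k(T) = k20·ϑ_r^(T_water−20), ϑ_r = 1.07, applied to in-stream
  nitrification, uptake, denitrification and mineralization (the in-stream
  mineralization constant, 1.5 day⁻¹ at 20 °C, is one constant wherever
  stream mineralization appears).
- Groundwater: k_den = k_max·ϑ_g^(3.8−T_gw), ϑ_g = 0.3, referenced to the
  3.8 °C maximum groundwater temperature, gated on Q_s > 10⁵ m³ day⁻¹
  (denitrification only during rapid recharge). T_gw is the watershed-wide
  mean of the sub-watershed soil temperatures.

## Parameters

- **Watershed geometry** (areas, land-cover fractions, shale fractions,
  routing) is packaged as `EAST_RIVER`; totals 8.477×10⁷ m².
- **Scenario sets C1–C3, NM1–NM2, NC** package the published calibration
  table verbatim: vadose rate constants per land cover, litter interval
  rates, in-stream k20 values, groundwater k_max, and the weathering rates
  (moderate M_o = M_n = 7.5×10⁻⁶, M_a = 2×10⁻⁷ mol m⁻² day⁻¹; the high
  scenario three times that; the no-shale scenarios zero). NC sets the herd
  to zero and raises litter.
- **Deposition.** Wet concentrations are the long-term precipitation means
  (0.0068 NH4+, 0.011 NO3− mol m⁻³) with DON as 25% of TDN (0.00593
  mol m⁻³ by the closed form). Dry rates are scaled so watershed annual
  totals are 7.99×10⁴ / 1.73×10⁴ / 3.24×10⁴ mol yr⁻¹ (NH4/NO3/DON): the
  per-area station figures as published carry a unit error of about six
  orders of magnitude (their implied annual totals contradict the published
  totals while the species ratios agree), so the totals — which are
  internally consistent — are taken as authoritative.
- **Uptake table.** The per-cover Monod maxima and half-saturation
  constants are not published in the primary table; the shipped defaults
  are literature-plausible magnitudes (F_max of order 10⁻⁵–10⁻⁴
  mol m⁻² day⁻¹; K_m of order 10–20 µM) and are plainly labeled as
  defaults. Every value is overridable; conclusions that depend on the
  absolute uptake magnitude (e.g. the ±10% balance diagnostics) should be
  drawn only after site-specific calibration.
- **Baseflow index.** The seasonal β values are site-calibrated quantities
  not available here; the shipped defaults (winter 0.9, rising 0.5, falling
  0.6, monsoon 0.7; season windows at day-of-year 305–59, 60–151, 152–212,
  213–304) are placeholders with the right qualitative structure.
- **Stream temperature** uses a configurable affine map
  T_water = max(0, a + b·T_air), default (3.5, 0.6) — a literature-derived
  stand-in for a site regression, floored at 0 °C.
- **Cattle.** 500 head delivering 23.6 mol DON head⁻¹ day⁻¹ to soil; herd
  in LT day-of-year 196–251 (G = 1), then split 0.6/0.2/0.1/0.1 over
  ME/Copper/EAQ/Rustlers through day 288.
- **Fixation.** One uniform draw per sub-watershed per day in
  [10⁻⁸, 10⁻⁴] mol m⁻² day⁻¹ over 1% of the meadow area, active above
  0 °C soil. Draws are keyed by (seed, sub-watershed id), so results are
  independent of declaration order.

## Synthetic forcing

The generator emulates the hydrologic regime the model was built for:
near-zero infiltration under the winter snowpack, a March–June half-sine
melt pulse (default peak 6 mm day⁻¹) carrying ≥ 95% of the annual positive
infiltration, Poisson-distributed August–October monsoon storms, a small
summer soil-ET draw that makes net infiltration negative, and seasonal
air/soil temperature sinusoids (soil damped, lagged and clipped to
[−5, 20] °C). Storage volumes are produced by routing the input through toy
linear reservoirs (vadose → groundwater → stream, split by the seasonal β),
so storages recede coherently after the melt and the back-calculated flows
are non-negative — mirroring spatially aggregated integrated-hydrology
output. Baseline drainage is proportional to storage, so volumes are
structurally positive.

What the generator does **not** emulate: inter-annual snowpack variability,
upward vadose–groundwater flow reversals (exercised in tests with hand-built
forcing instead), spatial heterogeneity within a sub-watershed, and the
absolute magnitude of the spatially integrated infiltration flux of a
gridded model (which also carries re-infiltrating runoff). Consequently,
passing tests demonstrate structural correctness — conservation, routing,
kinetics, scenario contrasts — not that simulated concentrations match field
data; budget *shares* on synthetic forcing differ from those obtained under
the historical hydrology.

## Numerics

- **Integration**: classical RK4, hourly. Verified fourth-order on linear
  decay (error ratio ≈ 16 when halving the step) and accurate to ≤ 10⁻⁸
  relative against the analytic exponential over an e-folding time at
  k·Δt ≤ 0.1.
- **Ledger-exact conservation**: each step's four stage flux evaluations are
  combined with the RK4 weights (1/6, 1/3, 1/3, 1/6), and the state update
  is computed *from* the combined fluxes through a fixed incidence
  structure. Integrated ledger totals therefore reproduce the state mass
  change to machine precision, and nitrification/mineralization are
  zero-sum across species by construction.
- **Non-negativity limiter**: if the combined fluxes would drive a pool
  negative over the step, all outflows of that pool are scaled down by
  (N/Δt + inflow)/outflow (fixed-point iteration, scalings only decrease,
  with a conservative inflow-free final pass). This preserves conservation
  exactly and is the quasi-equilibrium limit for pools made stiff by the
  soil-temperature factor; engagements are counted and logged. Stage
  evaluations clip negative intermediate pools to zero before computing
  fluxes.
- **Routing** is stage-consistent: upstream stream export (N_r/τ_r) feeds
  the receiver inside the same RK4 stage, avoiding a one-step lag. Results
  are independent of the order in which sub-watersheds are declared.
- **Degenerate flows**: residence times are undefined (NaN), not zero, when
  the corresponding flow is ≤ 0; export/exchange fluxes gate on flow
  direction. A negative stream balance is floored at zero discharge with
  the deficit logged. Negative net infiltration removes vadose N at the
  precipitation concentration (the literal reading of the wet-deposition
  term); `clamp_wet_deposition` floors the term at zero instead (default
  off).
- **Initialization**: explicit pools, fixed starting concentrations
  (defaults of order 1–20 µM per compartment), or spin-up that repeats the
  first 90 days of forcing (the non-growing season of a water-year start)
  until no subsurface pool changes by more than 1% per repeat (max 20
  repeats, warning on non-convergence). The published initialization
  procedure is an iterative manual adjustment and is not reproducible
  verbatim; the spin-up rule is this package's replacement.
- **Water-year bookkeeping**: budgets run Oct 1–Sep 30; the budget function
  refuses partial years. Leap years are handled through calendar-aware
  day-of-year in the litter intervals.

## Problem sizes

The test suite and the acceptance script run the full five-sub-watershed
model at hourly resolution for one to two simulated years (8 760–17 519
steps; a few seconds per simulated year on one CPU), with 30–120 day runs
for scenario-contrast checks. These sizes were chosen as the shortest runs
that exercise a full seasonal cycle (melt, growing season, monsoon, winter)
and a complete water-year budget.

## Known limitations

- The soil-temperature response with ϑ_s = 12 is implausibly steep at warm
  soils; above roughly 12 °C the vadose inorganic pools operate in the
  limiter's quasi-equilibrium regime rather than the resolved-kinetics
  regime.
- Uptake parameters and β are placeholders (see above); the ±10% balance
  diagnostics are meaningful only after calibrating them to a site.
- Equifinality is a feature of the problem, not a defect of the code: the
  six scenarios fit the same stream nitrate about equally well while
  implying weathering shares from 0% to tens of percent. Conclusions about
  source apportionment should always be reported across scenarios.
- The model cannot track the provenance of an N atom once it enters a pool;
  "new N" accounting is flux-based, not isotopic.
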