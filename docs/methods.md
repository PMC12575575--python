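# Methods

This note documents the models, defaults and design choices behind
`catchex`, and what the test suite does and does not establish.

## Scope and structure

The package forecasts forestry-induced nitrogen and phosphorus exports from
a boreal catchment over a 50-year horizon divided into 10-year periods, for
every combination of one management system (RF, ERP, CCF, none) and one
water-protection practice (none, ponds, dams, wetlands, riparian).  The
unit of simulation is the forest compartment; there is no hydrological
routing between compartments and no in-stream processing — exports are
accounted at the compartment edge and summed per land class, which is the
appropriate resolution for ranking management options rather than
predicting concentrations at a river mouth.

Two land classes generate exports: mineral-soil forest (operation pulses
only) and drained peatland (operation pulses plus the drainage legacy).
Undrained peatland and non-forest land are carried in the register for
area bookkeeping but are unmanaged and export-free in this accounting;
their natural background load is outside the forestry-induced budget.

## Drainage legacy

The August water-table level of each drained-peat compartment is evaluated
annually from its current growing-stock volume with an empirical regression
(sign convention: positive cm = depth below the soil surface).  The
regression's inputs and defaults:

| symbol | meaning | default | unit |
|---|---|---|---|
| V | growing-stock volume | simulated | m³/ha |
| S | mean monthly summer (Jul–Aug) precipitation | 70 | mm |
| D | average ditch depth | 60 | cm |
| LAT | northern latitude | 65.0 | ° |

S = 70 mm/month is consistent with ~520 mm annual precipitation in the
central-boreal zone; D = 60 cm is the typical depth where more than a
decade has passed since ditch maintenance.  Latitudes outside 59–71 °N are
outside the regression's calibration domain and trigger a warning.

The WTL→export response is the package's main calibration placeholder.
The underlying process-simulator curves are published only graphically, so
the default is a piecewise-linear hinge per fertility class,
`export = slope × max(0, WTL − 30 cm)`, with N slopes 0.040 / 0.032 /
0.024 / 0.017 kg ha⁻¹ yr⁻¹ cm⁻¹ (herb-rich → xeric) and P slopes about a
factor 9 smaller.  The slopes were fixed once so that the catchment-mean
first-period legacy N export of a default mature synthetic register falls
in the 0.3–0.6 kg/ha/yr band characteristic of catchment-scale scenario
studies; users with access to calibrated response curves should replace
them via `LegacyResponse` / `legacy_response.yaml`.  Because of this, all
legacy-related tests target curve *properties* (monotonicity, fertility
ordering, zero anchor), never absolute values.

## Operation exports

Export coefficients (kg/ha/yr by years-since-treatment, year 1 = first
year after the operation) are compiled in for DNM, mineral-soil N
fertilization (ammonium nitrate), drained-peat ash fertilization and
mineral-soil clear-cutting, and are overridable from `coefficients.yaml`.
Three conventions matter:

* The DNM columns already embed the suspended-solids N and P
  concentrations and the removal of the assumed 30% water-protection
  reduction from their source data; nothing is re-applied.  Their constant
  P:N ratio (~0.072) identifies them as purely particulate, and DNM ledger
  entries carry a `particulate` flag that settling structures target.
* Harvests on drained peat — clear-cut, thinning or selection cut alike —
  export at a level logistic in the removed stem volume, held constant for
  4 years (sub-xeric or poorer) or 6 years (mesic or better).  No
  within-duration decay is applied because none is published.
* Partial harvests on mineral soils are export-free; only clear-cuts (and
  seed-tree fellings, which remove comparable volumes) use the mineral
  schedule.

A treatment dated to the mid-period year therefore contributes the first
five years of its schedule to its own period — the residual tail spills
into the next, and pre-simulation fellings (negative event years) spill
into period 1.

## Stand dynamics surrogate

The individual-tree growth, survival, ingrowth and taper model chains used
by operational forestry simulators are not publicly tabulated, so growth is
a deliberately simple cohort model chosen for qualitative fidelity:

    dd/dt = base(fertility) · (TS/1000 dd) · d/(d+5 cm) · e^(−0.03·G) · m(origin)

with base increments 0.45 / 0.40 / 0.32 / 0.25 cm/yr (herb-rich → xeric),
stand basal area G in m²/ha, origin multipliers 1.10 (planted) and 1.05
(seeded), constant background ingrowth (20 stems/yr damped by basal area)
into a seedling cohort, and 0.5%/yr mortality.  Cohort diameters move
continuously (no re-binning onto a fixed grid), so the model integrates its
own rate law to within Euler error — a test checks single-cohort growth
against `scipy.integrate.solve_ivp` to 1%.  N fertilization and DNM boost
the increment by +15% for 10 years (a simplified stand-level response;
ash fertilization on peat is treated the same way).  Volumes come from a
two-parameter single-tree function v(d) = 2.54·10⁻⁴ d^2.3 m³.

The management rule engine follows the published rule set: final felling
when mean diameter exceeds a threshold (ERP: ×1.10), thinning from below
(RF) or above (ERP) to a post-thinning basal area when a limit is crossed,
CCF selection cuts above a basal-area threshold linear in mean diameter
with removal intensity increasing toward larger cohorts, fertilization and
DNM windows exactly as published.  Felling diameters (24–28 cm by
fertility), thinning limits (20–26 → post 13–17 m²/ha) and the CCF
threshold parameters are *recommendation-style configuration defaults*,
not published constants; the CCF defaults give 15–25-year cutting cycles.
Within a period, treatments are evaluated felling → thinning/selection →
fertilization → DNM; the published procedure does not state this order, so
it is configuration by convention here.  DNM is evaluated only under
rotation systems: continuous cover forestry never clear-cuts, so the
post-felling water-table rise that ditch maintenance remedies never
occurs.  Tending is a scheduled no-op event (its growth effect is
unstated); seed-tree felling on xeric pine removes the full stand volume
and is treated as a clear-cut for export purposes, with natural
regeneration instead of planting.  Mid-rotation xeric stands not dominated
by pine regenerate like sub-xeric ones (pine seeding).

## Water protection

Pond and dam retention uses a saturating-exponential fraction
`f(L) = 0.40·(1 − e^−(L−L₀)/K)` of the particulate DNM load above the
structure, with L₀ = 0.5 and K = 2 kg/ha/yr on the N scale.  The
exponential (rather than Michaelis–Menten) form was chosen so the curve
actually attains the published 40% peak within the observed load range.
P loads are an order of magnitude smaller, so the P-axis parameters
default to the N values scaled by the suspended-solids P:N ratio 0.072.
No peak retention is published for peak-runoff-control dams; the default
mirrors the pond curve and is flagged configuration.

Wetland-buffer retention subtracts the non-forestry background (N 1.3,
P 0.025 kg/ha/yr) from the load above the buffer and applies a logistic
fraction (max 0.90) of the forestry-induced remainder, evaluated on each
compartment-year total and allocated proportionally across sources.  The
source data contain no N loads below 0.6 kg/ha/yr; the default curve's
behaviour below that (fraction < 0.5) is an extrapolation.  Riparian
buffer zones apply a flat, load-independent fraction — 12% at 3% areal
coverage, +5 percentage points per coverage doubling — to every
mineral-soil forestry entry.  Ponds and dams are instantiated per DNM
event's contributing area, and one practice applies per scenario; a ledger
provenance check rejects double application.

## Synthetic catchment generator

No stand register is deposited for the study region, so the generator
draws one: 2000 compartments by default, land-class areas rescaled so the
class shares (mineral 0.40, drained peat 0.315, undrained peat 0.211,
non-forest remainder) and the 3824 km² total are matched exactly;
compartment areas log-normal (median 3 ha — compartment sizes are not
published); initial stands from truncated-Weibull 2-cm diameter classes
with per-fertility mean-diameter and basal-area ranges; 10% of mineral
compartments carry a pre-simulation clear-cut in years −1…−9 so that
residual exports appear in the first period even without management (the
rate is not published; 10% reproduces the qualitative first-period
signal).  The fertility composition per land class is a placeholder — no
breakdown is published for the region — and is flagged as such here; all
of it is configuration.  The generator is deterministic under its seed
(byte-identical CSV output).

What the generator does *not* emulate: spatial arrangement and routing,
age-class legacies of real management history beyond the single
pre-simulation cut, mixed-species cohort structure, and the actual
fertility distribution of any real catchment.  Passing scenario-ordering
tests on these registers therefore demonstrates that the *model logic*
produces the published qualitative rankings under plausible boreal stand
states — not that the package reproduces any real catchment's export
magnitudes, which would require the proprietary stand data.

## Numerical choices

* Growth integrates in 1-year Euler steps; treatments at mid-period.
* Thinning removes continuous (fractional) stems per hectare, making
  removal plans order-independent; cohort splits conserve basal area by
  pooling at the quadratic-mean diameter.
* The CCF removal plan solves its intensity scaling by water-filling with
  a 0.98 per-cohort cap, so planned and realized basal-area removal agree
  to 10⁻⁶ m²/ha whenever the cap is not binding.
* Retention fractions are clamped to [0, 1); negative reductions are
  clamped to zero.
* All randomness flows through `numpy.random.default_rng` seeded from the
  catchment config and scenario spec; identical inputs give identical
  ledgers, byte for byte.
* Qualitative-ordering tests use 2000-compartment registers over 50 years
  and 20 seeds — large enough for stable class aggregates while keeping
  the full suite within a few minutes on one CPU.

## Known limitations

* Export magnitudes inherit the legacy-response calibration placeholder;
  only the printed constants (coefficient schedules, regression and
  logistic parameters, retention anchors) are exact.
* The growth surrogate is not calibrated to any inventory; rotation
  lengths and harvest volumes are plausible, not predictive.
* One protection practice per scenario; combined practices, restored
  (initially nutrient-releasing) wetland buffers, ditch-mounding exports
  and economic optimization of harvests are out of scope.
* ERP is undefined on drained peatland (by design of the scenario set);
  the engine rejects it rather than guessing a peatland ERP rule.
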