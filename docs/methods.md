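# Methods

## Scope and model

`forestcarbon` is a bookkeeping model, not a process model. It takes
reported or measured quantities — burned area by source, compartment fuel
loads, yearly fuel-dynamics coefficients and combustion-completeness
fractions from an external fire-enabled vegetation model, harvested stem
mass, grazing fluxes, and inventory-time forest area and biomass carbon
density — and closes a mass balance. Nothing upstream is simulated here:
fire behaviour, fuel moisture, vegetation dynamics and grazing estimation
are all consumed as inputs.

The pipeline has four stages.

**1. Burned-area reconstruction.** A continuous national series is spliced
from a historical statistical compilation (authoritative before the switch
year) and a satellite land-cover product (authoritative from the switch
year on; overlapping historical values are logged and discarded, never
averaged). Regional, per-category series are assembled from state agency
tables aggregated over a fixed four-region partition (NE, SE, RM, PC).
Where the agency source discontinued the state & private category, that
component is backed out by subtracting the covered categories from a
regional published total; negative residuals are clamped to zero and
logged, since burned area cannot be negative and residuals at the observed
few-percent source-agreement level are reporting noise. Satellite class
tables (deciduous/evergreen/mixed forest resolved to a category by
ownership, shrub/scrub to "other forest", herbaceous excluded and
reported) cover the recent decades. A configured excluded window (default
1980–1984) and the listed agency missing years remain explicit gaps —
asserted, never interpolated into a balance. A config flag exists to
interpolate for plotting only.

**2. Burned biomass.** B(y) = BA(y) · Σ_c FL_c(y)·CC_c(y) · f_C, with
completeness applied per compartment and then summed. The per-compartment
form matters: the severity sub-variants of the sensitivity design replace
the completeness vector compartment-wise, which an aggregate factor could
not express. Fuel loads anchor a contemporary field-measured reference
period (default 2003–2015) and move through time by multiplicative yearly
change coefficients; the timeline is normalized so its reference-period
mean equals the base load exactly, compartment by compartment. Years before
the first modeled year (default 1941) take that year's loads and
completeness unchanged (constant extrapolation). Sparse "other forest"
carries only duff/litter, 1-hr dead wood and herb fuels; productive
categories carry all seven compartments. National-scale estimation, where
only aggregate burned area exists, uses a region-area × category-mix
weighted fuel term with weights from the configuration.

**3. Carbon balance.** For each closed interval between inventory points:
ΔC is the density difference divided by the interval length; each removal
term is the unweighted mean annual per-area flux over the half-open year
range (t0, t1], skipping gap years; NEP is their sum. Negative ΔC is
permitted and means unquantified losses (insects, windthrow, drought)
appear implicitly as reduced stock change — they are deliberately not
separate terms. The per-area denominator is the mean of the two endpoint
forest areas (config-switchable to start or end; logged). Period averages
are duration-weighted means, which preserve the balance identity exactly.
Cumulative offsets divide time-integrated component fluxes by
time-integrated NEP, so the three removal shares plus the stock-change
share sum to 100%.

**4. Sensitivity.** A purely factorial design: fuel source
(field-measured vs. modeled tables) × fuel dynamics (static
reference-period loads vs. coefficient-scaled) × a static severity
completeness set (low/moderate/high), per region — 12 variants per region,
48 over four regions. Envelopes are pointwise minima/maxima across
variants; the central estimate (field-anchored dynamic loads with modeled
completeness) is reported alongside and intentionally not clipped into the
envelope. Harvest uncertainty is spanned by minimum/maximum expansion
factors, the grazing band by input multipliers. Extra toggles outside the
canonical 48 (exclude duff; across-category average loads; aggregated
total-forest area) are available as flags on the variant runner.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| carbon fraction f_C | – | 0.5 | standard dry-matter carbon content; single constant for fuels and stocks |
| acre→hectare | ha/ac | 0.40468564224 | exact unit definition |
| switch year | yr | 1985 | first satellite year; historical compilation ends 1984 |
| excluded window | yr | 1980–1984 | regional sources unusable between agency end and satellite start |
| moving-average window | yr | 5 (odd) | smooths large interannual fire variability for decadal comparison |
| reference period | yr | 2003–2015 | span of the contemporary fuel-load field campaign |
| first modeled year | yr | 1941 | earliest fuel-coefficient year; earlier years constant-extrapolated |
| denominator mode | – | mean of endpoints | forest area changes between inventories; choice logged and switchable |
| interval set | yr | decades, with 1926–1930 and 1970–1977 exceptions | inventory availability |

## The synthetic-data generator

`generate_world` draws a complete ground truth and `render_sources` writes
it into the source families above. Burned area per state follows a
declining exponential trend with lognormal year-to-year variation, split
into categories by fixed shares (0.80/0.12/0.08); defaults give ~7 Mha/yr
early national burning falling well below 1 Mha/yr late, a mid-century
harvest peak (~110 TgC/yr stem), declining grazing, and eastern stock
recovery. Stock density is *constructed* from a prescribed NEP trajectory
minus the generated removals, so the balance identity holds exactly before
any observation noise and interval NEP equals the prescription — parameter
recovery is therefore a sharp test. Reporting noise (multiplicative
lognormal on reported, not true, values — burned areas are positive and
heavy-tailed) defaults to zero, because the real sources agree to within a
few percent; the truth process carries the variability instead. Coverage
defaults mirror the study conditions: census 1926–1984, agency tables
1941–1985 with the listed missing years and the state & private category
discontinued after 1960, regional totals 1938–1979, satellite from 1985.
The random stream is split per component (fire, coefficients,
completeness, harvest, grazing, reporting) by fixed sub-seeds, so changing
one component's parameters does not perturb the others.

What the generator does **not** emulate: spatial structure (no gridded
burning, no polygon intersection), climate forcing, autocorrelated fire
regimes, reporting biases that drift over time, within-region state
heterogeneity in fuel profiles, and forest-area change between inventories
(area is constant per geography by default so the constructive identity is
exact). Passing tests therefore demonstrate correctness of the accounting
machinery under the stated statistical structure, not fidelity to any real
reconstruction.

## Numerical choices

- **Order-independent sums.** Every aggregation (states→regions,
  classes→categories, categories→totals) uses `math.fsum`, which returns
  the correctly rounded sum regardless of addend order, so equal multisets
  of inputs give bit-identical totals.
- **Integer-hectare reporting.** The generator rounds reported burned
  areas to whole hectares, as the historical sources do. A convenient
  consequence: sums and differences of reported values are exact in
  binary floating point, making exact-recovery and subtraction-inference
  checks bit-clean rather than tolerance-dependent.
- **Power-of-two class splits.** The renderer splits forest categories
  into satellite classes with fractions 1/2, 1/4, 1/4, so re-aggregated
  class areas reconstruct the category value exactly.
- **Timeline anchoring.** Coefficient timelines are divided by their
  reference-period mean before scaling the base load; the anchoring
  property (reference mean equals base) then holds to rounding error.
- **Clamping.** Negative subtraction residuals clamp to 0 with a
  diagnostic record; nothing else is adjusted.
- **Degenerate inputs.** Empty variant lists, zero denominators,
  completeness outside [0, 1], non-positive coefficients, even smoothing
  windows, unmapped states/classes and gap-only windows all raise typed
  validation errors rather than propagating NaN. Two zero reports agree at
  100%; a zero against a positive report agrees at 0%.
- **Identity validation.** `BalanceInterval` refuses construction if
  |nep − (ΔC + Σ removals)| ≥ 1e-9 tC/ha/yr; the identity is validated,
  never forced.

## Problem sizes

Tests and the acceptance script run on 92-year worlds with 12 states in
four regions, 7 fuel compartments and ~10 national balance intervals;
identity and bias checks use 100 seeded replicates. These sizes keep the
full suite under a minute of compute per hundred worlds while exercising
every code path; all sizes are configuration, not constants.

## Known limitations

- No harvested-wood-product lifecycle: harvest is an instantaneous
  removal.
- No attribution of ΔC to drivers (CO₂ fertilization, age structure);
  unquantified disturbances fold into ΔC.
- Non-forest burning (grassland, cropland) is out of scope; the herbaceous
  satellite class is excluded by construction.
- The factorial envelope is a bounding-box uncertainty, not a probability
  band; extreme severity variants are known to be conservative outliers.
- Sub-annual or duplicate reports within one source are assumed resolved
  upstream (one record per year × geography × category × protection ×
  source); duplicates are rejected at parse time.
- Whether regional published totals include "other forest" is a
  convention; both are supported via a flag, and the generator and
  pipeline must agree on it.
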