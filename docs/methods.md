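# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Track preprocessing

Tracking tables carry one row per location with individual id, UTC
timestamp, lon/lat, device (GPS | PTT | GLS) and population metadata.
Preprocessing runs per population in a fixed order — standardise →
equinox strip → speed filter → colony buffer → resample — and the colony
buffer is re-applied after resampling so every retained point satisfies
every filter predicate simultaneously; the chain is idempotent
(re-running it changes nothing), which the suite asserts.

* **Standardisation.** Longitudes normalised to [−180, 180); per
  individual, rows sorted by time and duplicate timestamps dropped (first
  kept). All longitude arithmetic elsewhere goes through great-circle /
  vector operations, so tracks crossing the antimeridian need no special
  casing (interpolation unwraps longitude first).
* **Equinox stripping (GLS only).** Light-based latitudes are unusable
  near the equinoxes. Windows are −21/+7 days around 20 March and −7/+21
  days around 22 September (UTC midnight, inclusive endpoints). Fixed
  calendar dates are used: the ±1-day astronomical drift of the true
  equinox is negligible against ≥7-day window arms. Datasets whose
  latitudes were already corrected upstream (e.g. with sea-surface
  temperature) pass through unchanged via a per-colony flag.
* **Speed filter (GPS/PTT only).** Iterative forward pass: a fix whose
  implied great-circle speed from the last *retained* fix strictly
  exceeds 90 km h⁻¹ is dropped; the comparison is strict, so a fix at
  exactly 90 km h⁻¹ survives. Each individual's first fix seeds the pass.
  (The visual outlier checking applied to the original datasets is a
  manual step and is represented only by these deterministic filters.)
* **Colony buffer.** GPS fixes < 5 km and PTT fixes < 15 km from the
  colony are colony attendance, not at-sea use, and are dropped; GLS
  fixes are never trimmed because their ~200 km error dwarfs any buffer.
* **Regularisation.** GPS/PTT tracks are linearly interpolated in time
  and resampled at 12-h steps (two fixes per day — the GLS resolution)
  from each individual's first retained fix, never extrapolating past the
  last. Interpolation is linear in lon/lat, adequate at 12-h petrel step
  lengths and documented as the swap-in point for great-circle
  interpolation; gaps of any length within a deployment are spanned, and
  month-long gaps are handled downstream by the sample-size rule.
  Single-fix tracks are dropped with a logged warning.

Distances use the haversine formula on a sphere of radius 6371 km.

## Breeding phenology from distance to colony

Per population, locations are pooled across individuals and years by
calendar month. A month is **non-breeding** when its mean distance to the
colony strictly exceeds the unweighted mean of the tracked monthly means,
or when no pooled location came within the 200-km attendance radius (a
bird "at the colony" cannot be distinguished from one 200 km away at GLS
accuracy); ties on the grand mean are breeding, and a single tracked
month is breeding. Smoothing then enforces one season of each type on the
cyclic calendar (December adjoins January; untracked months are skipped):

1. isolated months whose tracked cyclic neighbours agree on the opposite
   label are flipped, sweeping in calendar order with in-place updates to
   a fixed point (each flip merges runs, so this terminates);
2. if more than one run of a label still remains (possible with e.g.
   alternating two-month blocks, which flipping cannot repair), the
   labelling is replaced by the two-arc cyclic labelling minimising
   disagreements, ties resolved by the first arc placement scanning from
   January.

Stage 2 is the package's resolution of an under-specified corner: the
one-pass re-classification rule alone cannot guarantee single seasons for
arbitrary label sequences, and the stated goal of the procedure is one
breeding and one non-breeding season.

Published monthly schedules, where available, take precedence — except
that a published breeding month in which no tracked bird came within
200 km of the colony is overridden to non-breeding (the tracked birds
demonstrably did not attend). Months absent from the schedule take the
inferred label. Labels therefore describe the tracked sample, not the
species' general phenology.

## Utilisation distributions

Monthly population-level UDs use fixed-bandwidth kernel density
estimation in a planar equal-area frame:

* **Projection.** Spherical Lambert azimuthal equal-area centred on the
  month's spherical centroid (normalised mean of unit vectors; degenerate
  antipodal inputs fall back to the first point, logged). The projection
  is implemented in closed form (R = 6371 km); equal-area is what makes
  density × cell area a valid per-cell mass.
* **KDE.** Bivariate isotropic Gaussian, bandwidth h = 200 km (the GLS
  location-error scale, so all devices can share one smoothing), cells
  10 km × 10 km, grid extent covering the points plus a 3h margin
  (truncating < 10⁻³ of kernel mass). A 50-km bandwidth remains available
  as a config option for high-frequency GPS/PTT-only analyses. The kernel
  is separable, so the implementation evaluates exact point-to-cell
  Gaussian matrices and takes their product — no binning approximation —
  and the suite checks it against a brute-force double loop at 1e−12.
* **95% isopleth.** The smallest set of highest-density cells holding
  95% of the mass; interior densities are retained (not flattened), and
  masses outside the mask are zeroed without renormalisation. Ties at the
  boundary are broken by stable (row-major) cell order.
* **Land trim.** Cells whose *centre* lies on land are zeroed — a
  deterministic approximation chosen over polygon-area weighting.
* **Aggregation.** Each fine cell's mass is added to the 1°×1° global
  cell containing its back-projected centre. 1° cells are half-open
  [i, i+1) squares indexed by south-west corner; aggregation conserves
  mass to 1e−9. Months with fewer than five pooled locations are dropped
  before any of this.

Monthly grids are stored unnormalised; normalisation to unit sum happens
exactly once, at exposure time.

## Plastic layer

The three drift-model grids (1°×1°, pieces km⁻², natively centred at
180°E and reoriented at read time) are combined per cell by geometric
mean, with fallback to the geometric mean of two, the single available
estimate, or NA as coverage thins. A zero density is an exact zero ("no
plastic predicted"), so any zero contributor makes the cell's geometric
mean zero. The known-bad 0–1°W column is imputed row-wise from the
arithmetic mean of the non-missing values among its six neighbour
columns — 1–4°W on one side and, because the bad column sat at the native
array edge, 177–180°E on the other; six cells (three per side) is the
reading consistent with both listed ranges. Imputation runs after
combination, which is equivalent for fully observed rows and simpler.
The combined layer is then normalised to unit sum.

## Exposure scores

Exposure is the cellwise product of the unit-sum petrel and plastic
grids; the score is 10⁶ × the summed product. Properties the suite
enforces: scores are invariant to positive rescaling of either raw input;
bounded by [0, 10⁶] with the maximum only when both distributions share a
single cell; and maximised, for fixed plastic, by concentrating the
petrel mass on the argmax plastic cell. Petrel mass over plastic-missing
cells contributes zero and the missing-mass fraction is reported with
every result so coverage can be judged. The even-plastic reference equals
10⁶/N for N estimated cells, independent of the petrel distribution.

Aggregation: population scores are unweighted means over tracked months
(not season-balanced, so species with different tracking coverage remain
comparable); season scores are means over that season's months;
species scores are population-size-weighted means of population scores
(equal weights, logged, when any size is unknown), with a population's
contribution halved when it was tracked only in the breeding season.
Population maps are unweighted means of monthly maps, mirroring the
scores; species distribution grids weight population grids by size
*after* per-population normalisation, so each population contributes in
proportion to its size rather than its tracking effort. The all-species
map sums species grids with weight 1 (tracked in both seasons) or 0.5
(breeding only), renormalises, and multiplies by the plastic grid.
Shares of the total score by IUCN category, and a species-richness grid
(count of species with positive 95%-UD mass per cell), complete the
species-level products. Scores are reported at 1 d.p. (≥1) or 4
significant figures (<1); full precision is kept internally.

## Jurisdictions

Each 1° cell is assigned to the first jurisdiction polygon (file order)
containing its centre, boundary ties included; unassigned cells are high
seas. Centre-point assignment is a deliberate resolution-limited
approximation — a straddling cell is credited wholly to its centre's
polygon. Exposure in joint regimes and overlapping claims is split evenly
among the sovereigns. Shares always partition the total score exactly,
and merging polygons of one sovereign never changes that sovereign's
total. Per population, the fraction of exposure inside the breeding
country's own EEZ is reported, with a flag when it is not the maximum
share.

## Synthetic worlds

The generator exists so the full pipeline can be exercised and its
behaviour verified without the restricted tracking data. It emulates:

* **Plastic field:** strictly positive lognormal background (median
  0.05 pieces km⁻², log-sd 0.8) multiplied by Gaussian gyre hotspots
  (demo: one strong North-Atlantic-like hotspot, amplitude 30, scale
  1000 km, and a weaker South-Pacific-like one), NaN over land. Three
  model layers are the field times independent median-one lognormal noise
  (log-sd 0.7 — models agree to well within the 1–2 orders of magnitude
  of model-vs-trawl scatter), each with its own missing mask (polar caps
  at 60/65/70°, random coastal gaps, plus guaranteed cells missing in
  exactly one and exactly two models so both fallback branches are hit).
* **Land:** thresholded smoothed Gaussian noise (12% land by default),
  with each colony's cell kept ocean so its population has adjacent
  habitat; a colony on land with no ocean neighbour raises a generation
  error.
* **Movement:** discrete-time biased random walk in the local equal-area
  plane. Breeding months are out-and-back central-place trips (heading =
  bias toward a random waypoint plus Gaussian noise, speed ≤ 35 km h⁻¹
  with a uniform activity factor), hard-capped so true positions never
  exceed the maximum foraging range from the colony (the planar cap
  radius is chosen so the *great-circle* distance respects the cap
  exactly). Non-breeding months are a mean-reverting (10-day relaxation)
  walk around the wintering centroid with ~450 km stationary spread.
  Device error is isotropic Gaussian (GPS 0.05 km, PTT 1.5 km, GLS
  200 km — the error scale that motivates the 200-km smoothing), with an
  optional glitch-outlier rate to exercise the speed filter.
* **Jurisdictions:** rectangular toy EEZs around the colonies, one joint
  regime, one theoretical-EEZ category; partition logic is
  topology-independent, so rectangles are adequate.

Everything is a pure function of (seed, parameters); identical inputs
give byte-identical outputs (per-population streams are keyed by a CRC of
the population id so datasets are order-independent).

The demo world (2 species, 3 populations, 50 individuals, ~40k raw
locations over one year) is sized so the full pipeline runs in ~10 s on
one CPU while still exercising every preprocessing rule: an injected
> 90 km h⁻¹ glitch, GLS fixes inside both equinox windows (the austral
population breeds September–March), fixes inside the colony buffers, a
month with < 5 pooled locations, and a published schedule that wrongly
extends one population's breeding into a month the tracked birds had
left — so the reconciliation override observably fires.

What the synthetic data do **not** emulate: Argos error-class structure,
light-curve geolocation artefacts beyond isotropic error, migration
corridors between seasonal ranges (birds relocate between months; the
intervening fixes are filtered as implausible speeds), multi-year
individual fidelity, or any behavioural response to the plastic field
itself. Passing tests therefore demonstrate that the *procedure* is
implemented correctly and behaves monotonically (a range under the
hotspot scores strictly higher), not that real petrel scores take any
particular value.

## Numerical choices and limitations

* "Cell size of 10 km²" for the KDE grid is read as 10 km × 10 km cells,
  consistent with the later description of the fine UDs as 10 × 10 km.
* Normalisation tolerances are 1e−9; KDE-vs-oracle equality is asserted
  at 1e−12 per cell.
* The even-plastic reference depends only on the number of cells carrying
  a plastic estimate; on the demo world's synthetic layer it is ~22.5
  (≈44.5k estimated cells), not comparable across plastic layers with
  different coverage.
* Grid containers are plain (lat, lon) arrays with NaN for missing;
  serialisation is long-form CSV and CF-style NetCDF (scipy engine).
  Fine UDs record their projection parameters; polygons travel as
  GeoJSON.
* Sensitivity analyses included: published-vs-inferred phenology and
  size-weighted-vs-unweighted species scores, both summarised by Kendall
  tau on the demo world (the acceptance script reports both). The
  alternate 50-km-bandwidth/high-frequency variant is exposed through
  config (`kde_bandwidth_km`, `resample_interval_h`) rather than scripted.
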