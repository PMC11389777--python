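# Methods

This note documents the models, defaults, and numerical conventions
behind `roadpm`, and what the synthetic scenarios do and do not
demonstrate about real-world analyses.

## Scope and design

The pipeline estimates annual-average PM2.5 exposure attributable to
on-road vehicle emissions and its distribution across demographic
groups, over a multi-year scenario. It deliberately treats atmospheric
transport and chemistry as a *given linear operator* (a per-species
source-receptor matrix): the scientific content here is the exposure and
disparity accounting downstream of that operator, not the derivation of
the operator itself. No health-impact functions are included.

All geometry is planar, in meters, under a projected-coordinates
convention declared in file headers; the analysis is resolution- and
area-driven, and geodesic corrections would add nothing at domain scales
of tens of kilometers.

## Adaptive grid

Emissions, matrices and concentrations live on a single tiling of the
rectangular domain by square cells with dyadic side lengths
(`finest × 2^k`). Starting from coarse tiles, a cell larger than the
finest size splits into four children when its contained population
(area-apportioned from block-group polygons) exceeds `max_pop`
(default 20,000 people) or when it overlaps any block group denser than
`max_density` (default 2,500 people/km²). Splits are all-or-none — a
violating parent always produces four children even if three are empty —
which preserves exact tiling. The source grids this emulates quote a
1–48 km range; 48 km is not dyadic from 1 km, so the package defaults to
a 64 km coarsest cell (package runs here use 8 km coarsest on 16–32 km
domains) and treats the 48 km figure as descriptive of its source.
Cell boundaries are half-open `[x0, x1) × [y0, y1)`; ids are assigned by
Morton (Z-order) traversal, so rebuilding from identical inputs gives
identical grids.

## Synthetic scenario generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

- **Road network.** Two arterials cross the population core; a freight
  corridor runs offset from it. Fleet activity budgets (defaults LDV
  100, HDV 25, MDV 15, OTH 5 nominal units) split between the two
  systems with fleet-specific shares (LDV 85% arterial, HDV 85%
  freight), giving each fleet a distinct spatial footprint. Corridor
  positions are jittered per seed and never coincide with cell
  boundaries.
- **Emissions.** Road activity is rasterized to cells by line-length
  overlap; base-year emission rates per (species, process) are fixed
  nominal factors (precursor gases dominate by mass; brake+tire wear
  starts at ~15% of primary PM2.5). Year-*t* emissions equal base-year
  emissions times a cumulative annual factor per (species, process).
  Default factors are set so the two-decade totals change by −70%
  (exhaust PM2.5, NOx, VOC, and SOx, for which no separate figure is
  published), −15% (NH3), and +20% (brake and tire wear) — the
  aggregate trends of the California on-road inventory the scenario
  mimics.
- **Demographics.** The domain is tessellated into `n_tracts`
  rectangles; tract totals concentrate near the arterial with lognormal
  noise and sum exactly to the configured total (counts are real-valued
  so areal apportionment is exact). Group shares start from a common
  baseline (abstract groups A–D plus "other"; no synthetic output
  masquerades as census data) and tilt with the `segregation` dial
  s ∈ [0, 1]: group A toward both corridors (freight weighted 1.2×),
  B toward the freight corridor, C mildly toward the arterial, D away
  from roads. Affinities are mean-normalized, so at s = 0 every group
  has the same expected spatial distribution and all expected
  disparities vanish; per-tract Dirichlet noise (concentration 300)
  makes realizations random. The default s = 0.6 produces persistent
  positive disparity for A and negative for D.
- **Community designation.** Tracts are ranked by a score (in the
  pipeline: first-year full-fleet exposure), and the minimal prefix of
  tracts holding the target population share is flagged (defaults 8.1%
  and 30%, the two designation-program analogs). Ties break by stable
  tract id.

A single root seed sequence spawns one child stream per operation in a
fixed order, so outputs are bit-identical under a fixed config and seed.

## Synthetic source-receptor matrices

Entry `(r, s)` is `peak · exp(−d_rs/λ) · A₀/(2πλ²)` with `d_rs` the
centroid distance and `A₀` the finest-cell area; the `1/(2πλ²)` factor
keeps the spatially integrated response roughly λ-independent, so `peak`
alone sets a species' potency. Primary PM2.5 uses λ = 3 km; the four
precursors use λ = 8 km with peaks damped by `secondary_fraction = 0.6`.
These defaults encode the qualitative contrast the analysis requires —
primary impacts spatially sharper than secondary, secondary formation
contributing the large majority (~80%) of exposure, and primary relative
disparities larger than secondary ones by a factor near 1.7. The overall
amplitude (`peak = 0.15`) sets the default base-year statewide PWM near
3 µg/m³, an on-road-sector-like share of ambient PM2.5; every relative
metric is invariant to it. The matrices are symmetric, non-negative, and
carry the grid fingerprint; using a matrix on a different grid is
rejected.

Application order is fixed (species, then fleet, then process, each
ascending, source cells in id order), so additive decompositions are
reproducible run to run; parts of a partition sum to the full field to
better than 1e-9 relative (floating-point reassociation only).

## Population mapping and metrics

Tract populations are split across cells in proportion to overlap area
(uniform density within a tract — the single largest approximation
inherited by this design). Fragments smaller than 1e-6 of the tract area
are merged into the tract's dominant fragment to suppress
floating-point slivers. Concentrations are constant within a cell, so
metrics on fragments equal metrics on per-cell aggregates algebraically;
fragments additionally carry tract-level stratifiers.

Metric conventions:

- Disparities are computed from unrounded PWMs; percent formatting
  happens only in the report layer (printed concentration/disparity
  pairs rounded independently need not be mutually consistent).
- Population-weighted quantiles use a left-continuous step (no
  interpolation): the smallest exposure whose cumulative population
  share reaches the target.
- Decile composition sorts fragments by exposure (stable order),
  cuts the cumulative population into ten equal bins, and splits
  fragments proportionally at cuts; *tied* exposures are pooled and
  split proportionally, so a uniform field reproduces the overall
  composition in every bin.
- Fractional contributions with a total absolute disparity below
  1e-12 µg/m³ are flagged unstable rather than returned as huge ratios.
- The most-vs-least exposure inequality uses the PWM-ratio form
  `PWM_most/PWM_least − 1 = (1+D_R,most)/(1+D_R,least) − 1`; a
  difference-of-disparities form would be an alternative reading, but
  the ratio form is the one consistent with the published endpoint
  values this metric is modeled on.
- Demographics are temporally static within a run: one table applies to
  all years (sensitivity to the vintage is explored by re-running with
  a different table).

## Problem sizes and runtime

Default scenario: 32 × 32 km domain, 8 km coarsest / 1 km finest cells
(~46 cells after refinement), 144 tracts, 400,000 people, 20 years,
4 fleets × 5 species × 4 processes. Parameter-recovery studies (the
exchangeability null over 100 seeds and the segregation sweep over 20
seeds) use a reduced 16 × 16 km, 25-tract, single-year scenario; these
sizes were chosen so a full sweep completes in seconds on one CPU while
leaving the disparity signal far above Monte-Carlo noise.

## What passing tests show — and what they do not

On synthetic scenarios the pipeline provably conserves population,
decomposes exposure additively, recovers the segregation dial
monotonically, returns zero expected disparity for exchangeable groups,
and reproduces the arithmetic identities connecting published summary
figures. None of that validates the *physical* realism of any real
application: the synthetic SRM is an isotropic exponential kernel, not a
chemistry-transport model (no meteorology, terrain, plume rise, or
nonlinear aerosol chemistry); the road network and demographics are
stylized; sub-kilometer near-road gradients are unresolved; exposures
are residence-based. Conclusions about a real region require a real
inventory, a real source-receptor matrix, and real census data in place
of the generator.
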