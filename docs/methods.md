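# Methods

## Model overview

The package simulates equilibrium marine biodiversity as the static
interaction of a fixed niche pool with a time-varying physical
environment.  There are no population dynamics, no dispersal limits, no
biotic interactions and no origination/extinction processes: a species
exists wherever (and only wherever) its thermal niche is satisfied under
the persistence rule.  Temporal change in global richness therefore
reflects the changing geography and climate alone, which is exactly the
hypothesis the package is built to examine.

## Niche pool

Each niche is an interval [Y − X/2, Y + X/2].  Breadth and centre are

    X = d1 (δ − γ) + γ,                    d1 ~ U(0,1)
    Y = d2 (β − X/2 − (α + X/2)) + (α + X/2),   d2 ~ U(0,1)

with defaults α = −2 °C, β = 44 °C, γ = 4 °C, δ = 20 °C,
N = 100,000.  An alternative breadth formula, X = d1(δ − γ) + δ
(range [δ, 2δ − γ]), is retained behind
`breadth_formula="verbatim"`; it is inconsistent with γ and δ being the
minimum and maximum tolerance breadths, and the consistent form above is
the default.  Draws are taken niche-by-niche (d1 then d2) from one
seeded NumPy `default_rng` stream, so a smaller pool is a prefix of a
larger one with the same seed.  Suitability uses closed interval
endpoints; the choice has measure-zero effect on results.

A useful closed form: conditional on X, the centre is uniform on
[α + X/2, β − X/2], so the probability that a random niche covers a
temperature t is an integral over X available in
`coverage_probability`.  Under the defaults the curve rises from the
domain edges and is **exactly flat on [α + δ, β − δ] = [18, 24] °C**:
for central temperatures no centre-clipping occurs for any admissible
breadth.  The often-quoted "coverage peaks at the mid-domain 21 °C" is
therefore a plateau whose centre is 21 °C, not a point maximum; tests
and the acceptance script estimate the peak as the half-range-weighted
centroid of the curve, which is unbiased for this symmetric shape.

## Synthetic worlds

The generator emulates the statistical structure of gridded monthly
palaeo-SST forcing:

* annual mean SST(φ) = pole + (equator − pole)·cos²φ — smooth,
  monotone poleward, qualitatively matching coupled-model meridional
  profiles;
* seasonal term A·sin φ·cos(2π(m − 6)/12) (m = 0 is January) —
  anti-phased between hemispheres, zero at the equator, NH maximum in
  July; A is the polar peak amplitude in °C;
* iid Gaussian noise (default 0) and a hard floor at −2 °C (sea-water
  freezing; note the floor interacts with the seasonal cycle to raise
  polar *annual means* slightly above −2 °C);
* continents are rectangles in lat/lon (longitude may wrap the seam);
  bathymetry is `shelf_slope` (default 300 m) per cell of Chebyshev
  distance to land, capped at `abyssal_depth` (4,000 m), giving
  controllable <600/<1000/<1500 m shelves;
* each slice draws from an RNG stream seeded by (seed, age), so slices
  are independent and order-insensitive.

What the generator does **not** emulate: realistic coastline geometry,
ocean dynamics (gyres, upwelling, zonal asymmetry), orbital or CO₂
forcing, eustatic sea level, and equal-area grids.  Passing tests on
synthetic worlds therefore validates the *operations* (masking,
projection, counting, indices) and the *qualitative mechanics* of the
niche–environment interaction, not the realism of any particular
palaeoclimate.

Drift scenarios interpolate continent rectangles linearly between
waypoint configurations; a change in the number of continents between
waypoints switches configuration at mid-segment, which is how
fragmentation events are expressed.

## Shelf masks

"Around continents" is implemented as Chebyshev (8-neighbour) distance
to the nearest land cell ≤ ring width (1 or 2), with longitude wrap and
no polar wrap; Manhattan adjacency is available by option.  Depth limits
are strict (< 600/1000/1500 m b.s.l.).  The eight ring×depth variants
are enumerable (`all_variants`), nested, and longitude-translation
equivariant.  Cell areas use the closed-form WGS-84 ellipsoid zone-area
formula per latitude band divided evenly across columns; the global sum
reproduces the ellipsoid surface area to numerical precision.

## Occupancy, richness and speciation

Monthly suitability, the ε-month rule (default ε = 8) and patch
counting follow the model definition.  Two richness-map conventions are
exposed because they answer different questions: `monthly_mean` (the
mapping convention — mean over months of the per-month suitable-niche
count) and `annual` (count of niches passing the ε rule).  Global
counts always use the annual rule.  Patch counting labels 8-connected
components (scikit-image) and merges labels across the periodic
longitude seam with a union–find pass; 4-connectivity is an option.
Months with missing SST count as unsuitable.  `months_suitable` runs in
niche blocks to bound memory; results are block-size independent, and
the monthly-mean richness map uses an exact sorted-interval-stabbing
count rather than a per-niche loop.

A note on ε-monotonicity: raising ε shrinks every niche's occupancy, so
the occupancy cube and the without-speciation count are non-increasing
in ε.  The with-speciation total is **not** monotone — shrinking a
patch can split it in two — and the test suite deliberately asserts
only the monotone quantities.

## Driver indices

The LBG is the mean richness per latitude over masked cells (rows with
no masked cells are flagged undefined, excluded from profiles, and
contribute 0 to sums).  The LCI counts masked cells holding at least
one species under the annual rule; a `months="sum"` option instead sums
the twelve monthly occupied-cell counts, covering the alternative
cell-months reading of the index.  The LBG-weighted LCI multiplies each
latitude's occupied-cell count by the same slice's monthly-mean LBG
value.  Temperature-density diagnostics histogram the masked
(cell, month) SST samples in 1 °C bins over [−2, 41] and report the
modal bin and mean.  External age series (e.g. a continental
fragmentation index) are ingested as (age, value) tables and resampled
by shape-preserving monotone Hermite (PCHIP) interpolation; no
extrapolation is permitted.

## Fossil composite index

Input diversity curves are 0–1 standardised (min→0, max→1), PCHIP
interpolated to the target ages, z-scored per curve, and decomposed by
PCA of the correlation matrix.  The first component is reported with
explained-variance fractions and loadings.  PCA sign being arbitrary,
PC1 is oriented to correlate positively with the across-curve mean of
the standardised inputs (ties broken toward a positive loading on the
first curve), so the index visibly tracks the raw curves and is
deterministic.  Raw PC1 scores are returned without further rescaling.

## Correlation statistics

Pearson r with the two-tailed t test at df = n − 2.  The
autocorrelation correction computes the effective sample size

    1/N* = 1/N + (2/N) Σ_{j=1..⌊N/5⌋} ρxx(j) ρyy(j)

with biased (1/N-normalised) sample autocorrelations — the common usage
of this class of correction; lag cap and estimator are the package's
choice where finer detail is unspecified, and the plain product form is
used rather than the cross-correlation-augmented variant.
df_adj = max(2, ⌊N*⌋ − 2) keeps the t distribution defined.  df* is
found by exponential search plus bisection on the exact t CDF (p is
monotone decreasing in df for fixed r); r = 0 or sub-threshold |r|
returns a "none" sentinel.  Map correlations flatten the jointly masked
cells and attach df* as the spatial-autocorrelation robustness check.

## Qualitative Phanerozoic mechanics — scenario design

The drift experiment (10 slices, 36×36 grid, 5,000 niches) moves a
16°-tall continent from 65° S to a tropical centroid of 20° S in steps
of exactly one grid cell (5°), so every slice changes the geography by a
whole cell and the land-cell count is constant.  The climate is warm
with a shallow gradient and strong seasonality (equator 22 °C, pole
14 °C, amplitude 12 °C).  This regime matters: global richness on a
shelf reflects two competing effects, the *span* of temperatures the
shelf offers (maximal where the meridional gradient is steepest, at
mid-latitudes) and the *position* of those temperatures relative to the
coverage plateau plus the seasonal stability of the tropics.  Under
steep-gradient climates the span effect wins mid-drift and the count
peaks before the tropics — an emergent, scientifically interesting
non-monotonicity.  The shallow-gradient, strongly seasonal world makes
the position/stability effect dominate, which is the regime in which
equatorward drift monotonically raises diversity.  The fragmentation
experiment splits one tropical continent into two blocks of equal total
land area with shelves far enough apart (> 4 cells) to be disconnected,
exactly doubling the with-speciation count while leaving the
without-speciation count unchanged.  The climate-state experiment
compares cold (18/−2), modern (28/−2) and hot (38/16 °C equator/pole)
worlds around one meridional continent: the equator-to-pole richness
drop orders cold > modern > hot, with the hot world flat or inverted —
the tropics exceed the upper thermal optimum while mid-latitudes enter
it.

## Problem sizes and numerical choices

Tests and the acceptance script run at: 100 randomized toy instances
(≤12×12 grids, ≤10 niches) for exact oracle equivalence; 10,000 niches
for the pool law; 5,000 niches on 36×36 grids for the drift,
fragmentation and climate experiments; 5,000 replicates (n = 100) for
the type-I-error calibration; 5 curves × 109 ages for the fossil index.
The niche pool default N = 100,000 is untouched by these choices —
callers pass the pool size explicitly.  Floating-point tolerances:
oracle equivalence for integer counts is exact; richness means are
compared at 1e-12; PCA explained variance at 1e-10 against an
independent eigensolver; PCHIP against an independent Fritsch–Carlson
implementation at 1e-10.

## Known limitations

Regular lat–lon grids only (equal-area grids are not generated or
ingested); single-variable (temperature) niches; no mass-extinction or
dispersal dynamics; rectangular synthetic continents; NetCDF3 dialect
for on-disk worlds.  The drift monotonicity result is regime-dependent
as described above and should not be read as a universal prediction of
the model.
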