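# Methods

This note documents the models, conventions and numerical choices behind
`altiband`, including every place where the underlying workflow is
conventionally underspecified and the package had to fix a rule.

## Band schemes

**Equal-elevation bands.** The domain [min, max] is tiled by bands of fixed
width w; the span must be an exact multiple of w (a partial top band would
silently distort the top-band area, so non-divisible spans raise). Intervals
are half-open [lower, upper) with the topmost band closed — the literature
rarely states a convention, and this one maps every elevation to exactly one
band. Band area is planimetric: cell area × number of DEM cells in the band
(no slope correction). Cells outside the domain are excluded and counted in
`BandScheme.n_outside`, never dropped silently.

**Equal-area bands.** Integer DEM values are jittered by one independent
U(−0.5, +0.5) draw per cell, taken in raster row-major order from an
explicit seed, which breaks the massive ties of an integer DEM and makes
class boundaries well defined. The jittered values are ranked and cut into
n groups whose sizes differ by at most one (the first `n_cells mod n_bands`
groups take the extra cell — the `numpy.array_split` convention). Interior
boundaries are midpoints between the two jittered values straddling each
cut, so the boundary is independent of the side it is approached from; the
outer boundaries clamp to the domain. GIS packages that build equal-area
classes do not document their boundary rule; the rank-quantile/midpoint rule
used here is the reproducible equivalent and is stamped into the run
manifest. Per-band climate summaries use the ranked-split assignment, not a
re-binning, so cell membership and boundaries are always consistent.

## Richness counting

A species is present in every band whose interval intersects the **closed**
range [elev_min, elev_max]. Consequently a species whose maximum equals a
band's lower edge is counted in that band (conservative presence under the
continuous-range interpolation assumption); presence sets are always
contiguous runs of bands. Genus and family presence derive from species
presence — no independent genus ranges. Range-size groups use thresholds
(150 m, 500 m) with both endpoints in Group II ("between 150 and 500" read
inclusively, "<150" strictly); the boundary rule matters only for ranges of
exactly 150 or 500 m and is recorded in the manifest. Method 2 is literally
`richness_table` re-run on the equal-area scheme — one code path, two
schemes.

The partition identities S = TS+SS+HS = IS+IIS+IIIS and S ≥ G ≥ F hold by
construction for any checklist and are enforced property-test-style.

## Species–area fits and method 1

Three linearisations are fitted by OLS (statsmodels): S~A, S~lnA, lnS~lnA.
Natural logs throughout; the log–log slope z is base-invariant, the
intercept is ln c. Bands with zero richness are excluded from **all three**
fits (not just the log ones) so the AICc comparison runs on a common subset.
AICc uses the Gaussian log-likelihood at the ML residual variance and K = 3
(slope, intercept, σ²) — the standard count for simple regression; K shifts
all three AICc values by the same constant, so the selected version cannot
depend on it. AICc is reported as NaN below n = K + 2, where the correction
is undefined. The winner is the minimum-AICc version; rivals within 2 units
are flagged co-best. TRcor₁ = 100·TRobs/A^z with A in km²; since c (and
hence TRcor₁'s scale) depends on the area unit, the unit is stamped into the
output. Zero-richness bands get TRcor₁ = 0.

## Mid-domain null

The null preserves each species' range size r and draws the range midpoint
uniformly on the feasible interval [min + r/2, max − r/2] — the canonical
range-size-preserving placement, chosen because it admits an exact
expectation: the presence probability in band [a, b] is
|[a − r/2, b + r/2] ∩ feasible| / (D − r), and 1 when r = D. The simulated
mean (default 1000 placements) is the MDE prediction; 2.5 %/97.5 %
simulation quantiles are reported alongside. Zero-size ranges (single-record
species) are legal and occupy exactly one band per placement. Band
intersection reuses the richness presence rule, so simulation and counting
can never disagree on conventions. The closed form is used as an independent
oracle in the tests, never as the prediction itself.

## Spatial statistics

Bands are observations along one geographic axis. For equal-elevation
schemes, positions are band mid-elevations, so distance classes are
naturally 100 m, 200 m, …; a class links pairs separated by
(d − step/2, d + step/2]. For equal-area schemes, mid-elevations are
irregular — a fixed 100-m neighbourhood would isolate wide bands — so the
default weights are rank adjacency (band i ~ i±1), with metric distance
retained as an option; the choice is recorded per fit.

Moran's I is computed on the **raw binary** weights of a class,
I = (n/S)·ΣΣwᵢⱼ(xᵢ−x̄)(xⱼ−x̄)/Σ(xᵢ−x̄)², with S the link count. Constant
inputs and empty classes raise rather than return 0/0. Correlogram p-values
come from a two-sided permutation test (999 permutations, seeded); the
permutation-null mean is ≈ −1/(n−1), which the tests verify.

The SAR error model y = Xβ + u, u = λWu + ε uses the row-standardised W
(isolated rows stay zero) and profile maximum likelihood: for each λ the
spatial filter (I − λW) is applied to both sides, β and σ² follow in closed
form, and log|I − λW| = Σ log(1 − λωᵢ) with ωᵢ the eigenvalues of W —
computed from the similar symmetric matrix D^(−1/2)AD^(−1/2), exact and
cheap at n ≈ 37. λ is profiled over (−0.999, 0.999) by bounded scalar
minimisation (xatol 1e-8); SE(λ) from the numeric curvature of the profile.
At λ = 0 the fit reduces exactly to OLS (tested). Pseudo-R² is the squared
Pearson correlation between y and the full prediction Xβ + λW(y − Xβ);
the trend-only pseudo-R² is reported alongside for transparency. AICc for
SAR uses K = p + 2 (trend coefficients, λ, σ²). ML λ̂ is biased toward zero
at n = 37 (mean ≈ 0.52 at truth 0.6 in the recovery tests); this is the
known small-sample behaviour of the estimator, not a defect, and the
recovery check budgets for it.

Order selection (first vs second degree): the quadratic must beat the
linear fit by ≥ 2 AICc units, otherwise the linear fit is kept for
parsimony. Coefficients are reported as Q (quadratic), S (slope),
C (constant). No multiple-testing correction is applied across the model
battery; significance thresholds are 0.05/0.01/0.001.

Responses with zero-richness bands (e.g. trees absent from summit bands)
are fitted on the positive subset, and the spatial weights are **recomputed
on that subset** — whether neighbours should instead be inherited from the
full scheme is genuinely open; recomputation is the choice here and is
logged per fit via `n_used`.

## Synthetic data

The generator emulates the statistical structure the analysis consumes, not
terrain. Cell elevations are drawn from a two-component mixture of truncated
normals (70 % mass in a component of sd span/8 at the hypsographic peak,
30 % in a broad upslope shoulder of sd span/3), sampled by **stratified
inverse-CDF** draws so per-metre cell counts deviate from expectation by at
most one — the histogram mode is structural rather than a sampling accident —
then rounded to integer metres, honouring the premise of the equal-area
jitter rule. MAT is linear in elevation (default 12 °C at the base, lapse
0.006 °C/m); MAP interpolates a rise–fall–rise piecewise-linear profile
with a dry minimum of 912 mm at 4200 m. Climate noise defaults to 0
(the band-scale noise structure of gridded climatologies is not something
this generator tries to model; a noise-sd knob exists).

Checklists default to 2028 species in proportions 830/554/644 across the
range-size groups, life forms 290/392/1346 (tree/shrub/herb), and a
single-record fraction of 717/2028 — point ranges are drawn inside Group I
so the group mixture is undisturbed. Range sizes are uniform within each
group's interval; midpoints follow a unimodal elevation profile (Gaussian at
mid-domain, sd span/4) restricted to each range's feasible interval, sampled
by discretised inverse CDF (257-point grid). Taxonomy is nested by
construction: species → genus → family with mean sizes 2028/625 and 625/136.

What the generator does **not** emulate: spatial autocorrelation of ranges,
occupancy gaps inside ranges, detection error, realistic terrain morphology,
and climate noise. Tests passing on synthetic data therefore demonstrate
correctness of the machinery and the stated statistical properties, not
field-data conclusions; in particular, which correction method "wins" on a
synthetic mountain depends on the generator's richness profile and is
reported, not asserted.

## Problem sizes and determinism

Default analyses use a 120×120-cell DEM (tests use 50–80² grids), 37 bands,
2028 species and 1000 MDE placements; recovery simulations use 200
replicates at n = 37, matching the scale at which the statistics are
actually applied. Every random stage takes an explicit integer seed — DEM,
checklist, jitter, MDE, permutations — and reruns with the same config are
byte-identical (tested on the serialized artifacts). There is no hidden
global RNG state.

## Known limitations

- Only the error-type SAR is implemented (no lag/mixed variants), matching
  the analysis it supports; single-predictor models only, no variance
  partitioning.
- The untransformed species–area version is fitted as a line in S–A space,
  not as a nonlinear power-law fit.
- Equal-area boundaries depend on the jitter seed at the ~0.5 m scale;
  richness counted on the scheme can differ by a species or two between
  seeds when a record sits within jitter range of a cut.
- The MDE null is the uniform-midpoint variant only; resampled-range or
  spreading-dye variants are out of scope.
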