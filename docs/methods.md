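# Methods

This note documents the models implemented in `esdrought`, the choices
made where the methodology was genuinely open, what the synthetic
landscape generator does and does not emulate, and the package's known
limitations. Problem sizes quoted below are the defaults the tests and
the acceptance script use.

## Service models

All four services are computed per cell and year on one co-registered
grid (one shape, one cell size, one validity mask — a cell invalid in
the land-use map is invalid everywhere).

**Water retention (mm).** Water yield (an input raster; its hydrological
model is out of scope) attenuated by three clamped terms:
`min(1, 249/Velocity) · min(1, 0.9·TI/3) · min(1, Ks/300) · Yield`, with
the flow-velocity coefficient dimensionless, the topographic index TI
dimensionless and saturated hydraulic conductivity Ks in cm/d. Each term
is clipped to [0, 1], so retention never exceeds yield and is monotone
in each input.

**Soil conservation (t·hm⁻²·a⁻¹).** The RUSLE factor product with the
cover/practice term in the form `R·K·L·S·(1 − P·C)`. This is the form
implemented and tested; because the more common textbook variant
multiplies `(1 − C)(1 − P)` instead, a `rusle_variant` switch selects
between the two. Factor sub-models (R from rainfall records, K from
texture, LS from flow routing) are out of scope; factors are inputs.

**Carbon sequestration.** Proportional to net primary productivity:
`1.63 · NPP` per unit area. With NPP in g·m⁻²·a⁻¹ the value is
numerically t·km⁻²; `per_cell=True` multiplies by the cell area in km²
for the per-cell total. The coefficient is applied as a literal
constant; no claim is made about whether NPP is carbon mass or dry
matter.

**Food supply (t·km⁻²).** Municipal grain totals `P_sum` are
disaggregated onto cropland cells proportionally to NDVI:
`P_i = NDVI_i / NDVI_sum · P_sum`. Mass is conserved exactly per
zone-year (tested to 1e-9 relative). Cropland cells with negative NDVI
are excluded from `NDVI_sum` (with a warning) rather than clipped to
zero: this keeps allocations non-negative while preserving conservation.
A zone with positive yield but no positive cropland NDVI is an error.
Allocated tonnes are divided by cell area to report a density, keeping
FS commensurable with the other services.

## Drought classification

Annual SPEI is classified into five ordered levels with half-open
intervals closed on the severe side: none (> −0.5), slight
(−1.0, −0.5], medium (−1.5, −1.0], serious (−2.0, −1.5], extreme
(≤ −2.0). This is the standard SPEI drought grading; the cutoffs are
configurable. Drought frequency `SPEI_F` is the fraction of years in
any drought class, and a cell-year counts as "drought" for
stratification when SPEI ≤ −0.5, consistent with the table's onset.
Drought vs non-drought service means are compared with Welch's unequal-
variance t-test; the choice of test is ours — the convention of
reporting star levels does not pin one down. Both pooling modes
(cell-years, and distributions per drought class with Δ against the
no-drought baseline) are provided because the observation unit is a
free choice. The temperature × precipitation surface of bin-mean SPEI
defaults to 1 °C × 100 mm bins.

## Trends

Per-cell Theil–Sen slope (median of all pairwise slopes, units per
calendar year; missing years are dropped pairwise while indices keep
calendar spacing) and the Mann–Kendall test with the tie-corrected
variance `[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18`, continuity-corrected
normal score and two-sided p-value. Prewhitening for serial correlation
and the seasonal variant are out of scope. Monte-Carlo calibration
(1,000 white-noise series of length 23) keeps the empirical type-I
error at α = 0.05 within [0.035, 0.065]; the continuity correction
makes the test mildly conservative (~0.04 observed).

## Constraint lines

The upper boundary of a response-vs-driver scatter is estimated by
quantile segmentation: 100 equal-width bins over the driver range, the
99.9th percentile of the response per bin (linear interpolation between
order statistics), bins below `min_count` dropped, at least 10
qualifying bins required. The bin representative is the midpoint —
deterministic and independent of the x distribution.

Candidate families are a quadratic hump, a gaussian-plus-offset hump,
and a cubic (able to express a convex-wave shape with an interior
maximum); the catalog is configurable. Because the polynomial families
are nested, selecting by raw R² would always prefer the cubic;
selection therefore uses BIC with a positive-evidence margin (a family
with more parameters must win by more than 2 BIC points per extra
parameter; numerically exact fits tie-break to the fewest parameters),
while the plain R² on the boundary points is reported. On a noisy
parabolic boundary this keeps the quadratic the winner in ≥ 95% of
replicates.

The threshold is the driver value at the fitted maximum, obtained
analytically from the derivative for every family (vertex of the
quadratic, derivative roots of the cubic filtered by a negative second
derivative, the gaussian's mean). A curve whose maximum on the observed
range sits at an endpoint is flagged `boundary_max` rather than
assigned an interior threshold.

Two numerical cautions surfaced during development. First, the upper
percentile of a sparsely populated bin is biased low (the 99.9th
percentile of ~30 points is effectively their maximum, which sits below
the envelope); on landscape-scale extractions with tens of thousands of
points per stratum we therefore raise `min_count` to 50 so that the
biased tail bins drop out — with the default 10 the fitted vertex can
shift by several tenths of an SPEI unit. Second, with the generator's
default drought suppression the realized envelope is the planted
parabola kinked downward left of SPEI = −0.5, so thresholds fitted on
the default landscape legitimately sit below the planted apex;
apex-recovery checks use suppression-free configurations.

## Bundles

Cells are described by period-mean services plus SPEI_F (a per-year row
mode also exists), z-scored with the sample standard deviation
(ddof = 1); a zero-variance column is an error naming the column. The
self-organizing map uses one unit per bundle (2×2 for the default
k = 4) on a rectangular grid with a Gaussian neighborhood. Training is
deterministic *batch* SOM: per epoch, rows are assigned to their
best-matching unit and each codebook vector is blended toward the
neighborhood-weighted data mean, with radius decaying linearly
1.0 → 0.05 and the blend rate 0.5 → 0.01 over 50 epochs; the codebook
is initialized from seeded random data rows. Batch training was chosen
over per-sample online updates because it is order-independent, exactly
reproducible and fast at this scale; at one unit per bundle it
converges in tens of epochs, so hundreds of online epochs buy nothing.
Empty units produce a warning and a realized bundle count. Bundle
naming is left to the analyst; summaries report per-bundle medians,
IQRs, means and SDs in original units.

## Trade-offs, synergies and regressions

Pearson correlations between services are computed over the cells of a
stratum (drought degree — the most severe class a cell experienced — or
bundle), on period-mean values by default with per-year pooling as an
option. p-values use the exact t-transform with n−2 df; stars follow
* p<0.05, ** p<0.01, *** p<0.001 with no multiple-testing correction by
default. Negative r is read as a trade-off, positive as a synergy.
Spatial autocorrelation is ignored in these significance values — a
deliberate replication of common practice in this literature, so the
p-values are anti-conservative for spatially smooth fields. The
ES~SPEI regressions are OLS on annual stratum means (one point per
year, per land-use class).

## Attribution

A random-forest surrogate (scikit-learn, seeded, held-out R² reported)
predicts each service from the twelve drivers; the attribution contract
is model-agnostic — anything with a `predict` works, and tests use
hand-written linear and polynomial models. The value function is the
interventional expectation over a background sample: features in the
coalition take the instance's values, the rest take each background
row's values, predictions are averaged. Shapley values are computed by
*full enumeration* of all 2ⁿ coalitions (n ≤ 15 enforced; 12 features →
4,096 coalitions) with the exact combinatorial weights; a
permutation-averaged implementation serves as an independent oracle in
the tests (n ≤ 5). The conditional (on-manifold) value function is not
implemented. Pipeline defaults attribute 25 instances per bundle
against a 25-row background with a 60-tree forest — enough for a stable
mean-|φ| ranking at a few seconds per service-bundle pair; the library
functions accept larger samples (e.g. 500 instances / 100 background
rows) where a study needs them.

## Synthetic landscape generator

The generator emulates the statistical structure the analysis assumes,
not any real geography. Per cell it draws a land-use class, a bundle
archetype (capacity multipliers per service plus a target drought
frequency) and a drought-degree stratum; per cell-year it draws SPEI
(normal years ~ N(0.35, 0.30); globally forced drought years
~ N(−1.3, 0.25), so a forced year's grid mean sits below −1; cell-level
drought years placed to realize the bundle's frequency, with the
deepest year's SPEI drawn strictly inside the stratum's class interval
so classification recovers the stratum). A service value is
`b(SPEI) · U · L`: `b` a planted parabolic envelope per (service,
land-use) — default apices include 0.81/0.96 for forest WR/SC —
`U ~ Beta(5, 1)` so ~10% of draws land within 2% of the envelope, and
`L ∈ (0, 1]` the cell's capacity level, correlated across services
within a stratum via a Gaussian copula (default: WR–FS −0.25 and
SC–FS −0.32 among extreme-drought cells, WR–CS +0.11 among
slight-drought cells) with a 15% coefficient of variation. Services in
drought cell-years are additionally suppressed (defaults 30/25/5/10%
for WR/SC/CS/FS — regulation services hit hardest, carbon least).

Input rasters are then back-solved so the service equations reproduce
the planted values exactly: Yield from WR and static attenuation
rasters, R from SC and static RUSLE factors, NPP from CS, and cropland
NDVI proportional to the FS target with zone totals set to the planted
sums (so the allocation rule returns the target bit-for-bit, up to
float32 storage). Drought cell-years get a hot-dry climate signature
(TEM ≈ 24 °C, PRE ≈ 500 mm), planting the minimum of the binned SPEI
surface in the 23–25 °C × 400–600 mm window. Linear trends
(default: NPP +3.2 g·m⁻²·a⁻¹·a⁻¹, giving CS ≈ +5.2 t·km⁻²·a⁻¹) and
additive Gaussian noise are applied per variable afterwards, truncated
at hard physical bounds (NDVI ∈ [−1, 1], non-negative fluxes).
Municipal zones are contiguous rectangular blocks; grids use a local
metric projection with a top-left origin; years map to 2000–2022 by
default.

What the generator does **not** emulate: real spatial autocorrelation
(cells are conditionally independent given their labels; an analysis
robust to smooth fields is not validated here), monthly dynamics,
realistic co-variation between drivers and topography, or measurement
error structure. Passing tests therefore demonstrate algorithmic
correctness and recoverability of planted structure, not skill on real
rasters.

Identical config + seed reproduces the dataset bit-exactly, and a
written fixture (float32 TIFF per variable-year, CSV zone table,
SHA-256 manifest) round-trips bit-exactly; corruption is detected by
checksum.

## Problem sizes and numerical tolerances

Formula oracles are asserted to 1e-9; Shapley efficiency to 1e-8 and
oracle agreement to 1e-10; Pearson and Theil–Sen brute-force agreement
to 1e-12. Simulation-based checks use: 100 replicates of 10⁴ points for
threshold recovery (tolerance ±0.1 on the apex, ≥95 hits), 1,000
series for Mann–Kendall calibration, 500 replicates for slope recovery
(median within 5%), 10⁴ rows for bundle recovery (ARI ≥ 0.9), and a
6,400-cell landscape with ≥5,000 extreme-stratum cells for correlation
recovery (±0.03). The end-to-end run uses a 100×100×23 landscape and
completes in well under five minutes on one CPU.

## Known limitations

* The constraint-line threshold is defined as the curve maximum; other
  notions of "inflection" (zero second derivative) are not reported as
  thresholds, though the cubic's full derivative roots are available
  from the coefficients.
* Boundary extraction is sensitive to bin population (see above);
  bootstrap uncertainty for thresholds is not implemented.
* Correlation and regression significance ignores spatial
  autocorrelation (documented, deliberate).
* SPEI itself is consumed as an input; the package does not compute it
  from climate data, and sub-annual drought events are invisible at the
  annual step.
* The attribution surrogate's fit quality bounds the meaning of its
  Shapley values; the held-out R² is reported alongside every
  importance table for exactly this reason.
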