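# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices inside the mixed-model fitter and permutation
machinery, and the known limitations. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Growth rate and the measurement pipeline

Relative growth rate is `RGR = ln(B)/t` with aboveground biomass B (kg)
and planting age t (yr), i.e., mean annual relative biomass increment
under the assumption of negligible mass at planting. Biomass comes from
power-law allometry `ln B = a + b ln D` on stem diameter D (cm) measured
at 130, 50, or 10 cm; coefficients are resolved per species where
available, else per life form (here: genus, with a generic class for
non-focal genera). The natural logarithm is used throughout — any other
base would rescale all slopes by a constant. Focal plants with B < 0.1 kg
are removed from the focal set (strictly below; they remain as
neighbors), since such plants plausibly recruited after establishment.
When several stem rows share a plant id, per-stem biomass would be summed;
the generator emits single-stemmed plants, so this path is exercised only
through the allometry API.

Species mean traits — SLA (mm² g⁻¹), wood density (g cm⁻³), maximum
height (m) — must be complete for focal species. Missing non-focal
traits are interpolated as the mean of *measured* congeneric species
means occurring in plots within 50 km (great-circle distance on plot
coordinates; here plots inherit their planting's coordinates). Averaging
species means, not individual measurements, is a deliberate choice:
it weights each congener equally regardless of how many plots it
occupies. Interpolation never chains through interpolated values, never
alters measured values, and is idempotent; species with no congener in
radius stay missing and are listed in the coverage report.

## Neighborhood predictors

All metrics treat the neighborhood as the focal's plot minus the focal
itself (stem coordinates are unavailable in these surveys, so no
distance-weighted kernels):

- density `(n − 1)/(area/10⁴)` in plants ha⁻¹;
- proportion of conspecific neighbors (undefined for an empty
  neighborhood);
- rarefied richness `E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)]` with exact
  log-space binomials, at n = 9; plots with fewer than 10 plants cannot
  support it and their focals drop from richness-requiring models;
- FEve, the minimum-spanning-tree evenness index, and FDis, the
  abundance-weighted mean distance to the abundance-weighted centroid,
  both on Euclidean distances over the three traits z-scored across the
  full species pool of the dataset (all traits are numeric, so Gower
  distances would add nothing). FEve needs ≥ 3 species; species with any
  missing trait are dropped from both indices with abundances
  renormalized;
- functional range (product of per-trait ranges) is computed for reports
  but never enters a model: it is largely redundant with richness.

MST construction uses `scipy.sparse.csgraph` (a constant is added to all
edge weights so coincident species are not read as absent edges, which
leaves the tree unchanged); ties among equal distances are broken by the
implementation's deterministic scan order. Metrics are cached per
(plot, focal species): two conspecific focals see identical
neighborhoods.

## Design, transformations, and the model ladder

Planting age, maximum height, and solar radiation are ln-transformed and
neighbor density square-root-transformed before modeling; all continuous
predictors are then z-standardized (sample SD, n−1) over the pooled
focal dataset, so partial slopes are comparable across predictors and
genera. The standardizer stores its means and SDs so that fixed raw
moisture values can be located on the modeled scale. Genus is coded by
treatment contrast with *Acacia* as reference; per-genus slopes are
reported as linear combinations (Eucalyptus slope = main + interaction)
with delta-method standard errors, which makes the report invariant to
the coding.

The seven fixed-effect structures are strictly nested along two chains
(base → no_genus → genus_intercepts → genus_slopes →
genus_slopes_moisture, and no_genus → no_genus_moisture →
genus_intercepts_moisture → genus_slopes_moisture), enabling valid
likelihood-ratio tests. Marginality is enforced: every lower-order term
of any interaction is present, so the moisture main effect appears in
all moisture models. Plot area is a design covariate; following a
screening analysis in which plot area interacts with every other
predictor and interactions with |z| ≥ 1.96 are retained, the default
ladder hard-codes a single retained interaction, plot_area ×
prop_intraspecific. The screening procedure itself is exposed as
`screen_plot_area_interactions`. Collinearity is checked by VIFs on the
main-effect design with a warning threshold of 3; the synthetic default
configuration stays near 2.2.

## The mixed-model fitter

The growth models carry four crossed/nested random-intercept factors
with up to ~10³ combined levels, beyond what off-the-shelf Python mixed
models handle comfortably at this scale, so the fitter is purpose-built
(statsmodels' MixedLM serves as an independent cross-check in the test
suite on small crossed designs). Both the fixed effects and the residual
variance are profiled out; the optimizer works on the relative standard
deviations λ_f = σ_f/σ_e only. Each objective evaluation performs one
bordered Cholesky factorization of

    [ DZ'ZD + I   DZ'X ]           D = diag(λ per column of Z)
    [ X'ZD        X'X  ]

whose leading and trailing diagonal blocks give log|A| and log|X'V⁻¹X|
simultaneously, with all cross-products precomputed once — evaluation
cost is independent of the number of observations. Profiled criteria:

    ML:   log|A| + n(1 + log(2π r²/n))
    REML: log|A| + log|X'V⁻¹X·σ²| + (n−p)(1 + log(2π r²/(n−p)))

with r² the penalized residual sum of squares. REML is used for all
reported estimates; ML refits feed AIC and likelihood-ratio tests, with
the AIC parameter count including all variance components and the
residual.

Numerical choices: a single factor is optimized by bounded Brent on the
log scale (this path reproduces the balanced one-way ANOVA closed form
to ~10⁻⁸). Multiple factors use Nelder-Mead on the λ scale with
absolute-value folding, which turns the σ_f → 0 boundary into a smooth
interior point; relative SDs below 10⁻⁴ are reported as exact zeros with
a boundary flag. Non-convergence triggers restarts from a fixed grid of
shared relative SDs before a fit is flagged (flagged fits are excluded
from comparisons). Boundary likelihood-ratio p-values are *not*
mixture-corrected — plain χ² upper tails are reported, favoring fidelity
to common practice over refinement. Pseudo-R² follows the variance-
partitioning definition: marginal = var(Xβ̂)/(var(Xβ̂) + Σσ²ᵣ + σ²ₑ)
with var(Xβ̂) the population variance of fitted fixed-effect predictions
over the estimation sample; conditional adds Σσ²ᵣ to the numerator.

## Permutation nulls

The null for each standardized partial slope comes from shuffling growth
rates uniformly across all focal plants dataset-wide — deliberately not
stratified by plot, planting, or genus (a stratified option exists but is
off by default) — and refitting the full model structure, random effects
re-estimated, on every shuffle. Per-permutation seeds are base_seed +
index, so runs parallelize reproducibly. Permutation refits warm-start
from the previous permutation's variance ratios (shuffled responses share
a near-structureless optimum) under loosened tolerances; the harvested
slopes are insensitive to the variance ratios at this accuracy. Fits
that still fail to converge are dropped and counted, and more than 1%
of them aborts the run.

The empirical p is two-sided with the +1 correction,
p = (1 + #{|null| ≥ |obs|})/(n_perm + 1), never exactly zero. The
"significant" flag compares the observed slope to the null 2.5–97.5
percentile interval; the null SD is also recorded so a ±1.96·SD
rectangle can be reconstructed if preferred. Moisture conditions default
to the dataset's own 10th/90th quantiles; the fixed 0.27/0.76 contrast
is available for comparability with published analyses of this system.

A known property of the unrestricted shuffle: for predictors that vary
within groups, strong random-effect variance makes the null wider than
the observed slope's sampling distribution (conservative); the test is
exactly calibrated when the exchangeability assumption holds, i.e., when
grouping variance is small relative to residual. The calibration study
in the acceptance suite therefore simulates a reduced design — two
random factors (planting, species) with variances a few percent of the
total, ~1,400 focals, a three-predictor genus-slopes model, and the
tested coefficient exactly zero — under which the nominal 5% level is
achievable; with 199 permutations the percentile interval's small-sample
discreteness adds about a point of anti-conservatism. Under the full
default variance structure the same test is conservative for
within-plot predictors, which should be kept in mind when interpreting
"ns" flags on real data.

## The synthetic-data generator

Defaults mirror the study system the pipeline was built for: 137
plantings in 10 subregions, ~3.6 plots per planting, plot areas
truncated-normal with mean 232 m² (SD 116, all < 400 m²), plot occupancy
a truncated negative binomial with mean 34.8 and SD 25.6 (minimum 10
plants, matching the smallest surveyed plots; a lower minimum exercises
the under-occupied code path), planting ages truncated-normal mean 12 yr
(SD 5.27) on [4, 33], 43 *Acacia* and 80 *Eucalyptus* focal species plus
30 other-genus species with 40% per-trait missingness, and per-genus
log-normal trait distributions with broad overlap. Moisture is uniform
on (0.21, 0.82) — placing the 10th/90th quantiles near 0.27/0.76 — and
solar radiation is a Gaussian linear response to moisture calibrated to
a correlation of −0.69. Plot composition is Dirichlet-multinomial over a
small species set; every plot seeds one species of each focal genus
(the genera co-dominate these plantings), with other-genus stems scaled
to ~35% of individuals. A single global seed fans out to fixed per-stage
child seeds.

Growth is simulated as rgr = Xβ + b_subregion + b_planting + b_plot +
b_species + ε on the standardized design of the full moisture-interaction
model (absent truth terms are zero; realized intercepts are stored for
recovery tests). Focal diameters are then *back-computed* through the
inverse allometry from B = exp(rgr·t), so the measurement pipeline
(diameter → biomass → RGR) reproduces the simulated response exactly and
a realistic few percent of plants fall below the 0.1 kg exclusion
boundary; non-focal plants get age-dependent log-normal diameters. One
consequence: the analysis standardizes over the post-filter focal set
while the simulator standardizes over all candidates, a sub-percent
scale difference absorbed by the recovery tolerances.

The default truth sets main effects following the qualitative pattern
seen in such plantings (growth slower in older plantings and denser
neighborhoods; trait effects differing between genera) and a subset of
genus/moisture interaction terms at standardized magnitude ±0.05, the
rest exactly zero. Variance components (subregion 0.006, planting 0.016,
plot 0.006, species 0.007, residual 0.050) are calibrated so an
intercept-only fit yields conditional pseudo-R² ≈ 0.54 with zero
marginal — the hallmark of strong design structure; the calibration
accounts for group-level fixed signal being absorbed by the random
intercepts in that fit.

What the generator does *not* emulate: stem coordinates (none existed in
the source surveys), mortality and recruitment, grass-layer competition,
temporal remeasurement, spatial autocorrelation beyond the subregion
intercept, and multi-stemmed growth forms. Passing tests therefore
demonstrate the statistical machinery under the assumed generating
model, not robustness to these real-data complications.

## Problem sizes in the automated checks

The test suite scales its simulations to desk-scale runs as a package
choice: truth-recovery uses 20 replicate landscapes of ~120 plantings /
~400 plots / ~8–9 thousand focals; ladder discrimination 25 replicates
at ~50 plantings; null calibration 200 reduced datasets (~1,400 focals,
199 permutations each); oracle checks run 1,000 random neighborhoods and
every abundance configuration with ≤ 12 individuals. The acceptance
script runs one full-ladder analysis at the 120-planting scale plus one
reduced permutation study.

## Known limitations

- Variance-component estimates for factors with few levels (10
  subregions) are noisy in any single dataset; only their average over
  replicates is held to a tight tolerance.
- The AIC counts parameters naively (fixed + variance components); no
  small-sample correction is applied.
- LRT p-values at variance boundaries are anticonservative in theory
  (no 50:50 mixture correction), as noted above.
- The congener-interpolation radius treats a planting as a point; plots
  within a planting share coordinates.
- The permutation test's calibration depends on exchangeability, as
  discussed; stratified permutation is available but off by default to
  match the dataset-wide shuffle as specified.
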