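# revegrowth

Models of individual plant growth rate in mixed-species restoration
plantings.

Ecological restoration plantings across climatic gradients mix dozens of
woody species, and the growth of any one plant reflects its species'
traits, the planting's climate and age, and the density and diversity of
its neighbors. This package implements the full analysis pipeline used to
ask how those drivers differ between the two dominant genera of such
plantings — nitrogen-fixing *Acacia* and canopy-forming *Eucalyptus* —
and how their effects shift along a moisture-availability gradient. It
is written for quantitative ecologists who have plot-inventory data (or
want to study the method itself on simulated data with known truth).

## What it computes

**Growth rate.** Aboveground biomass is estimated from stem diameter via
allometric equations `ln B = a + b ln D`, and relative growth rate is

    RGR = ln(B) / t        [kg kg⁻¹ yr⁻¹]

with planting age *t*, assuming zero mass at planting. Focal plants under
0.1 kg are excluded as likely post-planting recruits.

**Neighborhood predictors.** For each focal, all other plants in its plot
provide: density (plants ha⁻¹), proportion of conspecific neighbors,
rarefied species richness E[S₉] (hypergeometric expectation for 9
neighbors), and the functional-diversity indices FEve (minimum-spanning-
tree evenness) and FDis (abundance-weighted dispersion) over z-scored
SLA, wood density, and maximum height. Missing neighbor traits are
interpolated from congeners within 50 km.

**Mixed models.** RGR is modeled with linear mixed models carrying four
random-intercept factors — subregion ⊃ planting ⊃ plot, crossed with
species — fit by a profiled REML/ML optimizer built for crossed designs
with thousands of levels. Seven nested fixed-effect structures of
increasing complexity (intercept-only up to three-way
moisture × genus × predictor interactions) are compared by AIC,
likelihood-ratio χ², and marginal/conditional pseudo-R².

**Permutation nulls.** Growth rates are shuffled between focal plants
(1000 times by default) and the model refit on every shuffle, giving a
null distribution for each standardized partial slope per genus — and,
for the moisture model, at "dry" and "mesic" moisture values (10th/90th
dataset quantiles by default, or the fixed 0.27/0.76 contrast).

**Synthetic data.** Because real planting inventories of this kind sit
under data-sharing agreements, a first-class generator produces datasets
with the same nested design, occupancy, trait, and climate structure from
a known coefficient set, so every stage is testable end to end.

## Worked example

`examples/model_ladder.py` simulates a 40-planting landscape under the
default truth (a genus- and moisture-dependent slope model), runs the
measurement pipeline, and fits the ladder:

```
3274 focal plants (123 excluded below 0.1 kg biomass)

model                                AIC      dAIC  marg R2  cond R2
base                              -166.2       0.0    0.000    0.479
no_genus                          -200.7     -34.5    0.137    0.475
genus_intercepts                  -199.4     -33.2    0.139    0.477
genus_slopes                      -285.0    -118.9    0.210    0.489
no_genus_moisture                 -322.6    -156.4    0.207    0.489
genus_intercepts_moisture         -321.2    -155.1    0.208    0.490
genus_slopes_moisture             -386.2    -220.0    0.270    0.490

no_genus vs genus_slopes: chi2 = 110.4, df = 13, p = 1.6e-17
```

The generating model (`genus_slopes_moisture`) attains the lowest AIC;
genus-specific slopes improve fit far more than genus intercepts alone;
and the base model's conditional R² near 0.5 with zero marginal shows how
much growth-rate variance sits in the nested design before any predictor
enters. The other examples cover dataset simulation, the neighborhood
metrics on a hand-built plot, and observed-vs-null slope tables.

## Command line

A thin CLI drives batch runs from one YAML config:

```bash
revegrowth simulate -c config.yaml -o outdir   # synthetic dataset CSVs + truth.yaml
revegrowth metrics  -c config.yaml -o outdir   # biomass, RGR, neighborhoods, standardization
revegrowth fit      -c config.yaml -o outdir   # model comparison, coefficients, VIF
revegrowth null     -c config.yaml -o outdir   # permutation null report
revegrowth report   -c config.yaml -o outdir   # final tables
```

Repeated runs with the same config and seed are byte-identical.

### Data formats

`plants.csv`: plant_id, plot_id, planting_id, subregion_id, species,
genus, measure_height_cm (10/50/130), diameter_cm. `plots.csv`: plot_id,
planting_id, area_m2. `plantings.csv`: planting_id, subregion_id,
lon, lat, moisture, radiation, age_yr. `species_traits.csv`: species,
genus, sla (mm² g⁻¹), wood_density (g cm⁻³), max_height (m), plus
per-trait provenance (measured / interpolated / missing). Allometric
coefficients are user-supplied as `allometry.csv` (key,
measure_height_cm, a, b) keyed by species or life form; the packaged
synthetic table serves simulations and tests.

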