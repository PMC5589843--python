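# Methods

`lakecoupling` estimates, for each of many large lakes, the *interannual*
association between surface chlorophyll-a (chl-a, a phytoplankton-biomass
proxy, mg m⁻³) and lake surface temperature (LST, °C) from gapped
satellite-style grids, and then asks which lake characteristics explain why
some lakes warm into higher phytoplankton biomass while others warm into
lower biomass. This note records the model, the estimator, the synthetic
world used to exercise it, and the numerical choices that were genuinely
open.

## 1. The inference target

All observations are reduced to a common resolution of 0.1° cells and 5-day
bins (spatial medians, then temporal medians; half-open cells anchored at
multiples of 0.1°, bins anchored at Jan 1 with bin 73 absorbing days
361–366). Within one lake, the pairs are subdivided by pixel and by 5-day
day-of-year stratum, so a subdivision holds at most one (LST, chl-a) pair
per year. The association inside a subdivision is the tie-corrected Kendall
rank correlation τ_b across years — an interannual quantity by
construction, blind to the (much larger) seasonal covariation. Subdivisions
with fewer than eight coincident years, or with degenerate ranks (all
values tied), are dropped and counted.

The lake-level target is the *balanced* mean of the stratum correlations,

  r_lake = mean over (pixel, stratum) of τ(pixel, stratum),

with every pixel and every stratum weighted equally. The observed stratum
correlations r_i are not balanced: clouds and ice over-represent particular
seasons and places, so the naive mean of the r_i is biased toward the
best-observed strata.

## 2. The bias-corrected estimator

Per lake, a boosted regression tree models r_i on (latitude, longitude,
day-of-year stratum); lakes with more than 10,000 stratum correlations are
fit on a seeded uniform subsample of exactly 10,000. The fitted surface is
then resampled *uniformly*: each of n ensemble members draws a pixel (an
observed (lat, lon) pair, with replacement) and a stratum (with
replacement) from the lake's unique observed lists, takes the model
prediction there, and adds one residual from the training-residual pool
drawn without replacement (the pool is a permutation consumed exactly
once). r_lake is the ensemble mean; a two-sided Wilcoxon signed-rank test
of the members against zero and a Benjamini–Hochberg correction across
lakes give the significance flags. The signed-rank test is applied to the
ensemble members because r_lake is defined from them; members are not
independent (they share one fitted surface and one residual pool), so the
test is anti-conservative — the null-calibration test asserts only a soft
bound (≤10% nominal rejections at α = 0.05 across uncoupled lakes) and
this caveat stands.

Pixel/stratum resampling is with replacement (without-replacement is
impossible once n exceeds the number of unique combinations) and pixels are
drawn as observed pairs rather than independent marginals, so the surface
is never evaluated at never-observed off-lake locations.

## 3. The boosting protocol

Squared-error stagewise boosting over shallow best-first CART trees
(scikit-learn's `DecisionTreeRegressor` is the base inducer; the protocol
layers are implemented here):

- **Tree complexity** = number of predictors in the model (splits per tree),
  so the per-lake surface uses 3-split trees and the cross-lake model
  8-split trees.
- **Tree count** chosen at the minimum of the k-fold cross-validated
  deviance (default k = 10; the shipped configuration and the tests use
  k = 3 for desk-scale runtime), with an early abort once the running
  minimum has not improved for `patience` stages (default 100; 30 in the
  shipped configuration). An accepted fit must select between 1,000 and
  10,000 trees.
- **Learning rate** searched on the descending grid 0.1, 0.05, 0.01, 0.005,
  0.001, 0.0005, 0.0001; the first rate whose selected tree count lands in
  the window wins; 0.0001 is the admissibility floor.
- **Weights** are non-negative per-observation multipliers of the loss and
  of the influence accounting (the cross-lake model weights each lake by
  1 − p of its Wilcoxon test).
- **Missing predictor values** are routed by the base tree's learned
  default split direction; rows are never dropped. Unknown categorical
  levels at prediction time are routed as missing.
- **Relative influence** is the weighted squared-error improvement summed
  over every split, per predictor, normalized to 100%.
- **Partial dependence** is empirical marginalization: the focal column of
  the training matrix is overwritten with each grid value and predictions
  are averaged over all training rows. The isolated median-chl-a effect
  curve is this quantity on a log-spaced grid over the observed range
  (display transforms: log₁₀ x, asinh y).
- Bag fraction 0.5 (rows subsampled without replacement per stage),
  deterministic under the spec seed; predictors enter in sorted-name order
  and the cross-lake table is canonicalized by lake id, so neither column
  nor row order can change a fit.

**Featureless surfaces.** The tree-count window is reachable only when the
response surface has structure: the selected count grows roughly as
1/learning-rate when a deviance dip exists, and stalls near zero when it
does not (more trees then only overfit, at every rate). A constant-coupling
lake is the cleanest example. Eliminating such lakes would discard exactly
the cases where the naive and balanced means agree, so the tuner instead
raises its insufficient-data signal carrying the best converged fit, and
the debias stage keeps the lake with that small-ensemble surface
(predictions ≈ the lake mean — the correct balancing surface when there is
nothing to correct), flagging it `null_surface`. Lakes below a 30-row
stability floor are still eliminated with reason code
`learning_rate_floor`. A constant (single-valued) τ field short-circuits to
an exact constant surface.

## 4. Rank statistics

- Kendall τ_b by direct pair counting (samples never exceed the year
  count). Two-sided p-values: exact null for n ≤ 10 without ties (Mahonian
  convolution of the inversion-count distribution; p = P(|S′| ≥ |S|)),
  tie-corrected normal approximation otherwise, no continuity correction.
- Wilcoxon signed-rank: zeros dropped, average ranks on tied magnitudes;
  exact null by convolution over sign assignments for ≤ 25 nonzero values
  (p is the symmetric tail mass P(|W − μ| ≥ |w − μ|)), normal approximation
  with continuity correction above.
- Multiplicity: Benjamini–Hochberg step-up (the correction method was an
  open choice; BH is the field default for large batches of dependent-ish
  tests).

## 5. The synthetic world

The generator emulates the statistical structure the estimator assumes, not
satellite physics. Per lake: a grid of 0.1° pixels (default 10×10 for
single-lake studies, 3×3 in the shipped multi-lake configuration), 73
five-day bins, default 15 years. Within each (pixel, bin) stratum the
interannual anomalies of LST and log chl-a are a bivariate standard normal
pair with correlation ρ(pixel, bin) — a Gaussian copula, chosen because the
implied Kendall correlation has the closed form τ = (2/π) arcsin ρ, giving
an analytic oracle; the pipeline itself never assumes Gaussianity. LST is a
seasonal cosine (amplitude 8 °C, hemisphere-aware phase, annual mean tied
to the lake's median-temperature attribute) plus a 1 °C interannual
anomaly; chl-a is the lake median times a lognormal seasonal/anomaly factor
(seasonal log-amplitude 0.4, interannual log-sd 0.5) — strictly positive,
and harmless to τ since Kendall correlation is invariant under monotone
transforms. Each stratum-year cell is retained independently with a
per-(pixel, bin) probability (cosine or two-level seasonal ramp, optional
spatial tilt); dependent cloud runs are out of scope.

The cross-lake world draws median chl-a log-uniformly over 0.1–100 mg m⁻³.
With amplification on, the lake-mean ρ is a strictly increasing linear
function of log₁₀ median chl-a crossing zero near the middle of the
gradient (~3 mg m⁻³): warm anomalies depress chl-a in phytoplankton-poor
lakes and raise it in phytoplankton-rich ones. Within-lake structure
defaults to a seasonal ρ amplitude of 0.2 and a north–south tilt of 0.1 —
strong enough that the tuned per-lake fits typically land in the tree
window. Catalog attributes (elevation, latitude, area, perimeter, depth,
salinity class, median temperature) are drawn at plausible large-lake
scales, with a configurable 10% of non-key entries deliberately missing.
In-situ samples are observed grid cells plus Gaussian LST error and a
multiplicative chl-a bias (plus optional lognormal error), so standardized
major axis (SMA) validation slopes away from 1 can be produced on demand.

What a green test does **not** establish: realistic cloud climatology or
persistence, within-stratum autocorrelation across years (the generator
assumes independent years), optical-water-type complexity in the chl-a
proxy, or the magnitudes any particular real archive would produce.

## 6. Validation statistics

In-situ samples match their nearest coincident satellite cell (great-circle
distance ≤ 4 km — one cell at the reduced scale — and ≤ 5 days; ties broken
by temporal offset, then lexically; distances tie at millimetre
resolution). Per variable and per lake-level comparison: SMA slope
(sign(r)·sd(y)/sd(x)) with the standard F-based 95% interval, Pearson
correlation, and median absolute error; the report flags whether the slope
interval covers 1. Whether chl-a is compared raw or log-transformed is
configurable (raw by default).

## 7. Reproducibility and limits

Every stochastic step is seeded from the run configuration; re-running an
identical configuration reproduces byte-identical artifacts (the manifest
records a config hash and no timestamps enter the outputs). Known limits:
the Wilcoxon anti-conservatism above; no spatial-autocorrelation-aware
standard errors; no lagged cross-correlations; the featureless-surface
fallback is this package's own resolution of a protocol corner the source
procedure leaves undefined.
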