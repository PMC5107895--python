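# Methods

This note documents the models and procedures the package implements, the
defaults and why they hold, what the synthetic worlds do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Predictor construction

Environmental predictors are long-term monthly extremes at the seabed. For
each analysis cell whose bottom depth lies in the mesophotic working window
(default 15–200 m), the variable is interpolated trilinearly — bilinear in
lon/lat, linear in depth — from the coarse climatology at
(lon, lat, bottom depth), separately for every year × month. Within each
year the extreme month is taken, and extremes are averaged across years.
The alternative reading (extreme of the across-year monthly climatology)
coincides with this one when interannual variability is zero; a unit test
pins that equivalence. Depth queries above the first or below the last
climatology level are clamped to the nearest level, because profile
products rarely start exactly at the window's upper edge; horizontal
queries outside the hull of coarse cell centers are missing.

Monotone signs attach to the statistic: a minimum-type predictor can only
limit a niche from below (sign +1), a maximum-type from above (−1), and
terrain (slope) is unconstrained (0).

Slope uses Horn's 3×3 weights on metric distances (R = 6371 km sphere,
east–west cell size scaled by cos φ), reported in degrees; edge cells and
cells with any missing neighbour are missing. Slope is invariant to adding
a constant to the bathymetry, and depth sign conventions cancel in the
magnitude.

Interpolation quality control correlates bottle (water-sample) values with
the value interpolated at each bottle's (lon, lat, depth, month, year); the
bottle's own year and month are used when inside the profile span,
otherwise the climatological month. Under 1:1 signal-to-noise the expected
attenuation is r = 1/√2, which the test suite verifies by simulation.

## Occurrence processing

Grid bathymetry — not the depth reported with a record — is the
authoritative plausibility filter: records on land cells or deeper than the
window are dropped, and reported depth is retained only as metadata.
Surviving records snap to cell centers, one record per (cell, label).

Spatial dependence is measured with a multivariate Mantel correlogram:
Euclidean distance on z-scored predictor values at the record cells,
correlated per contiguous distance class (default 2.5 km classes up to
50 km) with class membership, permutation p-values (default 9999
permutations; the same permutations serve all classes) and the sign flipped
so that positive autocorrelation reads positive. The autocorrelation range
is the upper edge of the initial run of positive significant classes;
leading classes with fewer than two pairs (possible when the grid cell
exceeds the class width) are skipped rather than treated as failures.
Thinning then keeps a maximal subset with pairwise great-circle distance
at least that range, visiting records in a seeded random order (the
tie-break is not prescribed by the method, so it is randomized and
seeded); greedy acceptance guarantees every dropped record lies within the
radius of a kept one, and thinning is idempotent.

## Pseudo-absences

The Environmental Suitability Map assigns each cell the upper-tail
chi-square probability (df = number of predictors) of the Mahalanobis D²
between its z-scored predictor vector and the presence mean under the
presence covariance. The covariance receives a ridge of 10⁻⁶ × mean
diagonal before inversion; a condition number above 10¹² after that is an
error naming the most collinear pair (with the relative ridge this is a
defensive bound — exact duplicates already pass at condition ~10⁶, which a
test documents). Cells with suitability ≤ 0.2 and no presence form the
candidate pool; K-means (k-means++, 10 restarts, seeded) with k equal to
the number of presences structures the pool into environmentally
dissimilar groups, and one cell per group is drawn with probability
proportional to the kernel-density effort surface (uniform in groups with
no effort mass). One absence per cluster yields balanced classes — the
method sets k but not the final count, and a 0.5 prevalence removes the
intercept's dependence on an arbitrary background size. The effort
bandwidth defaults to the Mantel autocorrelation range, the one length
scale the data themselves provide.

## Boosted trees with monotone constraints

The boosting core is written for this package: binary response, Bernoulli
deviance −2·mean(y log p + (1−y) log(1−p)) with probabilities clipped to
[10⁻⁹, 1−10⁻⁹], intercept at the log-odds of training prevalence. Each
stage draws `bag_fraction` of the rows without replacement (seeded), fits a
regression tree to the negative gradient (y − p) by greedy best-first
splitting on squared-error reduction with `tree_complexity` = number of
splits (tc = 1 gives stumps; best-first growth is the implemented reading
of an unstated growing order), sets leaf values by one Newton step
(Σ residuals / Σ p(1−p)) and adds the tree with shrinkage `learning_rate`.

Monotone constraints act at split time and through bounds: a split on a
constrained predictor is rejected if the clipped child values violate the
required order, and the midpoint of the accepted child values becomes a
bound on every descendant leaf. Each tree is therefore monotone in each
constrained predictor, hence so is the additive model and its partial
dependence — the audit asserts this to 10⁻¹². Missing predictor values are
rejected outright; the pipeline masks cells instead, since predictor
rasters are complete on working-window cells.

Partial dependence is the mean prediction over training rows with one
column forced to each grid value, on the probability scale.

## Spatial cross-validation, selection, contribution

Records are sorted by longitude and cut into 10 contiguous equal-count
(±1) bands — equal-count rather than equal-width, so clustered records
cannot empty a fold. For every predictor combination with pairwise
|Pearson r| < 0.8 (enumeration capped at 500, seeded-sampled beyond), each
(lr, tc) grid point is scored by mean held-out Bernoulli deviance across
bands; TSS and deviance explained (1 − residual/null, with the null at the
training prevalence) are recorded per fold at the winning point. Folds
with a single class in either side are skipped with a warning. Trees are
fixed (default 2000, at least 1000) rather than early-stopped.

Model-set selection ranks combinations by mean fold TSS and descends,
retaining each candidate whose fold-TSS vector a two-group Kruskal–Wallis
test cannot distinguish **from the best combination's vector** at
α = 0.05, stopping at the first rejection. Two anchoring choices keep the
descent selective. First, the reference is the fixed best vector, not a
pool of everything retained so far — a pooled reference drifts downward as
mediocre combinations accumulate and ends up admitting nearly everything
(observed empirically: 34 of 35 combinations retained). Second, the test
is one-sided: the descent asks whether a candidate is *inferior* to the
best, and its mean never exceeds the reference's by construction, so the
two-sided p is halved. With fold-TSS standard deviations around 0.15 (ten
spatially heterogeneous bands), a two-sided test at α = 0.05 retains
combinations a full 0.13 of TSS below the best; the diluted median then
re-admits cells that only the missing predictor could exclude.

Predictor contribution is the mean held-out deviance decrease over all
evaluated pairs (C, C ∪ {j}), reported as a percentage of the summed
positive contributions; predictors with no such pair are flagged rather
than silently zeroed. The minimum combination size is 2 — a one-predictor
niche model is degenerate.

Contribution also feeds an overfitting guard: predictors whose mean
held-out deviance decrease is not positive are discarded, and combinations
using them are removed from the selection candidates before the descent.
Without the guard, noise-predictor combinations that the Kruskal–Wallis
test cannot statistically separate from the best slip into the ensemble,
and their median vote re-admits map cells that only an informative
predictor could exclude.

## Ensemble, reclassification, accounting

Selected combinations are refitted on the full record set at their tuned
hyperparameters; cell-wise median and standard deviation form the
prediction and uncertainty surfaces. The median's record-level predictions
are thresholded at the value maximizing sensitivity + specificity (ties →
the lowest threshold, favouring sensitivity, the conservation-minded
choice); the binary map is intersected with the hard-bottom mask, with
missing substrate propagated as missing rather than absent. Areas use the
spherical-rectangle formula (R·Δφ)(R·Δλ·cos φ) at the cell-center
latitude; MPA membership tests cell centers against the polygons (bias
below one cell ring per polygon at analysis resolutions); every percentage
is computed against its own denominator. Limiting points are extracted
from the environment-only binary map — substrate is not an environmental
axis — and a predictor whose extreme over presence cells coincides with
its raster extreme is flagged as imposing no tipping point in the region.

## The synthetic study system

The default world plants a known truth in data with the statistical
hazards the method is built for: presence-only sampling, spatially biased
effort, collinear predictors, spatial autocorrelation.

- **Grid**: 200 × 200 cells; default extent 0–16°E, 30–46°N at 0.08°
  (~1600 km), a domain large relative to the 50 km correlogram window, as
  in shelf-scale surveys. On much smaller domains every ≤50 km pair is
  "near" relative to the domain and the detected range pins at the cap,
  which starves the pipeline after thinning.
- **Bathymetry**: land band along the east, shelf deepening westward
  (slope scaled to the extent so the 15–200 m window spans most of the
  sea), three seamounts rising to 25–60 m.
- **Environment** (monthly, 11 years × 12 months × 8 depth levels on a
  0.25° lattice): per variable, latitudinal gradient + spatially modulated
  seasonal sinusoid (damped with depth, scale 350 m — a well-mixed-shelf
  regime that spreads both thermal edges across the whole domain) +
  vertical lapse + short-range anomaly field (temperature sd 2.5 °C at
  ~10 km) + per-year offset. Anomalies dominate record-level environmental
  relatedness, so the Mantel range lands at ~10–25 km, the regime reported
  for real coastal records; the seasonal-amplitude variance (2.8 °C) keeps
  corr(temperature_min, temperature_max) safely below the 0.8 collinearity
  cap so the min/max pair of the same variable remains jointly usable, as
  in the real predictor sets this emulates.
- **Niche truth**: suitability = logistic ramp of temperature_min above
  14 °C × logistic ramp of temperature_max below 24 °C, edge softness
  0.15 °C. The responses cross 0.5 exactly at the planted limits, so "the
  suitability ≥ 0.5 region" and the nominal plateau edges coincide; a much
  softer edge would widen the occupied envelope beyond the nominal limits
  and make them unidentifiable at sub-degree precision by any estimator.
- **Sampling**: 150 presence cells drawn without replacement with
  probability ∝ suitability × effort, effort 3:1 west:east; hard bottom
  covers ~40% of sea cells in ~20 km patches; 5 MPA polygons; 300 bottle
  samples.

What the generator does **not** emulate: ocean dynamics (no advection,
fronts or eddies beyond stationary anomaly fields), detection error in the
records, taxonomic misidentification, depth-reporting error, coastline
complexity, or real geography. Passing tests therefore demonstrate that
the pipeline recovers a known niche under idealized but adversarial
sampling — not that any real map is correct.

## Problem sizes and profiles

`PipelineConfig` defaults carry the literature values throughout
(|r| < 0.8, ESM ≤ 0.2, lr grid {0.01, 0.005, 0.001, 0.0005}, bag 0.5,
≥1000 trees, 10 folds, α = 0.05, 15–200 m window, 50 m mesophotic cutoff,
9999 Mantel permutations). `fast_profile()` is the package's
minutes-scale configuration for end-to-end synthetic studies: lr grid
{0.01, 0.005}, tc up to the combination size, 1000 trees, combination
sizes 2–3, 999 Mantel permutations — every scientific threshold unchanged.
The test suite and the acceptance script use it; a full-grid run is a
config change away.

## Known limitations

- The correlogram's permutation test is two-tailed per class with no
  multiple-testing correction across classes; the initial-run range rule
  is therefore slightly liberal.
- K-means with k = n-presences on a large pool can in principle yield
  empty clusters; scikit-learn's implementation repairs them, and a
  bounded re-seeding loop guards the remainder.
- Limiting points are extremes over predicted-presence cells and inherit
  the fragility of extreme statistics: a handful of spurious cells moves
  them. The ensemble median damps this but does not remove it.
- Roughly one synthetic world in eight yields a weak best model (the warm
  niche edge poorly covered by the biased sampling of that draw), and
  recovery there is marginal (balanced accuracy ~0.87, limit errors around
  0.5 °C) under any selection rule — a reminder that the method's output
  quality tracks the spatial coverage of the records.
- Cell-center MPA membership and spherical (not ellipsoidal) areas bias
  accounting by well under a percent at analysis resolutions; an
  ellipsoid would be a config-level change.
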