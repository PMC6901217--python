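# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, what the synthetic
data generator does and does not emulate, and the numerical decisions
that affect results.

## Data model and geometry

Rasters are plain 2-D arrays in WGS84 decimal degrees with an explicit
nodata mask; row 0 is the northernmost row and the origin is the outer
corner of the upper-left cell (cell centers at `origin + (idx+0.5)·Δ`).
No projected CRS is supported: every distance is great-circle
(haversine) on a sphere of radius 6371 km, and cell areas use the
spherical approximation `A = (πR/180)²·Δlon·Δlat·cos(φ_center)`, which
agrees with the exact zonal band area to well under 0.5 % at the
resolutions involved.  A point on a shared cell edge belongs to the
cell to the south-east (half-open cells), so coordinate→cell lookup is
unambiguous.

Site buffer extraction averages all valid cells whose *centers* lie
within the buffer radius (default 5 km).  Center membership rather
than polygon intersection was chosen because it is stable across
resolutions and has no partial-cell weighting ambiguity; when no
center qualifies (coarse grids), the nearest valid cell is used and
the result is flagged.

## Calibration

The simple calibration is OLS of measured tissue δ²H on the 5-km
buffer mean of the base isoscape.  The fitted model retains everything
prediction variance needs (x̄, Sxx, s², the coefficient covariance),
serialises to JSON, and keeps its training residuals for diagnostics.

The direct multiple-regression model starts from the full candidate
covariate set and removes, at each step, the single covariate whose
removal most lowers the Gaussian AIC `n·log(SSE/n) + 2k` (additive
constant dropped; `k` counts mean parameters including the intercept),
stopping when no removal lowers it.  Selection is on AIC alone; each
step's candidate p-values are logged on the model for audit but impose
no threshold.  Ties are broken by removing the covariate with the
largest p-value.  Note the known property of AIC selection that a pure
noise covariate survives whenever its squared t-statistic exceeds 2
(≈ 16 % of null replicates); the tests assert elimination at that rate
rather than always.

### Residual diagnostics

Spatial autocorrelation of training residuals is tested with Moran's I
under inverse-great-circle-distance weights, row-standardised.  The
weighting scheme and inference route are genuinely open choices;
inverse distance with a permutation p-value (999 permutations of the
residuals across sites, two-sided with add-one smoothing) was adopted
as the most assumption-light default, and both the weight floor for
near-duplicate coordinates (`min_distance_km`) and the permutation
count are configurable.  Exact duplicate coordinates raise an error
rather than being silently jittered.

## Variance propagation

For a calibrated isoscape the per-cell total is

    σ_i² = b̂²·σ²_base,i + s² + s²(1/n + (x̂_i − x̄)²/Sxx) + 2·b̂·cov_i.

Two deliberate choices:

* The base-isoscape prediction variance enters scaled by b̂², because
  base-model error passes through the calibration slope before
  reaching tissue scale.  An unscaled mode
  (`scale_base_by_slope=False`) exists for sensitivity analysis.
* No closed form is assumed for the covariance between the two
  prediction errors (component iv); the caller may supply a per-cell
  covariance grid, which enters as `2·b̂·cov_i`, and the default is
  none (0).  Any negative total cell aborts with a propagation error
  naming the components.

For a direct-MLR isoscape the base-model components are absent and the
total is `s² + x_iᵀ Σ_β x_i`.

An empirical alternative to the analytic calibration-line term is
`cv_prediction_variance`: per-site squared held-out errors from
repeated k-fold refits, smoothed onto the grid by inverse-distance
weighting (power 2, exact hits take the site value, output floored at
1e-12 so downstream likelihoods stay defined).  Kriging was considered
and left out of scope.

## Assignment

Likelihood, posterior and rescaled surfaces are computed entirely in
log space and normalised by log-sum-exp; the raw Gaussian density
underflows double precision once |δ_s − δ̂_i|/σ ≳ 40, which genuine
outliers reach.  "Rescaled between 0 and 1" is implemented as division
by the maximum of the normalised surface (a Gaussian posterior's
minimum is already ≈ 0); min–max rescaling is available behind
`rescale_mode="minmax"`.  The assignment region uses a *strict*
inequality, rescaled > threshold, with the 2:1-odds default 2/3.

## Metrics

* Accuracy difference: rescaledA − rescaledB at the true-origin cell.
* Precision area: total area of cells with rescaled probability ≥ the
  value at the true-origin cell.  Ties are included so the metric is
  defined on flat surfaces; at the surface maximum it degenerates to
  the area of the tied top cells.
* Similarity: for thresholds q ∈ {0, step, …, 1} the Jaccard overlap
  |maskA ∩ maskB| / |maskA ∪ maskB| of the ≥ q masks, integrated by the
  trapezoidal rule (step 0.01; halving the step moves smooth-surface
  indices by < 0.01).  The union denominator is the only reading under
  which identical surfaces score 1 and disjoint ones 0; an
  all-valid-cells denominator is available behind a flag.  Similarity
  thresholding uses ≥ (so s(0) = 1 for any pair) while region
  extraction uses strict >; the inconsistency is deliberate and
  confined to these two definitions.
* Paired comparisons: two-sided paired t-tests on per-sample accuracy
  and precision differences (df = n − 1).  An all-zero difference
  vector is 0/0; it is reported as statistic 0, p = 1 with a
  degenerate flag rather than NaN.

## Cross-validation

Each repeat partitions the training set into k balanced folds by
random permutation (fold sizes differ by at most 1).  The calibration
*and its variance surface* are refit per fold, so no full-data
residual variance leaks into held-out assignment.  A partition object
can be shared across models so comparisons see identical folds.
Coverage is the percentage of tests whose true origin falls in the
region; mean precision is the mean precision area.

## Synthetic data generator

The generator emulates the structure of a national tissue-isoscape
study without any real geography: a smooth base δ²H field (linear
latitude trend + synthetic elevation effect + Gaussian-smoothed noise,
affinely mapped onto −110…−50 ‰) over an abstract 10°×12° box at 0.2°
resolution; a smooth strictly positive base prediction-variance field
(default 0.5–5 ‰²); covariate fields (altitude, wind speed, min/max
temperature, sea-level pressure, latitude) each correlated with the
base field so stepwise MLR is exercisable; 120 training sites uniform
over valid cells plus 10 test sites stratified one-per-block over a
4×3 partition of the extent (a stand-in for administrative regions);
and tissue values `−30.87 + 1.31·(5-km buffer mean) + N(0, 4²)`.
A `skewed_region` option offsets the westernmost quarter of the base
field by +15 ‰ to emulate a regionally biased base model; calibrating
against the biased field produces Moran's-I-significant residuals
while the unbiased field does not.

All randomness flows from one config seed via `SeedSequence` spawn
keys, one stream per generation stage, so identical configs are
bit-identical and stages are independently reproducible.

What it does **not** emulate: real climate covariance structure,
coastline/nodata geometry, anisotropy, measurement error distinct from
calibration residual, or temporal integration of the isotope signal.
Passing tests therefore demonstrate the correctness and statistical
calibration of the machinery, not the field performance of any real
isoscape.

Problem sizes used in the test and acceptance runs — the default
60×50-cell grid, n = 120 + 10, 10×10-fold CV (1200 tests), 100
replicates for parameter recovery, 50 null replicates with 199
permutations for the Moran's I calibration — mirror the study design
the defaults encode while keeping a full run in seconds.

## Known limitations

* ESRI ASCII requires square cells (use GeoTIFF otherwise); GeoTIFF
  I/O writes the minimal georeferencing tag set (pixel scale,
  tiepoint, nodata), not a full CRS description.
* Buffer extraction loops over sites in Python; for very large site
  sets precompute `extract_buffer_means` once and pass
  `predictor_values` into fold refits (the CV code already does).
* The covariance component (iv) is user-supplied, not estimated; with
  the default none, total variance is conservative whenever the true
  covariance is negative and optimistic when positive.
* Uniform priors only in the pipeline; informative spatial priors are
  supported by `posterior_surface` but not surfaced in the CLI.
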