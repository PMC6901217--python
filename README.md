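# isoassign

Isoscape calibration, variance propagation and Bayesian geographic
assignment for stable-isotope provenance studies.

Where did a plant, animal or food sample come from?  Hydrogen isotope
ratios (δ²H, ‰ vs VSMOW) in precipitation vary systematically across a
landscape, and tissues grown from that water inherit the signal.  Given
a raster model of precipitation δ²H (a *base isoscape*) and a set of
reference tissue samples of known origin, `isoassign` builds a tissue
isoscape, propagates every variance source into a per-cell uncertainty
surface, and turns a measured δ²H value from an unknown sample into a
posterior probability-of-origin map.  It is aimed at isotope
ecologists and forensic/food-authenticity analysts who want the whole
workflow — calibration, assignment, cross-validated evaluation and
model comparison — as a reproducible library rather than a script pile.

## The model

**Calibration.**  For each reference site the base isoscape is averaged
over grid cells within a 5 km radius, and measured tissue δ²H is
regressed on that mean by OLS:

    δ²H_tissue = a + b·δ²H_base + ε,   ε ~ N(0, s²).

Alternatively a tissue isoscape is fitted directly on environmental
covariate rasters by multiple linear regression with backward stepwise
elimination on the Gaussian AIC, `n·log(SSE/n) + 2k`.

**Variance propagation.**  The total variance at cell *i* combines
(i) the base-isoscape prediction variance passed through the slope,
(ii) the calibration residual variance, (iii) the prediction variance
of the calibration line, and (iv) an optional covariance term:

    σ_i² = b̂²·σ²_base,i + s² + s²(1/n + (x̂_i − x̄)²/Sxx) + 2·b̂·cov_i.

A direct-MLR isoscape needs only `s² + x_iᵀ Σ_β x_i`.

**Assignment.**  For a sample with measured value δ_s, Bayes' rule with
a Gaussian likelihood gives the posterior probability of origin at
each cell:

    P(A_i | δ_s) ∝ P(A_i) · (2πσ_i²)^(−1/2) · exp(−(δ_s − δ̂_i)²/(2σ_i²)),

normalised to sum to 1 and rescaled by its maximum onto [0, 1].  Cells
with rescaled probability above the 2:1-odds threshold 2/3 ≈ 0.667 form
the assignment region.  Densities are computed in log space so 40σ
outliers do not underflow.

**Evaluation.**  Repeated k-fold cross-validation (default 10×10 on
n = 120, i.e. 1200 individual tests) refits the model and its variance
surfaces per fold and reports *coverage* (% of true origins inside the
region) and *mean precision area*.  Two models are compared per sample
by the change in probability at the true origin, the change in
precision area (10³ km²), and a threshold-integrated Jaccard similarity
index, with two-sided paired t-tests.

## Worked example

A fully synthetic study (60×50-cell abstract base isoscape spanning
−110 to −50 ‰, 120 training + 10 stratified test sites, tissue values
generated with intercept −30.87 ‰, slope 1.31, residual s.d. 4.0 ‰):

```python
import numpy as np
from isoassign import (SyntheticConfig, simulate_study, fit_simple_calibration,
                       predict_surface, total_variance_surface, posterior_surface,
                       assignment_region, repeated_kfold_assign, summarize_cv)

study = simulate_study(SyntheticConfig(seed=1))
model = fit_simple_calibration(study.train, study.isoscape)
comps = total_variance_surface(model, base=study.isoscape,
                               base_pred_var=study.base_variance)
predicted = predict_surface(model, base=study.isoscape)

site = study.test.first_site()
post = posterior_surface(study.test.d2H[0], predicted, comps.total, sample_id=site.id)
region = assignment_region(post, true_site=site)

records = repeated_kfold_assign(study.train, base=study.isoscape,
                                base_pred_var=study.base_variance,
                                k=10, repeats=10, seed=1)
summary = summarize_cv(records)
```

prints, with the formatting shown in the docstrings:

```
calibration: intercept -32.07 ‰, slope 1.297, RSE 3.85 ‰ (118 d.f.), r² 0.95
total variance: 15.9–23.6 ‰² (s.d. 3.99–4.85 ‰)
sample test_120: P(origin)=0.92 at the true site, region 146.1 ×10³ km², contains truth: True
CV: 1200 tests, coverage 64%, mean precision 121,106 km²
```

The refitted intercept/slope recover the generating calibration within
sampling noise; the held-out sample's true origin carries 92% of the
maximum rescaled probability and falls inside its 2:1-odds region; and
across 1200 cross-validated tests roughly two thirds of true origins
land inside their assignment regions.

The same pipeline runs from the shell:

```sh
isoassign run --seed 1 --out run1/        # simulate → calibrate → validate → compare
isoassign simulate --seed 1 --out data/   # just the synthetic rasters + samples
isoassign calibrate --base data/base_isoscape.asc --samples data/samples.csv --out model.json
```

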