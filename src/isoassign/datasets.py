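"""Published reference values from a New Zealand blackberry-leaf
δ²H provenance study.

A national study calibrated two precipitation δ²H isoscapes to 120
blackberry (*Rubus sp.*) leaf samples (models 1 and 2, simple linear
calibrations against a long-term and a short-term precipitation model
respectively) and fitted a third model directly on environmental
covariates (model 3).  Ten held-out samples were assigned with each
model and the models compared pairwise.  The per-sample numbers
published for that external test set are reproduced here as package
data: they exercise the comparison arithmetic in this package without
requiring the (national-scale) rasters that produced them.

All δ²H values are ‰ vs VSMOW; precision differences are in 10³ km².
"""

from __future__ import annotations

import pandas as pd

#: Measured and model-predicted δ²H for the ten external test samples,
#: with the rescaled assignment probability at each sample's true origin.
_TEST_ASSIGNMENTS = {
    "sample": list(range(1, 11)),
    "d2H_measured": [-67.8, -70.1, -65.7, -66.3, -70.8, -86.1, -89.8, -75.0, -95.2, -95.9],
    "d2H_predicted_model1": [-76.3, -75.6, -72.8, -77.7, -75.9, -88.9, -92.9, -74.2, -93.0, -89.6],
    "prob_model1": [0.63, 0.82, 0.72, 0.42, 0.84, 0.95, 0.93, 0.99, 0.97, 0.76],
    "d2H_predicted_model2": [-68.7, -71.4, -66.6, -68.7, -68.5, -82.8, -89.8, -80.2, -94.2, -99.0],
    "prob_model2": [0.97, 0.95, 0.99, 0.77, 0.88, 0.72, 0.99, 0.56, 0.98, 0.84],
    "d2H_predicted_model3": [-69.1, -70.0, -64.4, -69.9, -70.8, -84.1, -88.9, -80.1, -94.5, -97.3],
    "prob_model3": [0.94, 0.99, 0.94, 0.63, 0.99, 0.86, 0.97, 0.39, 0.98, 0.93],
}

#: Pairwise per-sample differences for the external test set: accuracy
#: (change in rescaled probability at the true origin) and precision
#: (change in precision area, 10³ km²), for each ordered model pair.
_PAIRWISE_DIFFERENCES = {
    "sample": list(range(1, 11)),
    "accuracy_m1_m2": [-0.35, -0.13, -0.27, -0.35, -0.05, 0.22, -0.06, 0.43, -0.01, -0.08],
    "precision_m1_m2": [26.39, 17.48, 7.83, 26.67, 15.35, 24.41, 55.28, -25.42, 22.22, 56.26],
    "accuracy_m1_m3": [-0.31, -0.18, 0.22, -0.21, -0.16, 0.09, -0.03, 0.60, -0.01, -0.17],
    "precision_m1_m3": [24.47, 26.06, -21.37, 30.09, 21.97, 35.90, 55.01, -44.18, 28.02, 70.05],
    "accuracy_m2_m3": [0.03, -0.05, 0.05, 0.14, -0.11, -0.14, 0.03, 0.17, 0.00, -0.09],
    "precision_m2_m3": [-1.92, 8.58, -29.20, 3.42, 6.62, 11.48, -0.27, -18.77, 5.80, 13.79],
}

#: Threshold-integrated similarity indices between assignment surfaces
#: for the ten external test samples, per model pair.
_SIMILARITY_INDICES = {
    "sample": list(range(1, 11)),
    "similarity_m1_m2": [0.46, 0.46, 0.40, 0.42, 0.45, 0.34, 0.39, 0.42, 0.53, 0.53],
    "similarity_m1_m3": [0.43, 0.42, 0.39, 0.40, 0.42, 0.34, 0.38, 0.41, 0.48, 0.49],
    "similarity_m2_m3": [0.84, 0.82, 0.86, 0.86, 0.82, 0.83, 0.83, 0.85, 0.86, 0.85],
}

#: Residual variances (‰²) of the three published calibrations.
PUBLISHED_RESIDUAL_VARIANCE = {"model1": 73.9, "model2": 14.38, "model3": 13.5}

#: Published repeated-k-fold summaries (coverage %, mean precision km²).
PUBLISHED_CV_SUMMARY = {
    "model1": {"coverage_pct": 63.0, "mean_precision_km2": 74351.0},
    "model2": {"coverage_pct": 68.0, "mean_precision_km2": 31002.0},
    "model3": {"coverage_pct": 68.0, "mean_precision_km2": 29233.0},
}


def blackberry_test_assignments() -> pd.DataFrame:
    """Measured/predicted δ²H and true-origin probabilities, external test set."""
    return pd.DataFrame(_TEST_ASSIGNMENTS)


def blackberry_pairwise_differences() -> pd.DataFrame:
    """Per-sample pairwise accuracy/precision differences (precision 10³ km²)."""
    return pd.DataFrame(_PAIRWISE_DIFFERENCES)


def blackberry_similarity_indices() -> pd.DataFrame:
    """Per-sample similarity indices for each model pair."""
    return pd.DataFrame(_SIMILARITY_INDICES)
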