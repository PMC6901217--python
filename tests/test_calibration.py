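"""Calibration fits, stepwise selection, prediction surfaces, Moran's I."""

import numpy as np
import pandas as pd
import pytest

from isoassign import (
    SampleSet,
    SyntheticConfig,
    diagnose_residuals,
    fit_mlr_stepwise,
    fit_simple_calibration,
    gaussian_aic,
    predict_surface,
    simulate_study,
)
from isoassign.calibration import (
    CalibrationModel,
    inverse_distance_weights,
    morans_i,
    morans_i_permutation_test,
)
from isoassign.exceptions import ConfigError, SingularFitError, WeightsError


def toy_samples(xs, ys, lons=None, lats=None, **covs):
    n = len(xs)
    frame = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "lon": lons if lons is not None else np.linspace(0, 1, n),
            "lat": lats if lats is not None else np.linspace(0, 1, n),
            "d2H": ys,
        }
    )
    for name, vals in covs.items():
        frame[name] = vals
    return frame, np.asarray(xs, dtype=float)


def fit_toy(xs, ys):
    frame, x = toy_samples(xs, ys)
    # bypass the raster extraction with precomputed predictor values
    return fit_simple_calibration(SampleSet(frame), base=None, predictor_values=x)


def test_toy_ols_closed_form():
    """(0,1),(1,3),(2,5) lie on y = 1 + 2x exactly."""
    m = fit_toy([0, 1, 2], [1, 3, 5])
    assert m.intercept == pytest.approx(1.0)
    assert m.slope == pytest.approx(2.0)
    assert m.resid_variance == pytest.approx(0.0, abs=1e-20)
    assert m.r2 == pytest.approx(1.0)
    assert m.predictor_stats == {"xbar": 1.0, "sxx": 2.0}


def test_r2_matches_independent_sums_of_squares(study):
    """r² equals 1 − SSE/SST accumulated independently of the fit path."""
    m = fit_simple_calibration(study.train, study.isoscape)
    y = study.train.d2H
    sse = sst = 0.0
    ybar = sum(y) / len(y)
    for yi, ri in zip(y, m.residuals):
        sse += ri * ri
        sst += (yi - ybar) ** 2
    assert m.r2 == pytest.approx(1 - sse / sst, rel=1e-10)


def test_ols_identities(study):
    """Intercepted OLS: residuals sum to 0; s²·df = SSE exactly."""
    m = fit_simple_calibration(study.train, study.isoscape)
    assert abs(m.residuals.sum()) < 1e-8 * np.abs(study.train.d2H).sum()
    assert m.resid_variance * m.df == pytest.approx((m.residuals**2).sum(), rel=1e-12)
    assert m.df == m.n - 2
    assert m.rse == pytest.approx(np.sqrt(m.resid_variance))


def test_zero_variance_predictor_rejected():
    with pytest.raises(SingularFitError):
        fit_toy([1.0, 1.0, 1.0], [1, 2, 3])


def test_parameter_recovery_over_replicates():
    """Mean fitted slope within 1% of 1.31, mean RSE within 5% of 4.0 ‰,
    over 100 default synthetic replicates."""
    slopes, rses = [], []
    for seed in range(100):
        study = simulate_study(seed=seed)
        m = fit_simple_calibration(study.train, study.isoscape)
        slopes.append(m.slope)
        rses.append(m.rse)
    assert np.mean(slopes) == pytest.approx(1.31, rel=0.01)
    assert np.mean(rses) == pytest.approx(4.0, rel=0.05)


def test_model_json_round_trip(study):
    m = fit_simple_calibration(study.train, study.isoscape)
    back = CalibrationModel.from_json(m.to_json())
    assert back.coefficients == pytest.approx(m.coefficients)
    assert np.allclose(back.coef_covariance, m.coef_covariance)
    assert back.predictor_stats["xbar"] == pytest.approx(m.predictor_stats["xbar"])
    assert back.df == m.df


# ---- stepwise MLR ----------------------------------------------------


def test_stepwise_drops_noise_keeps_generator():
    """With a strong generating covariate and a pure-noise candidate
    (n = 120), the generator is always retained and the noise term is
    eliminated at AIC's theoretical null-drop rate.

    Backward AIC keeps a null covariate whenever dropping it fails to
    lower AIC, i.e. when its squared t exceeds 2 — probability ≈ 0.157
    under the null — so elimination is expected in ≈ 84% of replicates,
    never in all of them.
    """
    kept_signal = dropped_junk = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=120)
        noise = rng.normal(size=120)
        y = 3.0 + 5.0 * x + rng.normal(scale=0.5, size=120)
        frame, _ = toy_samples(np.zeros(120), y,
                               lons=rng.uniform(0, 5, 120), lats=rng.uniform(0, 5, 120),
                               signal=x, junk=noise)
        m = fit_mlr_stepwise(SampleSet(frame), ["signal", "junk"])
        if "signal" in m.coef_names:
            kept_signal += 1
        if "junk" not in m.coef_names:
            dropped_junk += 1
    assert kept_signal == 20
    assert dropped_junk >= 12  # 4σ below the binomial(20, 0.843) mean


def test_stepwise_zero_candidates_gives_mean_model_aic():
    """Intercept-only AIC equals the closed-form Gaussian AIC of the mean."""
    rng = np.random.default_rng(0)
    y = rng.normal(10, 2, size=30)
    frame, _ = toy_samples(np.zeros(30), y)
    m = fit_mlr_stepwise(SampleSet(frame), [])
    sse = ((y - y.mean()) ** 2).sum()
    assert m.aic == pytest.approx(30 * np.log(sse / 30) + 2.0)
    assert m.coef_names == ["intercept"]
    assert m.coefficients["intercept"] == pytest.approx(y.mean())


def test_stepwise_never_increases_aic():
    study = simulate_study(seed=77)
    full_names = ["altitude", "wind_speed", "min_temperature", "max_temperature", "mslp", "latitude"]
    m = fit_mlr_stepwise(study.train, full_names)
    # refit the full model for its AIC
    import statsmodels.api as sm

    X = np.column_stack(
        [np.ones(len(study.train))]
        + [study.train.frame[c].to_numpy(float) for c in full_names]
    )
    res = sm.OLS(study.train.d2H, X).fit()
    full_aic = gaussian_aic(float(res.resid @ res.resid), len(study.train), X.shape[1])
    assert m.aic <= full_aic + 1e-9


def test_collinear_design_rejected_with_names():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    frame, _ = toy_samples(np.zeros(30), rng.normal(size=30), a=x, b=2 * x)
    with pytest.raises(SingularFitError, match="collinear"):
        fit_mlr_stepwise(SampleSet(frame), ["a", "b"])


# ---- prediction surfaces --------------------------------------------


def test_predict_constant_base_is_affine_constant(grid_factory):
    m = fit_toy([0, 1, 2], [1, 3, 5])
    base = grid_factory(np.full((4, 4), -80.0))
    out = predict_surface(m, base=base)
    assert np.allclose(out.values, 1.0 + 2.0 * -80.0)


def test_prediction_consistent_with_fitted_values(study):
    m = fit_simple_calibration(study.train, study.isoscape)
    from isoassign import extract_buffer_means

    x, _ = extract_buffer_means(study.isoscape, study.train, 5.0)
    fitted = study.train.d2H - m.residuals
    assert np.allclose(m.intercept + m.slope * x, fitted)


def test_surface_brackets_training_predictions(study):
    """Affine map: the surface min/max bracket every training fit when the
    grid brackets the training predictor range."""
    m = fit_simple_calibration(study.train, study.isoscape)
    surf = predict_surface(m, base=study.isoscape)
    fitted = study.train.d2H - m.residuals
    assert surf.valid_values().min() <= fitted.min() + 1e-9
    assert surf.valid_values().max() >= fitted.max() - 1e-9


def test_predict_mlr_missing_grid_names_term(study):
    m = fit_mlr_stepwise(study.train, ["altitude", "wind_speed"])
    with pytest.raises(ConfigError, match=m.coef_names[1]):
        predict_surface(m, covariate_grids={})


def test_predict_propagates_nodata(grid_factory):
    m = fit_toy([0, 1, 2], [1, 3, 5])
    mask = np.zeros((3, 3), dtype=bool)
    mask[0, 0] = True
    base = grid_factory(np.full((3, 3), -60.0), mask=mask)
    out = predict_surface(m, base=base)
    assert out.nodata_mask[0, 0]
    assert np.isnan(out.values[0, 0])


# ---- Moran's I -------------------------------------------------------


def test_morans_i_matches_hand_formula_on_4_sites():
    """Brute-force textbook evaluation on a hand-built weight matrix."""
    z = np.array([1.0, -2.0, 3.0, 0.5])
    w = np.array(
        [
            [0.0, 0.5, 0.3, 0.2],
            [0.4, 0.0, 0.4, 0.2],
            [0.1, 0.6, 0.0, 0.3],
            [0.3, 0.3, 0.4, 0.0],
        ]
    )
    zc = z - z.mean()
    num = sum(
        w[i, j] * zc[i] * zc[j] for i in range(4) for j in range(4)
    )
    expected = 4 / w.sum() * num / (zc**2).sum()
    assert morans_i(z, w) == pytest.approx(expected, rel=1e-12)


def test_morans_null_is_calibrated():
    """Random residuals: I ≈ −1/(n−1) and p > 0.05 in ≥ 90% of runs."""
    n = 30
    rng = np.random.default_rng(123)
    lons = rng.uniform(0, 5, n)
    lats = rng.uniform(0, 5, n)
    w = inverse_distance_weights(lons, lats)
    rejections = 0
    i_values = []
    for rep in range(50):
        z = rng.normal(size=n)
        i_obs, p = morans_i_permutation_test(z, w, permutations=199, seed=rep)
        i_values.append(i_obs)
        if p <= 0.05:
            rejections += 1
    assert rejections <= 5  # ≤ 10% false positives
    assert np.mean(i_values) == pytest.approx(-1 / (n - 1), abs=0.05)


def test_morans_detects_gradient():
    """A smooth north–south gradient in the residuals: I > 0, p ≤ 0.01."""
    n = 40
    rng = np.random.default_rng(7)
    lons = rng.uniform(0, 5, n)
    lats = rng.uniform(0, 5, n)
    z = lats - lats.mean()
    w = inverse_distance_weights(lons, lats)
    i_obs, p = morans_i_permutation_test(z, w, permutations=999, seed=0)
    assert i_obs > 0
    assert p <= 0.01


def test_duplicate_coordinates_raise_weights_error():
    lons = np.array([0.0, 0.0, 1.0])
    lats = np.array([0.0, 0.0, 1.0])
    with pytest.raises(WeightsError, match="duplicat"):
        inverse_distance_weights(lons, lats)
    # floored distances allow the computation
    w = inverse_distance_weights(lons, lats, min_distance_km=1.0)
    assert np.allclose(w.sum(axis=1), 1.0)


def test_diagnose_residuals_on_study(study):
    m = fit_simple_calibration(study.train, study.isoscape)
    diag = diagnose_residuals(m, study.train, permutations=199, seed=0)
    assert 0 <= diag.morans_p <= 1
    assert diag.rmse == pytest.approx(np.sqrt(np.mean(m.residuals**2)))
    assert diag.expected_I == pytest.approx(-1 / (len(study.train) - 1))


def test_skewed_base_field_yields_autocorrelated_residuals():
    """Calibrating against a regionally biased base field leaves a spatial
    signature in the residuals; the unbiased field does not."""
    cfg = SyntheticConfig(seed=99)
    biased_cfg = SyntheticConfig(seed=99, skewed_region=True)
    clean = simulate_study(cfg)
    # tissue simulated from the *clean* field, calibrated against the biased one
    from isoassign.synthetic_data import make_base_isoscape

    biased_iso, _, _ = make_base_isoscape(biased_cfg)
    m_clean = fit_simple_calibration(clean.train, clean.isoscape)
    m_biased = fit_simple_calibration(clean.train, biased_iso)
    d_clean = diagnose_residuals(m_clean, clean.train, permutations=199, seed=1)
    d_biased = diagnose_residuals(m_biased, clean.train, permutations=199, seed=1)
    assert d_biased.morans_p <= 0.01
    assert d_biased.morans_I > d_clean.morans_I
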