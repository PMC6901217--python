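"""Posterior probability surfaces, normalisation, rescaling, odds regions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoassign import (
    Grid,
    DEFAULT_ODDS_THRESHOLD,
    Site,
    assignment_region,
    cell_area_km2,
    likelihood_surface,
    posterior_surface,
)
from isoassign.exceptions import AssignmentError, ConfigError, LocationError


def test_likelihood_at_mode_is_standard_normal_peak(grid_factory):
    """δ̂ = δ_s, σ² = 1: density is 1/√(2π) ≈ 0.39894."""
    pred = grid_factory(np.full((2, 2), -70.0))
    var = grid_factory(np.ones((2, 2)), role="variance")
    lik = likelihood_surface(-70.0, pred, var)
    assert np.allclose(lik.values, 1 / np.sqrt(2 * np.pi))
    assert lik.values[0, 0] == pytest.approx(0.39894, abs=1e-5)


def test_likelihood_symmetry(grid_factory):
    pred = grid_factory(np.array([[-75.0, -65.0]]))
    var = grid_factory(np.full((1, 2), 4.0), role="variance")
    lik = likelihood_surface(-70.0, pred, var)  # both cells 5 ‰ away
    assert lik.values[0, 0] == pytest.approx(lik.values[0, 1], rel=1e-14)


def test_likelihood_matches_independent_pdf_oracle(grid_factory):
    """Every cell of a 5×5 surface equals scipy's normal pdf to 1e-12."""
    from scipy.stats import norm

    rng = np.random.default_rng(0)
    pred = grid_factory(rng.normal(-80, 10, (5, 5)))
    var = grid_factory(rng.uniform(5, 25, (5, 5)), role="variance")
    delta_s = -77.3
    lik = likelihood_surface(delta_s, pred, var)
    oracle = norm.pdf(delta_s, loc=pred.values, scale=np.sqrt(var.values))
    assert np.abs(lik.values - oracle).max() < 1e-12


def test_nonpositive_variance_rejected(grid_factory):
    pred = grid_factory(np.zeros((2, 2)))
    var = grid_factory(np.zeros((2, 2)), role="variance")
    with pytest.raises(AssignmentError, match="positive"):
        likelihood_surface(0.0, pred, var)


# ---- posterior -------------------------------------------------------


def test_flat_posterior_on_constant_surface(grid_factory):
    """Uniform prior + constant prediction: every valid cell gets 1/N,
    rescaled all 1."""
    mask = np.zeros((4, 5), dtype=bool)
    mask[0, :2] = True
    pred = grid_factory(np.full((4, 5), -70.0), mask=mask)
    var = grid_factory(np.full((4, 5), 16.0), mask=mask, role="variance")
    post = posterior_surface(-65.0, pred, var)
    n_valid = (~mask).sum()
    assert np.allclose(post.normalized.values[~mask], 1.0 / n_valid)
    assert np.allclose(post.rescaled.values[~mask], 1.0)
    assert np.nansum(post.normalized.values) == pytest.approx(1.0, abs=1e-9)


def test_zero_prior_annihilates(grid_factory):
    pred = grid_factory(np.zeros((2, 4)))
    var = grid_factory(np.ones((2, 4)), role="variance")
    prior_vals = np.ones((2, 4))
    prior_vals[:, :2] = 0.0
    prior = grid_factory(prior_vals, role="probability")
    post = posterior_surface(0.0, pred, var, prior=prior)
    assert np.allclose(post.normalized.values[:, :2], 0.0)
    assert np.nansum(post.normalized.values) == pytest.approx(1.0, abs=1e-12)


def test_posterior_invariant_to_prior_scaling(grid_factory):
    rng = np.random.default_rng(1)
    pred = grid_factory(rng.normal(-80, 10, (4, 4)))
    var = grid_factory(rng.uniform(10, 20, (4, 4)), role="variance")
    prior = grid_factory(rng.uniform(0.1, 1.0, (4, 4)), role="probability")
    scaled = grid_factory(prior.values * 137.0, role="probability")
    a = posterior_surface(-75.0, pred, var, prior=prior)
    b = posterior_surface(-75.0, pred, var, prior=scaled)
    assert np.allclose(a.normalized.values, b.normalized.values)
    assert np.allclose(a.rescaled.values, b.rescaled.values)


def test_extreme_tail_underflow_survives_log_space(grid_factory):
    """δ_s 40σ below every prediction: the raw Gaussian underflows to 0
    but the log-space posterior still sums to 1."""
    rng = np.random.default_rng(2)
    pred = grid_factory(rng.normal(-70, 2, (6, 6)))
    var = grid_factory(np.full((6, 6), 16.0), role="variance")
    delta_s = float(pred.values.min() - 40 * 4.0)
    assert likelihood_surface(delta_s, pred, var).values.max() == 0.0  # raw density underflows
    post = posterior_surface(delta_s, pred, var)
    assert np.nansum(post.normalized.values) == pytest.approx(1.0, abs=1e-9)
    assert np.nanmax(post.rescaled.values) == 1.0
    # ordering preserved: cell with the lowest prediction is most probable
    i, j = np.unravel_index(np.argmin(pred.values), pred.values.shape)
    assert post.rescaled.values[i, j] == 1.0


def test_underflow_posterior_matches_high_precision_oracle(grid_factory):
    """Log-space normalisation agrees with an mpmath-free high-precision
    oracle built from shifted exponentials."""
    rng = np.random.default_rng(3)
    pred = grid_factory(rng.normal(-70, 2, (5, 5)))
    var = grid_factory(rng.uniform(10, 20, (5, 5)), role="variance")
    delta_s = -250.0  # far tail
    post = posterior_surface(delta_s, pred, var)
    # oracle: exact log densities, shifted by their max before exponentiation
    logd = -0.5 * np.log(2 * np.pi * var.values) - (delta_s - pred.values) ** 2 / (
        2 * var.values
    )
    shifted = np.exp(logd - logd.max())
    oracle = shifted / shifted.sum()
    assert np.allclose(post.normalized.values, oracle, rtol=1e-12)


def test_rescaled_preserves_ordering(grid_factory):
    rng = np.random.default_rng(4)
    pred = grid_factory(rng.normal(-80, 8, (6, 6)))
    var = grid_factory(rng.uniform(10, 20, (6, 6)), role="variance")
    post = posterior_surface(-78.0, pred, var)
    order_n = np.argsort(post.normalized.values.ravel())
    order_r = np.argsort(post.rescaled.values.ravel())
    assert np.array_equal(order_n, order_r)


# ---- assignment regions ---------------------------------------------


def test_odds_threshold_value():
    """2:1 odds → 2/(2+1) = 0.667 at 3 d.p."""
    assert round(DEFAULT_ODDS_THRESHOLD, 3) == 0.667


def unimodal_posterior(grid_factory, seed=5, shape=(20, 24)):
    rng = np.random.default_rng(seed)
    pred_vals = np.add.outer(
        np.linspace(-95, -65, shape[0]), np.linspace(-5, 5, shape[1])
    )
    pred = grid_factory(pred_vals, origin=(0.0, float(shape[0])), cell=1.0)
    var = grid_factory(np.full(shape, 16.0), origin=(0.0, float(shape[0])), cell=1.0, role="variance")
    return posterior_surface(-80.0, pred, var)


def test_threshold_zero_selects_all_valid(grid_factory):
    post = unimodal_posterior(grid_factory)
    region = assignment_region(post, threshold=0.0)
    # strict > 0 excludes only cells that underflow to exactly 0
    areas = cell_area_km2(post.rescaled).values
    positive = post.rescaled.values > 0
    assert region.area_km2 == pytest.approx(areas[positive].sum())
    assert region.mask.sum() == positive.sum()


def test_region_area_non_increasing_in_threshold(grid_factory):
    post = unimodal_posterior(grid_factory)
    areas = [
        assignment_region(post, threshold=t).area_km2
        for t in (0.0, 0.2, 0.4, 0.667, 0.8, 0.95)
    ]
    assert all(a >= b for a, b in zip(areas, areas[1:]))
    assert areas[-1] > 0  # the mode always survives


def test_region_matches_brute_force_enumeration(grid_factory):
    post = unimodal_posterior(grid_factory)
    region = assignment_region(post, threshold=0.667)
    areas = cell_area_km2(post.rescaled).values
    brute = 0.0
    count = 0
    for i in range(post.rescaled.nrows):
        for j in range(post.rescaled.ncols):
            if post.rescaled.valid[i, j] and post.rescaled.values[i, j] > 0.667:
                brute += areas[i, j]
                count += 1
    assert region.area_km2 == pytest.approx(brute, rel=1e-12)
    assert region.mask.sum() == count


def test_region_grows_with_inflated_variance(grid_factory):
    """Uniformly inflating the total variance never shrinks the region."""
    shape = (20, 24)
    pred_vals = np.add.outer(np.linspace(-95, -65, shape[0]), np.linspace(-5, 5, shape[1]))
    pred = grid_factory(pred_vals, origin=(0.0, 20.0), cell=1.0)
    areas = []
    for scale in (1.0, 2.0, 4.0):
        var = grid_factory(np.full(shape, 16.0 * scale), origin=(0.0, 20.0), cell=1.0, role="variance")
        post = posterior_surface(-80.0, pred, var)
        areas.append(assignment_region(post).area_km2)
    assert areas[0] <= areas[1] <= areas[2]


@settings(max_examples=40, derandomize=True)
@given(
    delta_s=st.floats(min_value=-400.0, max_value=100.0),
    var_scale=st.floats(min_value=0.1, max_value=100.0),
)
def test_posterior_normalisation_property(delta_s, var_scale):
    """For any measured value and variance scale, the posterior sums to
    1 over valid cells and the rescaled maximum is exactly 1."""
    rng = np.random.default_rng(99)
    pred = Grid(rng.normal(-80, 10, (6, 7)), origin=(0.0, 6.0), cell_size=(1.0, 1.0))
    var = Grid(
        var_scale * rng.uniform(5, 25, (6, 7)),
        origin=(0.0, 6.0),
        cell_size=(1.0, 1.0),
        role="variance",
    )
    post = posterior_surface(delta_s, pred, var)
    assert np.nansum(post.normalized.values) == pytest.approx(1.0, abs=1e-9)
    assert np.nanmax(post.rescaled.values) == 1.0
    assert (post.rescaled.values[post.rescaled.valid] >= 0).all()


def test_true_site_evaluation_and_errors(grid_factory):
    post = unimodal_posterior(grid_factory)
    # the cell with the maximum is inside the region at any threshold < 1
    i, j = np.unravel_index(np.nanargmax(post.rescaled.values), post.rescaled.shape)
    lon = post.rescaled.lon_centers()[j]
    lat = post.rescaled.lat_centers()[i]
    region = assignment_region(post, true_site=Site("t", lon, lat))
    assert region.contains_true_origin
    assert region.prob_at_true_origin == pytest.approx(1.0)
    with pytest.raises(LocationError):
        assignment_region(post, true_site=Site("o", 170.0, 80.0))
    with pytest.raises(ConfigError):
        assignment_region(post, threshold=1.5)
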