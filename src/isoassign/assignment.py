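"""Bayesian probability-of-origin surfaces and odds-threshold regions.

For an unknown sample with measured value δ_s, each grid cell *i* gets
a Gaussian likelihood

    P(δ_s | A_i) = (2π σ_i²)^(−1/2) · exp(−(δ_s − δ̂_i)² / (2 σ_i²)),

with δ̂_i the predicted tissue value and σ_i² the total variance at the
cell.  Bayes' rule with a (default uniform) prior gives the posterior
P(A_i | δ_s), normalised to sum to 1 over valid cells and then rescaled
by its maximum onto [0, 1] for thresholding.  All densities are
computed in log space and normalised by log-sum-exp: the raw Gaussian
underflows once |δ_s − δ̂_i|/σ exceeds ≈ 40, which real outliers reach.

The assignment region is the set of cells with rescaled probability
strictly above a 2:1-odds threshold, 2/(2+1) ≈ 0.667 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import AssignmentError, ConfigError
from .grids import Grid, Site, cell_area_km2, require_coregistered

#: rescaled-probability cutoff from 2:1 posterior odds
DEFAULT_ODDS_THRESHOLD = 2.0 / 3.0

LOG_TWO_PI = np.log(2.0 * np.pi)


@dataclass
class PosteriorSurface:
    """Likelihood, normalised posterior and max-rescaled surfaces for one sample."""

    sample_id: str
    delta_s: float
    likelihood: Grid
    normalized: Grid
    rescaled: Grid
    log_posterior: Grid
    prior: Grid | None = None  # None means uniform

    def rescaled_at(self, site: Site) -> float:
        return self.rescaled.value_at(site.lon, site.lat)


@dataclass
class AssignmentRegion:
    """Cells whose rescaled probability exceeds the odds threshold."""

    mask: np.ndarray
    area_km2: float
    threshold: float
    contains_true_origin: bool | None = None
    prob_at_true_origin: float | None = None


def likelihood_surface(delta_s: float, predicted: Grid, total_var: Grid) -> Grid:
    """Per-cell Gaussian density of δ_s given each cell's prediction."""
    require_coregistered(predicted, total_var)
    return predicted.with_values(
        np.exp(_log_likelihood(delta_s, predicted, total_var)), role="probability"
    )


def _log_likelihood(delta_s: float, predicted: Grid, total_var: Grid) -> np.ndarray:
    var = total_var.values
    valid = predicted.valid & total_var.valid
    if np.any(var[valid] <= 0):
        raise AssignmentError("total variance must be strictly positive on valid cells")
    with np.errstate(invalid="ignore", divide="ignore"):
        ll = -0.5 * (LOG_TWO_PI + np.log(var)) - (delta_s - predicted.values) ** 2 / (2 * var)
    ll[~valid] = -np.inf
    return ll


def posterior_surface(
    delta_s: float,
    predicted: Grid,
    total_var: Grid,
    prior: Grid | None = None,
    sample_id: str = "",
    rescale_mode: str = "max",
) -> PosteriorSurface:
    """Posterior probability-of-origin surface via Bayes' rule.

    ``prior=None`` means uniform over valid cells.  ``rescale_mode``
    is ``"max"`` (divide the normalised surface by its maximum, the
    default) or ``"minmax"``.
    """
    require_coregistered(predicted, total_var)
    log_lik = _log_likelihood(delta_s, predicted, total_var)
    valid = np.isfinite(log_lik)
    if prior is not None:
        require_coregistered(predicted, prior)
        pvals = prior.values
        if np.any(pvals[prior.valid & valid] < 0):
            raise AssignmentError("prior must be non-negative")
        with np.errstate(divide="ignore", invalid="ignore"):
            log_prior = np.where(valid & (pvals > 0), np.log(pvals), -np.inf)
        if not np.isfinite(log_prior).any():
            raise AssignmentError("prior is zero on all valid cells")
        log_post = log_lik + log_prior
    else:
        log_post = log_lik

    finite = np.isfinite(log_post)
    if not finite.any():
        raise AssignmentError("degenerate posterior: no cell has positive probability")
    log_norm = logsumexp(log_post[finite])
    log_post_n = log_post - log_norm
    normalized = np.where(np.isfinite(log_post_n), np.exp(log_post_n), 0.0)
    normalized[~valid] = np.nan

    log_max = np.max(log_post_n[finite])
    if rescale_mode == "max":
        rescaled = np.where(np.isfinite(log_post_n), np.exp(log_post_n - log_max), 0.0)
    elif rescale_mode == "minmax":
        vals = np.where(np.isfinite(log_post_n), np.exp(log_post_n), 0.0)
        lo, hi = vals[finite].min(), vals[finite].max()
        rescaled = (vals - lo) / (hi - lo) if hi > lo else np.ones_like(vals)
    else:
        raise ConfigError(f"unknown rescale_mode {rescale_mode!r}")
    rescaled[~valid] = np.nan

    lik_grid = predicted.with_values(np.exp(log_lik), role="probability")
    lik_grid.nodata_mask |= ~valid
    post = predicted.with_values(normalized, role="probability")
    post.nodata_mask |= ~valid
    resc = predicted.with_values(rescaled, role="probability")
    resc.nodata_mask |= ~valid
    logp = predicted.with_values(log_post_n, role="probability")
    logp.role = "isoscape"  # log scale, not a probability in [0,1]
    return PosteriorSurface(
        sample_id=sample_id,
        delta_s=delta_s,
        likelihood=lik_grid,
        normalized=post,
        rescaled=resc,
        log_posterior=logp,
        prior=prior,
    )


def assignment_region(
    post: PosteriorSurface,
    threshold: float = DEFAULT_ODDS_THRESHOLD,
    true_site: Site | None = None,
) -> AssignmentRegion:
    """Extract the likely-origin region: rescaled probability > threshold
    (strict), with its spherical area; optionally evaluate a known true
    origin against the region."""
    if not 0.0 <= threshold < 1.0:
        raise ConfigError(f"threshold must be in [0, 1), got {threshold}")
    resc = post.rescaled
    mask = np.zeros(resc.shape, dtype=bool)
    mask[resc.valid] = resc.values[resc.valid] > threshold
    areas = cell_area_km2(resc).values
    area = float(areas[mask].sum())
    contains = None
    prob = None
    if true_site is not None:
        row, col = resc.index_of(true_site.lon, true_site.lat)
        contains = bool(mask[row, col])
        prob = float(resc.values[row, col])
    return AssignmentRegion(
        mask=mask,
        area_km2=area,
        threshold=threshold,
        contains_true_origin=contains,
        prob_at_true_origin=prob,
    )
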