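"""Total-variance surfaces for probabilistic assignment.

For a tissue isoscape built by calibrating a base isoscape, the total
variance on the predicted tissue value at cell *i* combines four
components:

(i)   the base-isoscape prediction variance, spatially varying, passed
      through the calibration slope (``b̂²·σ²_base,i``);
(ii)  the residual variance of the calibration, ``s²``, constant;
(iii) the prediction variance of the calibration line at the cell's
      base value, ``s²·(1/n + (x̂ − x̄)²/Sxx)``, which shrinks with the
      size of the calibration dataset;
(iv)  an optional covariance between the two prediction errors,
      entering as ``2·b̂·cov_i`` (no closed form is assumed; a per-cell
      covariance grid is supplied by the caller, default none).

For a direct multiple-regression isoscape there is no base-model step,
so the total reduces to ``s² + x_iᵀ Σ_β x_i`` (components (i)/(iv)
absent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationModel, fit_simple_calibration
from .exceptions import ConfigError, PropagationError
from .grids import Grid, SampleSet, extract_buffer_means, haversine_km, require_coregistered


@dataclass
class VarianceComponents:
    """Per-component variance surfaces (‰²) and their total."""

    base_pred_var: Grid | None     # component (i), already slope-scaled if applicable
    resid_var: float               # component (ii), scalar s²
    calib_pred_var: Grid | None    # component (iii)
    covariance_term: Grid | None   # component (iv), the full 2·b̂·cov_i term
    total: Grid

    def sd(self) -> Grid:
        return variance_to_sd(self.total)


def calib_prediction_variance(
    model: CalibrationModel, xhat: float | np.ndarray
) -> float | np.ndarray:
    """Prediction variance of the simple calibration line at x̂:
    ``s²·(1/n + (x̂ − x̄)²/Sxx)``."""
    if model.kind != "simple":
        raise ConfigError("calib_prediction_variance applies to the simple calibration")
    xbar = model.predictor_stats["xbar"]
    sxx = model.predictor_stats["sxx"]
    if sxx == 0:
        raise ConfigError("Sxx = 0: predictor has no variance")
    return model.resid_variance * (1.0 / model.n + (np.asarray(xhat) - xbar) ** 2 / sxx)


def total_variance_surface(
    model: CalibrationModel,
    base: Grid | None = None,
    base_pred_var: Grid | None = None,
    covariance: Grid | None = None,
    covariate_grids: dict[str, Grid] | None = None,
    scale_base_by_slope: bool = True,
) -> VarianceComponents:
    """Build the total-variance surface σ_i² for one fitted model.

    Simple kind: ``total_i = b̂²·σ²_base,i + s² + s²(1/n + (x̂_i−x̄)²/Sxx)
    + 2·b̂·cov_i`` with x̂_i the base value at cell i; the covariance
    term is omitted when ``covariance`` is None, and
    ``scale_base_by_slope=False`` drops the b̂² factor for sensitivity
    checks.

    MLR kind: ``total_i = s² + x_iᵀ Σ_β x_i`` over the supplied
    covariate grids.
    """
    if model.kind == "simple":
        if base is None:
            raise ConfigError("simple-kind total variance needs the base isoscape")
        grids = [base] + [g for g in (base_pred_var, covariance) if g is not None]
        require_coregistered(*grids)
        b = model.slope
        comp_iii_vals = calib_prediction_variance(model, base.values)
        comp_iii = base.with_values(comp_iii_vals, role="variance")
        total_vals = model.resid_variance + comp_iii_vals
        comp_i = None
        if base_pred_var is not None:
            scale = b**2 if scale_base_by_slope else 1.0
            comp_i = base.with_values(scale * base_pred_var.values, role="variance")
            total_vals = total_vals + comp_i.values
        comp_iv = None
        if covariance is not None:
            comp_iv = base.with_values(2.0 * b * covariance.values, role="variance")
            total_vals = total_vals + comp_iv.values
        template = base
    else:
        covariate_grids = covariate_grids or {}
        terms = model.coef_names[1:]
        for name in terms:
            if name not in covariate_grids:
                raise ConfigError(f"missing covariate grid for model term {name!r}")
        if not terms:
            raise ConfigError("mlr total variance needs at least one covariate grid")
        template = covariate_grids[terms[0]]
        require_coregistered(*[covariate_grids[t] for t in terms])
        # x_i' Σ x_i per cell, x_i = (1, covariates at cell i)
        stack = np.stack(
            [np.ones(template.shape)] + [covariate_grids[t].values for t in terms]
        )  # (p, nrows, ncols)
        sigma = np.asarray(model.coef_covariance)
        pred_var = np.einsum("irc,ij,jrc->rc", stack, sigma, stack)
        comp_i = None
        comp_iv = None
        comp_iii = template.with_values(pred_var, role="variance")
        total_vals = model.resid_variance + pred_var
        base = template

    valid = template.valid
    if np.any(np.asarray(total_vals)[valid] <= 0):
        bad = int(np.sum(np.asarray(total_vals)[valid] <= 0))
        raise PropagationError(
            f"{bad} cells have non-positive total variance; "
            f"components: resid_var={model.resid_variance}, "
            f"covariance supplied={covariance is not None}"
        )
    total = template.with_values(total_vals, role="variance")
    return VarianceComponents(
        base_pred_var=comp_i,
        resid_var=model.resid_variance,
        calib_pred_var=comp_iii,
        covariance_term=comp_iv,
        total=total,
    )


def variance_to_sd(v: Grid | float | np.ndarray) -> Grid | float | np.ndarray:
    """Element-wise square root, variance (‰²) to standard deviation (‰)."""
    if isinstance(v, Grid):
        vals = v.values
        if np.any(vals[v.valid] < 0):
            raise ConfigError("negative variance cell")
        out = v.with_values(np.sqrt(np.where(v.valid, vals, np.nan)), role="variance")
        return out
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0):
        raise ConfigError(f"negative variance {v}")
    result = np.sqrt(arr)
    return float(result) if np.isscalar(v) or arr.ndim == 0 else result


def idw_interpolate(
    grid: Grid,
    lons: np.ndarray,
    lats: np.ndarray,
    values: np.ndarray,
    power: float = 2.0,
) -> Grid:
    """Inverse-distance-weighted interpolation of site values onto a grid.

    A cell whose center coincides with a site takes that site's value.
    """
    lon_mesh, lat_mesh = grid.center_mesh()
    flat_lon = lon_mesh.ravel()
    flat_lat = lat_mesh.ravel()
    d = haversine_km(flat_lon[:, None], flat_lat[:, None], lons[None, :], lats[None, :])
    out = np.empty(flat_lon.shape)
    exact = d < 1e-9
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    w[~np.isfinite(w)] = 0.0
    wsum = w.sum(axis=1)
    out = (w @ values) / np.where(wsum > 0, wsum, 1.0)
    if has_exact.any():
        idx = np.argmax(exact, axis=1)
        out[has_exact] = values[idx[has_exact]]
    return grid.with_values(out.reshape(grid.shape), role="variance")


def cv_prediction_variance(
    samples: SampleSet,
    base: Grid,
    k: int = 10,
    repeats: int = 10,
    seed: int | None = None,
    radius_km: float = 5.0,
    power: float = 2.0,
    floor: float = 1e-12,
) -> Grid:
    """Cross-validated prediction-variance surface for the simple calibration.

    Repeated k-fold: each fold's samples are predicted by a calibration
    refit on the remaining folds; each site's mean squared held-out
    prediction error over all repeats is smoothed onto the grid by
    inverse-distance weighting (power 2).  Strictly positive (floored).
    """
    n = len(samples)
    if k > n:
        raise ConfigError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ConfigError("k must be at least 2")
    from .validation import make_fold_partitions  # local import to avoid a cycle

    partitions = make_fold_partitions(n, k, repeats, seed)
    y = samples.d2H
    x, _ = extract_buffer_means(base, samples, radius_km)
    sq_err = np.zeros(n)
    counts = np.zeros(n)
    for folds in partitions:
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            model = fit_simple_calibration(
                samples.subset(train_idx), base, radius_km,
                predictor_values=x[train_idx],
            )
            pred = model.intercept + model.slope * x[test_idx]
            sq_err[test_idx] += (y[test_idx] - pred) ** 2
            counts[test_idx] += 1
    site_mse = sq_err / counts
    surface = idw_interpolate(base, samples.lons, samples.lats, site_mse, power)
    surface.values[:] = np.maximum(surface.values, floor)
    return surface
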