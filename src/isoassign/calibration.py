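"""Tissue-isoscape model fitting and residual diagnostics.

Two model families are supported:

* **simple** — ordinary least squares of measured tissue δ²H on the
  5-km buffer mean of a base (precipitation) isoscape.  This is the
  classical isoscape calibration; the fitted intercept/slope rescale
  the base raster into a predicted tissue raster.
* **mlr** — multiple linear regression of tissue δ²H directly on
  environmental covariates, with backward stepwise elimination on the
  Gaussian AIC ``n·log(SSE/n) + 2k`` (additive constant dropped).  The
  selection criterion is AIC alone; per-step p-values are logged on the
  model for audit but impose no hard cutoff.

Residual diagnostics use Moran's I with inverse-great-circle-distance
weights, row-standardised, and a two-sided permutation p-value
(residuals permuted across sites).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import ConfigError, SingularFitError, WeightsError
from .grids import Grid, SampleSet, extract_buffer_means, haversine_km

BASE_PREDICTOR = "base_d2H"  # predictor name used by the simple calibration


def gaussian_aic(sse: float, n: int, k: int) -> float:
    """AIC of a Gaussian model up to an additive constant: n·log(SSE/n) + 2k.

    ``k`` counts estimated mean parameters (intercept included)."""
    if sse <= 0:
        # perfect fit: AIC diverges to -inf; return a large negative sentinel
        return -np.inf
    return n * float(np.log(sse / n)) + 2 * k


@dataclass
class CalibrationModel:
    """A fitted tissue-isoscape regression.

    ``coefficients`` maps predictor names (plus ``"intercept"``) to
    estimates; ``coef_covariance`` is ordered like ``coef_names``.
    ``predictor_stats`` stores what prediction variance needs: for the
    simple kind the training mean ``xbar`` and centered sum of squares
    ``sxx`` of the predictor; for the mlr kind the training column
    means.  ``residuals`` are the training residuals in sample order.
    """

    kind: str
    coef_names: list[str]
    coefficients: dict[str, float]
    coef_covariance: np.ndarray
    resid_variance: float
    rse: float
    r2: float
    n: int
    df: int
    predictor_stats: dict[str, float | dict[str, float]]
    aic: float
    residuals: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    coef_table: dict[str, dict[str, float]] = field(default_factory=dict)
    selection_log: list[dict] = field(default_factory=list, repr=False)

    # ----- prediction ----------------------------------------------

    @property
    def intercept(self) -> float:
        return self.coefficients["intercept"]

    @property
    def slope(self) -> float:
        """Slope of the simple calibration."""
        if self.kind != "simple":
            raise ConfigError("slope is only defined for the simple calibration")
        return self.coefficients[BASE_PREDICTOR]

    def design_row(self, predictors: dict[str, float]) -> np.ndarray:
        row = [1.0]
        for name in self.coef_names[1:]:
            if name not in predictors:
                raise ConfigError(f"missing predictor {name!r} for prediction")
            row.append(predictors[name])
        return np.array(row)

    def predict(self, predictors: dict[str, np.ndarray | float]) -> np.ndarray | float:
        out = self.coefficients["intercept"]
        for name in self.coef_names[1:]:
            if name not in predictors:
                raise ConfigError(f"missing predictor {name!r} for prediction")
            out = out + self.coefficients[name] * predictors[name]
        return out

    # ----- serialization -------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "kind": self.kind,
            "coef_names": self.coef_names,
            "coefficients": self.coefficients,
            "coef_covariance": np.asarray(self.coef_covariance).tolist(),
            "resid_variance": self.resid_variance,
            "rse": self.rse,
            "r2": self.r2,
            "n": self.n,
            "df": self.df,
            "predictor_stats": self.predictor_stats,
            "aic": None if np.isinf(self.aic) else self.aic,
            "coef_table": self.coef_table,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationModel":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(s).read_text()
        doc = json.loads(text)
        return cls(
            kind=doc["kind"],
            coef_names=list(doc["coef_names"]),
            coefficients={k: float(v) for k, v in doc["coefficients"].items()},
            coef_covariance=np.asarray(doc["coef_covariance"], dtype=float),
            resid_variance=float(doc["resid_variance"]),
            rse=float(doc["rse"]),
            r2=float(doc["r2"]),
            n=int(doc["n"]),
            df=int(doc["df"]),
            predictor_stats=doc["predictor_stats"],
            aic=float(doc["aic"]) if doc.get("aic") is not None else -np.inf,
            coef_table=doc.get("coef_table", {}),
        )


def _fit_ols(y: np.ndarray, X: np.ndarray, names: list[str], kind: str) -> CalibrationModel:
    """Shared OLS machinery (design X includes the intercept column)."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        # identify offending columns by dropping each in turn
        offending = [
            names[j]
            for j in range(1, p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise SingularFitError(
            f"rank-deficient design; collinear or constant columns: {offending or names}"
        )
    res = sm.OLS(y, X).fit()
    resid = np.asarray(res.resid)
    sse = float(resid @ resid)
    df = n - p
    resid_variance = sse / df if df > 0 else 0.0
    coef = {name: float(b) for name, b in zip(names, res.params)}
    coef_table = {
        name: {
            "estimate": float(res.params[j]),
            "std_error": float(res.bse[j]),
            "t_value": float(res.tvalues[j]),
            "p_value": float(res.pvalues[j]),
        }
        for j, name in enumerate(names)
    }
    if kind == "simple":
        x = X[:, 1]
        stats: dict = {"xbar": float(x.mean()), "sxx": float(((x - x.mean()) ** 2).sum())}
    else:
        stats = {"means": {name: float(X[:, j].mean()) for j, name in enumerate(names)}}
    return CalibrationModel(
        kind=kind,
        coef_names=names,
        coefficients=coef,
        coef_covariance=np.asarray(res.cov_params()),
        resid_variance=resid_variance,
        rse=float(np.sqrt(resid_variance)),
        r2=float(res.rsquared) if p > 1 else 0.0,
        n=n,
        df=df,
        predictor_stats=stats,
        aic=gaussian_aic(sse, n, p),
        residuals=resid,
        coef_table=coef_table,
    )


def fit_simple_calibration(
    samples: SampleSet,
    base: Grid,
    radius_km: float = 5.0,
    predictor_values: np.ndarray | None = None,
) -> CalibrationModel:
    """OLS of measured tissue δ²H on the buffer-mean base δ²H.

    Every site's predictor is the mean of valid base-isoscape cells
    within ``radius_km`` great-circle km of the site.
    ``predictor_values`` short-circuits the buffer extraction with
    precomputed per-site values (useful in cross-validation loops).
    """
    if len(samples) < 3:
        raise ConfigError(f"need at least 3 train sites, got {len(samples)}")
    y = samples.d2H
    if predictor_values is not None:
        x = np.asarray(predictor_values, dtype=float)
        if x.shape != y.shape:
            raise ConfigError("predictor_values must align with the sample set")
    else:
        x, _ = extract_buffer_means(base, samples, radius_km)
    if np.ptp(x) == 0:
        raise SingularFitError("zero variance in the base-isoscape predictor")
    X = np.column_stack([np.ones_like(x), x])
    return _fit_ols(y, X, ["intercept", BASE_PREDICTOR], kind="simple")


def fit_mlr_stepwise(
    samples: SampleSet, candidate_covariates: Sequence[str]
) -> CalibrationModel:
    """Backward stepwise multiple linear regression on AIC.

    Starts from the full model over ``candidate_covariates`` and
    repeatedly removes the single covariate whose removal most lowers
    the Gaussian AIC, stopping when no removal lowers it.  Ties are
    broken by removing the covariate with the largest p-value.
    """
    candidates = list(candidate_covariates)
    n = len(samples)
    if n <= len(candidates) + 1:
        raise ConfigError(
            f"n={n} too small for {len(candidates)} candidate covariates"
        )
    for name in candidates:
        if name not in samples.frame.columns:
            raise ConfigError(f"sample table has no covariate column {name!r}")
    y = samples.d2H

    def fit(names: list[str]) -> CalibrationModel:
        X = np.column_stack(
            [np.ones(n)] + [samples.frame[name].to_numpy(float) for name in names]
        )
        return _fit_ols(y, X, ["intercept"] + names, kind="mlr")

    current = candidates
    model = fit(current)
    log: list[dict] = []
    while current:
        trials = []
        for name in current:
            reduced = [c for c in current if c != name]
            trial = fit(reduced)
            trials.append((trial.aic, model.coef_table[name]["p_value"], name, trial))
        # best removal: lowest AIC; ties broken by largest p-value of the removed term
        best = min(trials, key=lambda t: (t[0], -t[1]))
        log.append(
            {
                "step_aic": model.aic,
                "candidate_removals": {t[2]: {"aic": t[0], "p_removed": t[1]} for t in trials},
            }
        )
        if best[0] < model.aic:
            current = [c for c in current if c != best[2]]
            model = best[3]
        else:
            break
    model.selection_log = log
    return model


def predict_surface(
    model: CalibrationModel,
    base: Grid | None = None,
    covariate_grids: dict[str, Grid] | None = None,
) -> Grid:
    """Per-cell predicted tissue δ²H raster; nodata propagates.

    Simple models take the base isoscape; mlr models take one grid per
    retained covariate (all co-registered).
    """
    if model.kind == "simple":
        if base is None:
            raise ConfigError("simple calibration needs the base isoscape grid")
        values = model.intercept + model.slope * base.values
        out = base.with_values(values, role="isoscape")
    else:
        covariate_grids = covariate_grids or {}
        template = None
        acc = None
        for name in model.coef_names[1:]:
            if name not in covariate_grids:
                raise ConfigError(f"missing covariate grid for model term {name!r}")
            g = covariate_grids[name]
            if template is None:
                template = g
                acc = np.full(g.shape, model.intercept)
            acc = acc + model.coefficients[name] * g.values
        if template is None:  # intercept-only model
            if base is None:
                raise ConfigError("intercept-only prediction needs a template grid")
            template = base
            acc = np.full(base.shape, model.intercept)
        mask = template.nodata_mask.copy()
        for name in model.coef_names[1:]:
            mask |= covariate_grids[name].nodata_mask
        out = Grid(
            values=acc,
            origin=template.origin,
            cell_size=template.cell_size,
            nodata_mask=mask,
            role="isoscape",
        )
    out.values[out.nodata_mask] = np.nan
    return out


# --------------------------------------------------------------------
# residual diagnostics: Moran's I
# --------------------------------------------------------------------


@dataclass
class ResidualDiagnostics:
    residuals: np.ndarray
    morans_I: float
    morans_p: float
    expected_I: float
    rmse: float
    permutations: int


def inverse_distance_weights(
    lons: np.ndarray, lats: np.ndarray, min_distance_km: float | None = None
) -> np.ndarray:
    """Row-standardised inverse great-circle-distance weight matrix.

    Exact duplicate coordinates make the inverse distance infinite;
    that raises :class:`WeightsError` unless ``min_distance_km`` is
    given, in which case all pairwise distances are floored at that
    value (the documented perturbation rule).
    """
    n = len(lons)
    d = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    off_diag = ~np.eye(n, dtype=bool)
    if min_distance_km is not None:
        d = np.maximum(d, min_distance_km)
    if np.any(d[off_diag] == 0):
        raise WeightsError(
            "duplicated site coordinates give infinite inverse-distance weights; "
            "deduplicate sites or pass min_distance_km to floor distances"
        )
    w = np.zeros((n, n))
    w[off_diag] = 1.0 / d[off_diag]
    row_sums = w.sum(axis=1, keepdims=True)
    return w / row_sums


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I statistic for a weight matrix W (any standardisation)."""
    z = values - values.mean()
    s0 = weights.sum()
    denom = float(z @ z)
    if denom == 0:
        return 0.0
    return float(len(values) / s0 * (z @ weights @ z) / denom)


def morans_i_permutation_test(
    values: np.ndarray,
    weights: np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Observed Moran's I and a two-sided permutation p-value.

    Values are permuted across sites; the p-value is
    ``2·min(P(I* ≤ I), P(I* ≥ I))`` with add-one smoothing, capped at 1.
    """
    rng = np.random.default_rng(seed)
    i_obs = morans_i(values, weights)
    perm = np.empty(permutations)
    for b in range(permutations):
        perm[b] = morans_i(rng.permutation(values), weights)
    p_hi = (1 + np.sum(perm >= i_obs)) / (permutations + 1)
    p_lo = (1 + np.sum(perm <= i_obs)) / (permutations + 1)
    return i_obs, min(1.0, 2.0 * min(p_hi, p_lo))


def diagnose_residuals(
    model: CalibrationModel,
    samples: SampleSet,
    permutations: int = 999,
    seed: int | None = None,
    min_distance_km: float | None = None,
) -> ResidualDiagnostics:
    """Spatial autocorrelation test of training residuals.

    Moran's I with inverse-distance weights (great-circle),
    row-standardised; p from ``permutations`` random permutations of
    the residuals across sites, two-sided.
    """
    if len(samples) < 8:
        raise ConfigError(f"need at least 8 sites for diagnostics, got {len(samples)}")
    resid = np.asarray(model.residuals)
    if resid is None or len(resid) != len(samples):
        raise ConfigError("model residuals do not align with the sample set")
    w = inverse_distance_weights(samples.lons, samples.lats, min_distance_km)
    i_obs, p = morans_i_permutation_test(resid, w, permutations, seed)
    return ResidualDiagnostics(
        residuals=resid,
        morans_I=i_obs,
        morans_p=p,
        expected_I=-1.0 / (len(samples) - 1),
        rmse=float(np.sqrt(np.mean(resid**2))),
        permutations=permutations,
    )
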