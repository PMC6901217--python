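"""Synthetic base isoscapes, covariate fields and sample sets.

Emulates the data structure a tissue-isoscape study needs without any
external downloads: a smooth precipitation-like δ²H field over an
abstract 10°×12° box, a strictly positive prediction-variance field,
environmental covariate fields correlated with the base field
(altitude, wind speed, minimum/maximum temperature, mean sea-level
pressure), and site samples whose tissue values follow a linear
calibration with Gaussian residuals.

Default calibration parameters (intercept −30.87 ‰, slope 1.31,
residual s.d. 4.0 ‰, 120 training + 10 stratified test sites) match the
blackberry-leaf calibration against a short-term precipitation isoscape
that this package's validation machinery is designed around.

All randomness flows from the single ``SyntheticConfig.seed``; each
generation stage derives its own child stream, so identical configs
give bit-identical outputs and the stages stay independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, SamplingError
from .grids import Grid, SampleSet, extract_buffer_mean, Site
import pandas as pd

#: names of the synthetic environmental covariate fields
COVARIATE_NAMES = (
    "altitude",
    "wind_speed",
    "min_temperature",
    "max_temperature",
    "mslp",
)

# stage indices for seed fan-out
_STAGE_FIELD = 0
_STAGE_COVARIATES = 1
_STAGE_VARIANCE = 2
_STAGE_SITES = 3
_STAGE_TISSUE = 4


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic study system.

    extent
        (lon_min, lon_max, lat_min, lat_max), decimal degrees.  The
        default is an abstract 10°×12° box; nothing depends on any real
        geography.
    resolution
        Cell size in degrees (square cells).  0.2° on the default
        extent gives a 60×50 grid.
    n_train, n_test
        Training and stratified external-test sample counts.
    calib_intercept, calib_slope, resid_sd
        Linear tissue calibration δ²H_tissue = a + b·δ²H_base + ε,
        ε ~ N(0, resid_sd²); defaults −30.87 ‰, 1.31, 4.0 ‰.
    field_range
        Target (min, max) of the base field in ‰; default −110 to −50.
    smoothness
        Correlation length of the smoothed noise component, degrees.
        ``inf`` suppresses the stochastic component entirely.
    noise_amplitude
        Standard deviation (pre-smoothing, in raw field units) of the
        stochastic component; 0 gives a deterministic plane in
        (latitude, elevation).
    base_var_range
        (min, max) of the smooth base prediction-variance field, ‰².
    skewed_region
        When True, one sub-region (the westernmost quarter) of the base
        field is offset by ``skew_offset`` ‰ *after* range mapping,
        emulating a long-term-biased base isoscape that produces
        spatially autocorrelated calibration residuals.
    test_blocks
        (n_lon, n_lat) regular blocks used to stratify the test split,
        standing in for administrative regions.
    buffer_radius_km
        Radius of the site buffer average used when simulating tissue.
    """

    extent: tuple[float, float, float, float] = (165.0, 175.0, -46.0, -34.0)
    resolution: float = 0.2
    n_train: int = 120
    n_test: int = 10
    calib_intercept: float = -30.87
    calib_slope: float = 1.31
    resid_sd: float = 4.0
    field_range: tuple[float, float] = (-110.0, -50.0)
    smoothness: float = 1.5
    noise_amplitude: float = 1.0
    base_var_range: tuple[float, float] = (0.5, 5.0)
    skewed_region: bool = False
    skew_offset: float = 15.0
    test_blocks: tuple[int, int] = (4, 3)
    buffer_radius_km: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.extent
        if lon_min >= lon_max or lat_min >= lat_max:
            raise ConfigError(f"degenerate extent {self.extent}")
        if self.resolution <= 0:
            raise ConfigError("resolution must be positive")
        if self.n_train < 10:
            raise ConfigError("n_train must be at least 10")
        if self.n_test < 0:
            raise ConfigError("n_test must be non-negative")
        if self.resid_sd < 0:
            raise ConfigError("resid_sd must be non-negative")
        if self.field_range[0] >= self.field_range[1]:
            raise ConfigError(f"field_range must be increasing, got {self.field_range}")

    @property
    def shape(self) -> tuple[int, int]:
        lon_min, lon_max, lat_min, lat_max = self.extent
        nrows = int(round((lat_max - lat_min) / self.resolution))
        ncols = int(round((lon_max - lon_min) / self.resolution))
        return nrows, ncols

    def rng(self, stage: int) -> np.random.Generator:
        """Child RNG for one generation stage, derived from the single seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


def _empty_grid(config: SyntheticConfig, role: str = "isoscape") -> Grid:
    nrows, ncols = config.shape
    lon_min, _, _, lat_max = config.extent
    return Grid(
        values=np.zeros((nrows, ncols)),
        origin=(lon_min, lat_max),
        cell_size=(config.resolution, config.resolution),
        role=role,
    )


def _smooth_noise(
    shape: tuple[int, int], sigma_cells: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise, re-standardised to unit sd."""
    white = rng.standard_normal(shape)
    if sigma_cells <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=sigma_cells, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _range_map(raw: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = raw.max() - raw.min()
    if span == 0:
        return np.full_like(raw, 0.5 * (lo + hi))
    return lo + (raw - raw.min()) * (hi - lo) / span


def make_base_isoscape(config: SyntheticConfig) -> tuple[Grid, Grid, dict[str, Any]]:
    """Generate the base δ²H isoscape, its prediction-variance grid and
    a truth record.

    The base field is a linear trend in latitude plus a synthetic
    elevation effect plus Gaussian-kernel-smoothed noise, affinely
    mapped into ``field_range``.  The truth record stores every
    generating coefficient, the covariate grids and the skew mask (if
    any), so downstream tests can verify recovery.
    """
    template = _empty_grid(config)
    lon, lat = template.center_mesh()
    sigma_cells = (
        0.0 if np.isinf(config.smoothness) else config.smoothness / config.resolution
    )

    rng_field = config.rng(_STAGE_FIELD)
    rng_cov = config.rng(_STAGE_COVARIATES)
    rng_var = config.rng(_STAGE_VARIANCE)

    # synthetic elevation, metres: smooth, non-negative
    elev_raw = _smooth_noise(template.shape, max(sigma_cells, 1.0), rng_cov)
    elevation = _range_map(elev_raw, 0.0, 1500.0)

    lat_min, lat_max = config.extent[2], config.extent[3]
    lat_coef = 2.0   # ‰ per degree latitude (raw scale, poleward depletion)
    elev_coef = -0.015  # ‰ per metre (altitude depletion)
    raw = lat_coef * (lat - lat_min) + elev_coef * elevation
    if config.noise_amplitude > 0 and not np.isinf(config.smoothness):
        raw = raw + config.noise_amplitude * _smooth_noise(
            template.shape, sigma_cells, rng_field
        )
    values = _range_map(raw, *config.field_range)

    skew_mask = np.zeros(template.shape, dtype=bool)
    if config.skewed_region:
        lon_min, lon_max = config.extent[0], config.extent[1]
        skew_mask = lon < lon_min + 0.25 * (lon_max - lon_min)
        values = values + np.where(skew_mask, config.skew_offset, 0.0)

    isoscape = template.with_values(values, role="isoscape")

    var_raw = _smooth_noise(template.shape, max(sigma_cells, 1.0), rng_var)
    variance = template.with_values(
        _range_map(var_raw, *config.base_var_range), role="variance"
    )

    covariates = _make_covariates(config, isoscape, elevation, lat, rng_cov)
    truth = {
        "lat_coef": lat_coef,
        "elev_coef": elev_coef,
        "field_range": config.field_range,
        "calib_intercept": config.calib_intercept,
        "calib_slope": config.calib_slope,
        "resid_sd": config.resid_sd,
        "elevation": elevation,
        "skew_mask": skew_mask,
        "covariate_grids": covariates,
    }
    return isoscape, variance, truth


def _make_covariates(
    config: SyntheticConfig,
    isoscape: Grid,
    elevation: np.ndarray,
    lat: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, Grid]:
    """Smooth covariate fields, each correlated with the base field.

    Each non-geometric covariate is an affine function of the
    standardised base field plus smooth noise, so a multiple regression
    of tissue values on these fields is well posed but not degenerate.
    """
    std = isoscape.values.std()
    z = (isoscape.values - isoscape.values.mean()) / (std if std > 0 else 1.0)
    sigma = config.smoothness / config.resolution
    if not np.isfinite(sigma):
        sigma = float(max(isoscape.shape))  # filter radius capped at the grid size
    sigma = max(sigma, 1.0)

    def noisy(scale_signal: float, loc: float, scale: float) -> np.ndarray:
        n = _smooth_noise(isoscape.shape, sigma, rng)
        return loc + scale * (scale_signal * z + (1 - abs(scale_signal)) * n)

    fields = {
        "altitude": elevation,
        "wind_speed": noisy(0.5, 6.0, 2.0),          # m/s
        "min_temperature": noisy(0.7, 6.0, 3.0),     # °C
        "max_temperature": noisy(0.6, 16.0, 3.0),    # °C
        "mslp": noisy(0.4, 1013.0, 5.0),             # hPa
    }
    grids = {name: isoscape.with_values(vals) for name, vals in fields.items()}
    # latitude is geometric, available directly from the grid
    grids["latitude"] = isoscape.with_values(lat)
    return grids


def sample_sites(isoscape: Grid, config: SyntheticConfig) -> SampleSet:
    """Draw train and stratified test sites on valid cells.

    Sites sit at cell centers, drawn uniformly without replacement.
    Test sites are stratified over a regular block partition of the
    extent (a stand-in for administrative regions): blocks are visited
    in random order and at most one test site is taken per block.
    """
    valid_idx = np.flatnonzero(isoscape.valid.ravel())
    need = config.n_train + config.n_test
    if len(valid_idx) < need:
        raise SamplingError(
            f"requested {need} sites but the grid has only {len(valid_idx)} valid cells"
        )
    rng = config.rng(_STAGE_SITES)
    lon_mesh, lat_mesh = isoscape.center_mesh()

    lon_min, lon_max, lat_min, lat_max = config.extent
    nbx, nby = config.test_blocks
    if config.n_test > nbx * nby:
        raise SamplingError(
            f"n_test={config.n_test} exceeds the {nbx * nby} stratification blocks"
        )

    flat_lon = lon_mesh.ravel()
    flat_lat = lat_mesh.ravel()
    bx = np.minimum(((flat_lon - lon_min) / (lon_max - lon_min) * nbx).astype(int), nbx - 1)
    by = np.minimum(((flat_lat - lat_min) / (lat_max - lat_min) * nby).astype(int), nby - 1)
    block_of = bx * nby + by

    # one test site from each of n_test distinct blocks, blocks shuffled
    test_idx: list[int] = []
    for block in rng.permutation(nbx * nby):
        if len(test_idx) == config.n_test:
            break
        candidates = valid_idx[block_of[valid_idx] == block]
        if len(candidates) > 0:
            test_idx.append(int(rng.choice(candidates)))
    if len(test_idx) < config.n_test:
        raise SamplingError(
            f"only {len(test_idx)} blocks contain valid cells; "
            f"cannot place {config.n_test} stratified test sites"
        )

    remaining = np.setdiff1d(valid_idx, np.array(test_idx, dtype=int))
    train_idx = rng.choice(remaining, size=config.n_train, replace=False)

    rows = []
    for label, indices in (("train", train_idx), ("test", test_idx)):
        for flat in indices:
            rows.append(
                {
                    "id": f"{label}_{len(rows):03d}",
                    "lon": flat_lon[flat],
                    "lat": flat_lat[flat],
                    "split": label,
                }
            )
    return SampleSet(pd.DataFrame(rows))


def simulate_tissue(
    sites: SampleSet,
    isoscape: Grid,
    config: SyntheticConfig,
    covariate_grids: dict[str, Grid] | None = None,
) -> SampleSet:
    """Attach simulated tissue δ²H (and covariates) to every site.

    δ²H_tissue = calib_intercept + calib_slope · (5-km buffer mean of
    the base field) + ε with ε iid N(0, resid_sd²).  Covariate columns
    are copied from the generating fields at the site cell.
    """
    rng = config.rng(_STAGE_TISSUE)
    frame = sites.frame.copy()
    base_vals = np.empty(len(frame))
    for i, site in enumerate(sites.sites()):
        base_vals[i] = extract_buffer_mean(isoscape, site, config.buffer_radius_km).value
    eps = rng.normal(0.0, config.resid_sd, size=len(frame)) if config.resid_sd > 0 else 0.0
    frame["d2H"] = config.calib_intercept + config.calib_slope * base_vals + eps
    if covariate_grids:
        for name, grid in covariate_grids.items():
            frame[name] = [grid.value_at(lon, lat) for lon, lat in zip(frame["lon"], frame["lat"])]
    return SampleSet(frame)


@dataclass
class SimulatedStudy:
    """One complete synthetic study: rasters, covariates, samples, truth."""

    config: SyntheticConfig
    isoscape: Grid
    base_variance: Grid
    covariate_grids: dict[str, Grid]
    samples: SampleSet
    truth: dict[str, Any] = field(repr=False, default_factory=dict)

    @property
    def train(self) -> SampleSet:
        return self.samples.split("train")

    @property
    def test(self) -> SampleSet:
        return self.samples.split("test")


def simulate_study(config: SyntheticConfig | None = None, **overrides: Any) -> SimulatedStudy:
    """Convenience wrapper running the full generation pipeline."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    isoscape, variance, truth = make_base_isoscape(config)
    sites = sample_sites(isoscape, config)
    samples = simulate_tissue(sites, isoscape, config, truth["covariate_grids"])
    return SimulatedStudy(
        config=config,
        isoscape=isoscape,
        base_variance=variance,
        covariate_grids=truth["covariate_grids"],
        samples=samples,
        truth=truth,
    )
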