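"""Georeferenced raster grids, raster/CSV I/O, cell geometry and buffer extraction.

The raster data model is deliberately minimal: a 2-D array of values in
WGS84 decimal degrees with an explicit nodata mask.  Row 0 is the
northernmost row; the grid origin is the *outer* corner (west edge,
north edge) of the upper-left cell, so cell centers sit at
``origin + (index + 0.5) * cell_size`` (ESRI ``xllcorner`` convention
translated to the upper-left).  No projected CRS support: all distances
are great-circle (haversine, R = 6371 km).

Two on-disk dialects are supported: single-band float GeoTIFF (via
``tifffile`` with the standard ModelPixelScale / ModelTiepoint /
GDAL_NODATA tags) and the ESRI ASCII grid
(``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import AssignmentError, ConfigError, FormatError, LocationError

EARTH_RADIUS_KM = 6371.0

#: accepted grid roles and the units of their values
GRID_ROLES = ("isoscape", "variance", "probability", "area")

# GeoTIFF tag codes used for georeferencing
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """A georeferenced 2-D field with a nodata mask.

    Parameters
    ----------
    values
        2-D float array.  Units depend on ``role``: ‰ (isoscape),
        ‰² (variance), dimensionless in [0, 1] (probability), km² (area).
    origin
        (lon, lat) of the outer corner of the upper-left cell, decimal
        degrees WGS84.
    cell_size
        (Δlon, Δlat), both strictly positive, degrees.  Row 0 is the
        northernmost row, so latitude decreases with row index.
    nodata_mask
        Boolean array, True where the cell is invalid.  Defaults to all
        valid.
    role
        One of ``GRID_ROLES``.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: tuple[float, float]
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    role: str = "isoscape"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError(f"grid values must be 2-D, got shape {self.values.shape}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ConfigError("values and nodata_mask must have identical shape")
        if self.cell_size[0] <= 0 or self.cell_size[1] <= 0:
            raise ConfigError(f"cell_size components must be positive, got {self.cell_size}")
        if self.role not in GRID_ROLES:
            raise ConfigError(f"unknown grid role {self.role!r}; expected one of {GRID_ROLES}")

    # ----- geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def lon_centers(self) -> np.ndarray:
        """Longitudes of cell centers, west to east (length ncols)."""
        return self.origin[0] + (np.arange(self.ncols) + 0.5) * self.cell_size[0]

    def lat_centers(self) -> np.ndarray:
        """Latitudes of cell centers, north to south (length nrows)."""
        return self.origin[1] - (np.arange(self.nrows) + 0.5) * self.cell_size[1]

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell-center coordinates, each shape (nrows, ncols)."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the outer grid edges."""
        lon0, lat0 = self.origin
        return (
            lon0,
            lon0 + self.ncols * self.cell_size[0],
            lat0 - self.nrows * self.cell_size[1],
            lat0,
        )

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point.

        Cells are half-open: a point on a shared edge belongs to the
        cell to the south-east of the edge.
        """
        lon_min, lon_max, lat_min, lat_max = self.extent
        if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
            raise LocationError(
                f"point ({lon}, {lat}) outside grid extent "
                f"lon [{lon_min}, {lon_max}], lat [{lat_min}, {lat_max}]"
            )
        col = int(np.floor((lon - lon_min) / self.cell_size[0]))
        row = int(np.floor((lat_max - lat) / self.cell_size[1]))
        # points exactly on the east/south outer edge still belong to the grid
        col = min(col, self.ncols - 1)
        row = min(row, self.nrows - 1)
        return row, col

    def value_at(self, lon: float, lat: float) -> float:
        row, col = self.index_of(lon, lat)
        return float(self.values[row, col])

    # ----- masking --------------------------------------------------

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def with_values(self, values: np.ndarray, role: str | None = None) -> "Grid":
        """A new grid sharing this grid's georeferencing and mask."""
        return Grid(
            values=np.asarray(values, dtype=float),
            origin=self.origin,
            cell_size=self.cell_size,
            nodata_mask=self.nodata_mask.copy(),
            role=role or self.role,
        )

    def copy(self) -> "Grid":
        return replace(
            self, values=self.values.copy(), nodata_mask=self.nodata_mask.copy()
        )

    def same_georeference(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
            and abs(self.cell_size[0] - other.cell_size[0]) <= tol
            and abs(self.cell_size[1] - other.cell_size[1]) <= tol
        )


def require_coregistered(*grids: Grid) -> None:
    """Raise ConfigError unless all grids share shape and georeferencing."""
    first = grids[0]
    for g in grids[1:]:
        if not first.same_georeference(g):
            raise ConfigError(
                "grids are not co-registered: "
                f"{first.shape}/{first.origin}/{first.cell_size} vs "
                f"{g.shape}/{g.origin}/{g.cell_size}"
            )


# --------------------------------------------------------------------
# sites and sample tables
# --------------------------------------------------------------------


@dataclass
class Site:
    """A sampling or query site in WGS84 decimal degrees."""

    id: str
    lon: float
    lat: float
    delta2H_measured: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ConfigError(f"site {self.id}: latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ConfigError(f"site {self.id}: longitude {self.lon} outside [-180, 180]")


_RESERVED_COLUMNS = ("id", "lon", "lat", "d2H", "split")


class SampleSet:
    """An ordered collection of sites backed by a DataFrame.

    Required columns: ``id``, ``lon``, ``lat``.  Optional: ``d2H``
    (measured tissue δ²H, ‰ vs VSMOW), ``split`` (``train``/``test``).
    Any other column is treated as a named environmental covariate.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.reset_index(drop=True).copy()
        for col in ("id", "lon", "lat"):
            if col not in frame.columns:
                raise FormatError(f"sample table missing required column {col!r}")
        if frame["id"].duplicated().any():
            dupes = frame.loc[frame["id"].duplicated(), "id"].tolist()
            raise FormatError(f"duplicate site ids: {dupes}")
        if (frame["lat"].abs() > 90).any() or (frame["lon"].abs() > 180).any():
            raise FormatError("coordinates outside WGS84 decimal-degree bounds")
        if "split" in frame.columns:
            bad = set(frame["split"].dropna()) - {"train", "test"}
            if bad:
                raise FormatError(f"unknown split labels: {sorted(bad)}")
            train = frame[frame["split"] == "train"]
            if "d2H" in frame.columns and train["d2H"].isna().any():
                raise FormatError("every train site must have a measured d2H value")
        self.frame = frame

    # ----- basic access --------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in _RESERVED_COLUMNS]

    @property
    def lons(self) -> np.ndarray:
        return self.frame["lon"].to_numpy(float)

    @property
    def lats(self) -> np.ndarray:
        return self.frame["lat"].to_numpy(float)

    @property
    def d2H(self) -> np.ndarray:
        if "d2H" not in self.frame.columns:
            raise FormatError("sample table has no d2H column")
        return self.frame["d2H"].to_numpy(float)

    def sites(self) -> Iterator[Site]:
        cov_names = self.covariate_names
        for _, row in self.frame.iterrows():
            yield Site(
                id=str(row["id"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                delta2H_measured=(
                    float(row["d2H"])
                    if "d2H" in self.frame.columns and pd.notna(row["d2H"])
                    else None
                ),
                covariates={c: float(row[c]) for c in cov_names},
            )

    def site(self, i: int) -> Site:
        return self.subset([i]).first_site()

    def first_site(self) -> Site:
        return next(self.sites())

    def subset(self, index: Sequence[int]) -> "SampleSet":
        return SampleSet(self.frame.iloc[list(index)])

    def split(self, label: str) -> "SampleSet":
        if "split" not in self.frame.columns:
            raise FormatError("sample table has no split column")
        return SampleSet(self.frame[self.frame["split"] == label])

    # ----- I/O ------------------------------------------------------

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleSet":
        try:
            frame = pd.read_csv(path)
        except (OSError, pd.errors.ParserError) as exc:
            raise FormatError(f"cannot read sample CSV {path}: {exc}") from exc
        return cls(frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


# --------------------------------------------------------------------
# distance and cell geometry
# --------------------------------------------------------------------


def haversine_km(
    lon1: np.ndarray | float,
    lat1: np.ndarray | float,
    lon2: np.ndarray | float,
    lat2: np.ndarray | float,
) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def cell_area_km2(grid: Grid) -> Grid:
    """Per-cell area grid (km²) under the spherical approximation.

    A = (πR/180)² · Δlon · Δlat · cos(φ_center), R = 6371 km.  Cells
    centered at a pole legitimately get area 0.
    """
    deg_to_km = np.pi * EARTH_RADIUS_KM / 180.0
    lat_c = grid.lat_centers()
    band = deg_to_km**2 * grid.cell_size[0] * grid.cell_size[1] * np.cos(np.radians(lat_c))
    areas = np.repeat(band[:, None], grid.ncols, axis=1)
    return grid.with_values(areas, role="area")


class BufferValue(NamedTuple):
    """Result of a buffered extraction: the value and whether the
    nearest-cell fallback was used (no cell center within the radius)."""

    value: float
    nearest_fallback: bool


def extract_buffer_mean(grid: Grid, site: Site, radius_km: float = 5.0) -> BufferValue:
    """Mean of valid cells whose centers lie within ``radius_km``
    great-circle km of the site.

    If no valid cell center falls inside the buffer, the value of the
    nearest valid cell is returned with ``nearest_fallback=True``.
    Membership is decided by cell center, not polygon intersection.
    """
    if radius_km <= 0:
        raise ConfigError(f"radius_km must be positive, got {radius_km}")
    if not grid.valid.any():
        raise AssignmentError("grid has no valid cells to extract from")
    lon, lat = grid.center_mesh()
    dist = haversine_km(lon, lat, site.lon, site.lat)
    inside = (dist <= radius_km) & grid.valid
    if inside.any():
        return BufferValue(float(grid.values[inside].mean()), False)
    dist = np.where(grid.valid, dist, np.inf)
    i, j = np.unravel_index(np.argmin(dist), dist.shape)
    return BufferValue(float(grid.values[i, j]), True)


def extract_buffer_means(
    grid: Grid, samples: SampleSet, radius_km: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Vector of buffer means for every site; second array flags fallbacks."""
    values = np.empty(len(samples))
    flags = np.zeros(len(samples), dtype=bool)
    for i, site in enumerate(samples.sites()):
        values[i], flags[i] = extract_buffer_mean(grid, site, radius_km)
    return values, flags


# --------------------------------------------------------------------
# raster I/O
# --------------------------------------------------------------------


def write_raster(
    grid: Grid,
    path: str | Path,
    dialect: str = "esri_ascii",
    nodata: float = DEFAULT_NODATA,
) -> None:
    """Write a grid as GeoTIFF or ESRI ASCII."""
    path = Path(path)
    if dialect == "esri_ascii":
        _write_esri_ascii(grid, path, nodata)
    elif dialect == "geotiff":
        _write_geotiff(grid, path, nodata)
    else:
        raise ConfigError(f"unknown raster dialect {dialect!r}")


def read_raster(path: str | Path, dialect: str = "esri_ascii", role: str = "isoscape") -> Grid:
    """Read a grid written by :func:`write_raster` (or compatible files)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"raster file does not exist: {path}")
    if dialect == "esri_ascii":
        return _read_esri_ascii(path, role)
    if dialect == "geotiff":
        return _read_geotiff(path, role)
    raise ConfigError(f"unknown raster dialect {dialect!r}")


def _write_esri_ascii(grid: Grid, path: Path, nodata: float) -> None:
    out = grid.values.copy()
    out[grid.nodata_mask] = nodata
    if abs(grid.cell_size[0] - grid.cell_size[1]) > 1e-12:
        raise FormatError(
            "ESRI ASCII requires square cells; "
            f"got cell_size {grid.cell_size} (use GeoTIFF instead)"
        )
    lon_min, _, lat_min, _ = grid.extent
    buf = io.StringIO()
    buf.write(f"ncols {grid.ncols}\n")
    buf.write(f"nrows {grid.nrows}\n")
    buf.write(f"xllcorner {lon_min!r}\n")
    buf.write(f"yllcorner {lat_min!r}\n")
    buf.write(f"cellsize {grid.cell_size[0]!r}\n")
    buf.write(f"NODATA_value {nodata!r}\n")
    np.savetxt(buf, out, fmt="%.10g")
    path.write_text(buf.getvalue())


def _read_esri_ascii(path: Path, role: str) -> Grid:
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"ESRI ASCII header of {path} missing field {key!r}")
    try:
        values = np.loadtxt(io.StringIO("\n".join(lines[data_start:])), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse ESRI ASCII data block of {path}: {exc}") from exc
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: data block shape {values.shape} does not match "
            f"header nrows={nrows} ncols={ncols}"
        )
    cell = header["cellsize"]
    nodata = header.get("nodata_value")
    mask = np.zeros_like(values, dtype=bool) if nodata is None else values == nodata
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    vals = values.astype(float)
    vals[mask] = np.nan
    return Grid(values=vals, origin=origin, cell_size=(cell, cell), nodata_mask=mask, role=role)


def _write_geotiff(grid: Grid, path: Path, nodata: float) -> None:
    import tifffile

    out = grid.values.astype(np.float64).copy()
    out[grid.nodata_mask] = nodata
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size[0], grid.cell_size[1], 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def _read_geotiff(path: Path, role: str) -> Grid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = {tag.code: tag.value for tag in page.tags.values()}
    except (tifffile.TiffFileError, OSError) as exc:
        raise FormatError(f"cannot read GeoTIFF {path}: {exc}") from exc
    if values.ndim != 2:
        raise FormatError(f"{path}: expected a single-band raster, got shape {values.shape}")
    if _TAG_MODEL_PIXEL_SCALE not in tags:
        raise FormatError(f"{path}: missing georeferencing tag ModelPixelScale (33550)")
    if _TAG_MODEL_TIEPOINT not in tags:
        raise FormatError(f"{path}: missing georeferencing tag ModelTiepoint (33922)")
    scale = tags[_TAG_MODEL_PIXEL_SCALE]
    tie = tags[_TAG_MODEL_TIEPOINT]
    cell_size = (float(scale[0]), float(scale[1]))
    # tiepoint maps raster (0, 0) to the upper-left outer corner
    origin = (float(tie[3]) - tie[0] * cell_size[0], float(tie[4]) + tie[1] * cell_size[1])
    nodata_tag = tags.get(_TAG_GDAL_NODATA)
    if nodata_tag is not None:
        nodata = float(nodata_tag)
        mask = values == nodata
    else:
        mask = np.isnan(values)
    vals = values.copy()
    vals[mask] = np.nan
    return Grid(values=vals, origin=origin, cell_size=cell_size, nodata_mask=mask, role=role)
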