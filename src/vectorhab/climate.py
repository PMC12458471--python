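"""Climate feature engineering on gridded daily weather data.

Raw inputs are daily rasters of 2-m air temperature (mean/max/min), dew-point
temperature, hourly-average precipitation and the u/v wind components on a
regular lat/lon grid (reanalysis-style, default 0.25 degree). From these the
pipeline derives the five daily habitat covariates used by the suitability
classifier:

* ``temp_range``   -- daily max minus min 2-m temperature [degC]
* ``temp_mean``    -- daily mean 2-m temperature [degC]
* ``rel_humidity`` -- August-Roche-Magnus relative humidity from dew point [%]
* ``precip_total`` -- 24 x hourly-average precipitation [mm/day]
* ``wind_speed``   -- Euclidean norm of the u/v components [m/s]

Each observation record is then joined with the feature sequence at its
nearest grid cell for the ``seq_len`` days preceding (and excluding) the
observation date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import (
    ConfigurationError,
    DataIntegrityError,
    IncompleteSequenceError,
    InvalidInputError,
    OutOfDomainError,
)

log = logging.getLogger(__name__)

#: Magnus-formula constants (temperatures in degC).
MAGNUS_A = 17.625
MAGNUS_B = 243.04

#: Canonical derived feature names, in model input order.
DERIVED_VARIABLES = (
    "temp_range",
    "temp_mean",
    "rel_humidity",
    "precip_total",
    "wind_speed",
)

#: Raw variables each derived feature consumes.
RAW_REQUIREMENTS = {
    "temp_range": ("t2m_max", "t2m_min"),
    "temp_mean": ("t2m_mean",),
    "rel_humidity": ("dewpoint", "t2m_mean"),
    "precip_total": ("precip_hourly_avg",),
    "wind_speed": ("wind_u", "wind_v"),
}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ClimateGrid:
    """A multi-day stack of raw weather rasters on a regular lat/lon grid.

    ``variables`` maps raw variable names to arrays of shape
    ``(n_days, n_lat, n_lon)``. Temperatures are degC (readers convert from
    Kelvin), precipitation is mm/h, wind m/s. ``land_mask`` is True on land.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    dates: pd.DatetimeIndex
    variables: dict[str, np.ndarray]
    land_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        self.lon_centers = np.asarray(self.lon_centers, dtype=float)
        self.dates = pd.DatetimeIndex(self.dates)
        _check_regular(self.lat_centers, "lat")
        _check_regular(self.lon_centers, "lon")
        shape = (len(self.dates), self.lat_centers.size, self.lon_centers.size)
        for name, arr in self.variables.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ConfigurationError(
                    f"variable {name!r} has shape {arr.shape}, expected {shape}"
                )
            self.variables[name] = arr
        if self.land_mask is None:
            self.land_mask = np.ones(shape[1:], dtype=bool)
        else:
            self.land_mask = np.asarray(self.land_mask, dtype=bool)
            if self.land_mask.shape != shape[1:]:
                raise ConfigurationError("land_mask shape does not match grid")
        self._validate_temperatures()

    def _validate_temperatures(self) -> None:
        v = self.variables
        if {"t2m_min", "t2m_mean", "t2m_max"} <= set(v):
            ok = (v["t2m_min"] <= v["t2m_mean"] + 1e-9) & (
                v["t2m_mean"] <= v["t2m_max"] + 1e-9
            )
            bad = ~ok & np.isfinite(v["t2m_min"]) & np.isfinite(v["t2m_max"])
            if bad.any():
                d, i, j = (int(x) for x in np.argwhere(bad)[0])
                raise DataIntegrityError(
                    "t2m_min <= t2m_mean <= t2m_max violated at "
                    f"date {self.dates[d].date()}, cell ({i}, {j})"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.dates), self.lat_centers.size, self.lon_centers.size)


@dataclass
class DerivedFeatureGrid:
    """Daily derived habitat covariates on the same grid as the raw data."""

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    dates: pd.DatetimeIndex
    features: dict[str, np.ndarray]
    land_mask: np.ndarray | None = None

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(self.features)

    def to_dataset(self) -> xr.Dataset:
        """Export as an xarray Dataset (CF-style lat/lon/time dims)."""
        return xr.Dataset(
            {
                name: (("time", "lat", "lon"), arr)
                for name, arr in self.features.items()
            },
            coords={
                "time": self.dates,
                "lat": self.lat_centers,
                "lon": self.lon_centers,
            },
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "DerivedFeatureGrid":
        ds = xr.open_dataset(path, engine="scipy")
        return cls(
            lat_centers=ds["lat"].values.astype(float),
            lon_centers=ds["lon"].values.astype(float),
            dates=pd.DatetimeIndex(ds["time"].values),
            features={name: ds[name].values.astype(float) for name in ds.data_vars},
        )


@dataclass
class FeatureSequence:
    """seq_len x n_vars feature matrix preceding one record's date.

    Row 0 is the day before the record date; row ``k`` is ``k + 1`` days
    before. The record's own date is never included.
    """

    record_id: str
    matrix: np.ndarray
    grid_cell: tuple[int, int]
    variable_names: tuple[str, ...] = field(default=DERIVED_VARIABLES)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise IncompleteSequenceError(
                f"record {self.record_id}: non-finite entries in feature matrix"
            )


# ---------------------------------------------------------------------------
# Scalar feature operations
# ---------------------------------------------------------------------------


def _require_finite(*values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("non-finite input")


def relative_humidity(t_dew, t_mean, clip: bool = False):
    """Relative humidity [%] from dew-point and mean temperature [degC].

    August-Roche-Magnus form::

        RH = 100 * exp(a*T_d / (b + T_d)) / exp(a*T_m / (b + T_m))

    with a = 17.625, b = 243.04. Supersaturated inputs (t_dew > t_mean)
    yield RH > 100; set ``clip=True`` to cap at 100.
    """
    t_dew = np.asarray(t_dew, dtype=float)
    t_mean = np.asarray(t_mean, dtype=float)
    _require_finite(t_dew, t_mean)
    if np.any(t_dew <= -MAGNUS_B) or np.any(t_mean <= -MAGNUS_B):
        raise InvalidInputError(f"temperatures must exceed -{MAGNUS_B} degC")
    rh = 100.0 * np.exp(
        MAGNUS_A * t_dew / (MAGNUS_B + t_dew) - MAGNUS_A * t_mean / (MAGNUS_B + t_mean)
    )
    if clip:
        rh = np.minimum(rh, 100.0)
    return rh if rh.ndim else float(rh)


def daily_precip_total(hourly_avg):
    """Total daily precipitation [mm/day] = 24 x average hourly rate [mm/h]."""
    hourly_avg = np.asarray(hourly_avg, dtype=float)
    _require_finite(hourly_avg)
    if np.any(hourly_avg < 0):
        raise InvalidInputError("hourly-average precipitation must be >= 0")
    out = 24.0 * hourly_avg
    return out if out.ndim else float(out)


def wind_speed(u, v):
    """Total wind speed [m/s] from u/v components (Euclidean norm)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    _require_finite(u, v)
    out = np.hypot(u, v)
    return out if out.ndim else float(out)


def temp_range(t_max, t_min, *, context: str = ""):
    """Daily temperature range [degC] = t_max - t_min (must be >= 0)."""
    t_max = np.asarray(t_max, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    _require_finite(t_max, t_min)
    if np.any(t_max < t_min):
        where = f" at {context}" if context else ""
        raise DataIntegrityError(f"t_max < t_min{where}")
    out = t_max - t_min
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------


def _check_regular(centers: np.ndarray, name: str) -> None:
    if centers.size < 1:
        raise ConfigurationError(f"{name} axis is empty")
    if centers.size > 1:
        steps = np.diff(centers)
        if np.any(np.abs(np.abs(steps) - np.abs(steps[0])) > 1e-9):
            raise ConfigurationError(f"{name} grid step is not uniform")


def normalize_longitude(lon):
    """Map longitudes to the canonical [-180, 180) convention."""
    lon = np.asarray(lon, dtype=float)
    out = ((lon + 180.0) % 360.0) - 180.0
    return out if out.ndim else float(out)


def derive_daily_features(
    grid: ClimateGrid,
    variables: Sequence[str] = DERIVED_VARIABLES,
    clip_humidity: bool = False,
) -> DerivedFeatureGrid:
    """Compute derived covariate rasters for every day of a climate grid.

    Applies the scalar feature formulas cellwise. Raises
    :class:`ConfigurationError` naming any raw layer absent from the grid.
    """
    missing = sorted(
        {
            raw
            for var in variables
            for raw in RAW_REQUIREMENTS[var]
            if raw not in grid.variables
        }
    )
    if missing:
        raise ConfigurationError(f"missing raw variable layers: {', '.join(missing)}")
    v = grid.variables
    out: dict[str, np.ndarray] = {}
    for var in variables:
        if var == "temp_range":
            out[var] = temp_range(v["t2m_max"], v["t2m_min"], context="grid")
        elif var == "temp_mean":
            out[var] = v["t2m_mean"].copy()
        elif var == "rel_humidity":
            out[var] = relative_humidity(v["dewpoint"], v["t2m_mean"], clip=clip_humidity)
        elif var == "precip_total":
            out[var] = daily_precip_total(v["precip_hourly_avg"])
        elif var == "wind_speed":
            out[var] = wind_speed(v["wind_u"], v["wind_v"])
        else:
            raise ConfigurationError(f"unknown derived variable {var!r}")
    return DerivedFeatureGrid(
        lat_centers=grid.lat_centers,
        lon_centers=grid.lon_centers,
        dates=grid.dates,
        features=out,
        land_mask=grid.land_mask,
    )


def nearest_grid_cell(lat: float, lon: float, grid) -> tuple[int, int]:
    """Index of the grid cell whose center is nearest the query point.

    Nearest is taken independently per axis; ties round toward the lower
    index (``argmin`` on the absolute distance). A point more than one cell
    step outside the bounding box is out of domain.
    """
    if not (-90.0 <= lat <= 90.0):
        raise InvalidInputError(f"latitude {lat} outside [-90, 90]")
    lon = normalize_longitude(lon)
    lats, lons = np.asarray(grid.lat_centers), np.asarray(grid.lon_centers)
    for centers, x, name in ((lats, lat, "lat"), (lons, lon, "lon")):
        step = np.abs(np.diff(centers)).max() if centers.size > 1 else 1.0
        if x < centers.min() - step or x > centers.max() + step:
            raise OutOfDomainError(
                f"{name}={x} lies more than one step outside the grid"
            )
    i = int(np.argmin(np.abs(lats - lat)))
    j = int(np.argmin(np.abs(lons - lon)))
    return i, j


def extract_sequence(
    record,
    features: DerivedFeatureGrid,
    seq_len: int,
    variables: Sequence[str] | None = None,
) -> FeatureSequence:
    """Feature matrix for the ``seq_len`` days before a record's date.

    Row ordering is most-recent-first (day -1 ... day -seq_len). Any missing
    prior day raises :class:`IncompleteSequenceError`; sequences are never
    zero-filled or truncated.
    """
    names = tuple(variables) if variables is not None else features.variable_names
    i, j = nearest_grid_cell(record.latitude, record.longitude, features)
    date = pd.Timestamp(record.date)
    start = features.dates[0]
    # dates are contiguous daily; index arithmetic avoids a per-day search
    offset = (date - start).days
    if offset - seq_len < 0 or offset - 1 >= len(features.dates):
        raise IncompleteSequenceError(
            f"record {record.id}: needs days {date.date()} -1 ... -{seq_len}, "
            f"coverage is {start.date()} ... {features.dates[-1].date()}"
        )
    rows = np.arange(offset - 1, offset - seq_len - 1, -1)
    matrix = np.column_stack([features.features[name][rows, i, j] for name in names])
    return FeatureSequence(
        record_id=record.id, matrix=matrix, grid_cell=(i, j), variable_names=names
    )


def extract_sequences(records, features, seq_len, variables=None):
    """Extract sequences for many records, dropping (with a logged warning)
    any record whose prior days are not fully covered.

    Returns ``(sequences, kept_records)``.
    """
    seqs, kept, dropped = [], [], 0
    for rec in records:
        try:
            seqs.append(extract_sequence(rec, features, seq_len, variables))
            kept.append(rec)
        except (IncompleteSequenceError, OutOfDomainError):
            dropped += 1
    if dropped:
        log.warning("dropped %d records with incomplete feature sequences", dropped)
    return seqs, kept


def load_climate_netcdf(
    path,
    name_map: Mapping[str, str] | None = None,
    kelvin: bool = False,
) -> ClimateGrid:
    """Read a CF-style NetCDF stack of raw daily weather variables.

    ``name_map`` maps file variable names to canonical ones. ``kelvin=True``
    converts all temperature layers to degC on load. A [0, 360) longitude
    axis is rolled onto [-180, 180).
    """
    ds = xr.open_dataset(path, engine="scipy")
    name_map = dict(name_map or {})
    variables = {}
    land_mask = None
    for raw_name in ds.data_vars:
        canon = name_map.get(str(raw_name), str(raw_name))
        if canon == "land_mask":
            land_mask = ds[raw_name].values.astype(bool)
        elif ds[raw_name].ndim == 3:
            variables[canon] = ds[raw_name].values.astype(float)
    lat = ds["lat"].values.astype(float)
    lon = ds["lon"].values.astype(float)
    if lon.max() > 180.0:
        order = np.argsort(normalize_longitude(lon), kind="stable")
        lon = normalize_longitude(lon)[order]
        variables = {k: v[:, :, order] for k, v in variables.items()}
        if land_mask is not None:
            land_mask = land_mask[:, order]
    if kelvin:
        for name in ("t2m_mean", "t2m_max", "t2m_min", "dewpoint"):
            if name in variables:
                variables[name] = variables[name] - 273.15
    return ClimateGrid(
        lat_centers=lat,
        lon_centers=lon,
        dates=pd.DatetimeIndex(ds["time"].values),
        variables=variables,
        land_mask=land_mask,
    )
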