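"""Population-at-risk accounting and trends.

Combines daily FNR rasters with gridded population to count person-days at
high risk: the sum over cells and days of population times an indicator
that the cell's FNR meets or exceeds a threshold (default 0.5, inclusive).
Population anchors at census years are linearly interpolated to
intermediate years; yearly burdens are fitted with ordinary least squares
and reported with a 90% t-based prediction interval for a new observation.
Person-day accounting uses a 365-day year (leap days dropped, matching the
seasonal statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AlignmentError, InsufficientDataError, InvalidInputError

DEFAULT_THRESHOLD = 0.5

#: Rough rectangular study regions (lat_min, lat_max, lon_min, lon_max);
#: approximations to commonly highlighted areas of concern.
DEFAULT_REGIONS = {
    "americas": (-60.0, 50.0, -130.0, -30.0),
    "western_europe": (35.0, 60.0, -10.0, 20.0),
    "se_asia": (-10.0, 30.0, 90.0, 140.0),
}


@dataclass
class TrendFit:
    """OLS fit of burden against year with a prediction-interval band."""

    slope: float
    intercept: float
    years: np.ndarray
    fitted: np.ndarray
    pi_lower: np.ndarray
    pi_upper: np.ndarray
    alpha: float = 0.10


def interpolate_linear(anchors, target_year: float) -> float:
    """Piecewise-linear interpolation between (year, value) anchors.

    Exact at anchors; extrapolation outside the anchor span is refused.
    """
    anchors = sorted(anchors)
    years = np.array([a[0] for a in anchors], dtype=float)
    values = np.array([a[1] for a in anchors], dtype=float)
    if not (years[0] <= target_year <= years[-1]):
        raise InvalidInputError(
            f"year {target_year} outside anchor span [{years[0]}, {years[-1]}]"
        )
    return float(np.interp(target_year, years, values))


def region_mask(lat_centers, lon_centers, bounds) -> np.ndarray:
    """Boolean raster for a (lat_min, lat_max, lon_min, lon_max) rectangle."""
    lat_min, lat_max, lon_min, lon_max = bounds
    lat = np.asarray(lat_centers, dtype=float)[:, None]
    lon = np.asarray(lon_centers, dtype=float)[None, :]
    return (lat >= lat_min) & (lat <= lat_max) & (lon >= lon_min) & (lon <= lon_max)


def population_days_at_risk(
    daily_fnr: np.ndarray,
    population: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    region: np.ndarray | None = None,
) -> float:
    """Person-days with FNR at or above threshold over one year of rasters.

    ``daily_fnr`` has shape (n_days, nlat, nlon); ``population`` is persons
    per cell on the same grid. The threshold comparison is inclusive (>=),
    so lowering the threshold never decreases the burden.
    """
    daily_fnr = np.asarray(daily_fnr, dtype=float)
    population = np.asarray(population, dtype=float)
    if daily_fnr.shape[1:] != population.shape:
        raise AlignmentError(
            f"risk grid {daily_fnr.shape[1:]} vs population grid {population.shape}"
        )
    days_at_risk = (daily_fnr >= threshold).sum(axis=0).astype(float)
    cellwise = population * days_at_risk
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != population.shape:
            raise AlignmentError("region mask grid mismatch")
        cellwise = cellwise[region]
    return float(cellwise.sum())


def aggregate_population(
    density: np.ndarray,
    factor: int,
) -> np.ndarray:
    """Mass-conserving downsampling of a fine population raster by an
    integer block factor (sum of persons, not density interpolation)."""
    density = np.asarray(density, dtype=float)
    nlat, nlon = density.shape
    if nlat % factor or nlon % factor:
        raise AlignmentError("population raster not divisible by block factor")
    return density.reshape(nlat // factor, factor, nlon // factor, factor).sum(
        axis=(1, 3)
    )


def trend_regression(years, burdens, alpha: float = 0.10) -> TrendFit:
    """OLS burden-vs-year fit with a (1 - alpha) prediction interval.

    The interval uses the standard t-based formula for a new observation at
    each observed year, via the fitted model's prediction machinery.
    """
    years = np.asarray(years, dtype=float)
    burdens = np.asarray(burdens, dtype=float)
    if years.size < 3:
        raise InsufficientDataError("trend regression needs at least 3 years")
    X = sm.add_constant(years)
    fit = sm.OLS(burdens, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=alpha)
    return TrendFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        years=years,
        fitted=np.asarray(pred["mean"]),
        pi_lower=np.asarray(pred["obs_ci_lower"]),
        pi_upper=np.asarray(pred["obs_ci_upper"]),
        alpha=alpha,
    )


def percent_change(series: dict, start_year: int, end_year: int) -> float:
    """Percent change of a yearly burden series between two years."""
    if start_year not in series or end_year not in series:
        raise InvalidInputError("both years must be present in the series")
    start, end = float(series[start_year]), float(series[end_year])
    if start <= 0:
        raise InvalidInputError("percent change undefined for zero/negative start")
    return 100.0 * (end - start) / start


def burden_series_frame(series: dict, species: str, region: str) -> pd.DataFrame:
    """Long-format (year, region, species, person_days) table for CSV export."""
    return pd.DataFrame(
        {
            "year": list(series),
            "region": region,
            "species": species,
            "person_days": list(series.values()),
        }
    )
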