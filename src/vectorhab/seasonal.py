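"""Seasonality statistics on day-of-year risk series.

All statistics operate on a 365-entry day-of-year FNR series per grid cell
(multi-year average; Feb 29 values are dropped before averaging so every
series has fixed length). Seasons follow the meteorological calendar:
MAM (Spring), JJA (Summer), SON (Fall), DJF (Winter, wrapping the year
boundary). The "mosquito season" of a cell is the shortest CIRCULAR
contiguous day-of-year window holding >= 95% of the series' cumulative
mass; its length d gives the seasonality score 1/d, and the season midpoint
is the day at which the running cumulative sum from the window start first
reaches half the total. Day-of-year numbering is 1-based with day 1 = Jan 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, EmptyInputError, UndefinedSeasonError

DAYS_PER_YEAR = 365

# 1-based day-of-year spans on the 365-day (no Feb 29) calendar
_MAR1, _JUN1, _SEP1, _DEC1 = 60, 152, 244, 335
SEASON_DAYS = {
    "MAM": np.arange(_MAR1, _JUN1),          # 92 days
    "JJA": np.arange(_JUN1, _SEP1),          # 92 days
    "SON": np.arange(_SEP1, _DEC1),          # 91 days
    "DJF": np.concatenate([np.arange(_DEC1, 366), np.arange(1, _MAR1)]),  # 90 days
}
SEASON_ORDER = ("MAM", "JJA", "SON", "DJF")
TRANSITION_ORDER = (
    "spring_to_summer",
    "summer_to_fall",
    "fall_to_winter",
    "winter_to_spring",
)


@dataclass
class SeasonalSummary:
    """Per-cell seasonal means, transitions, diameter, score and midpoint."""

    means: dict[str, float]
    transitions: dict[str, float]
    diameter: int
    seasonality: float
    midpoint: int


def _as_series(series) -> np.ndarray:
    s = np.asarray(series, dtype=float)
    if s.shape[-1] != DAYS_PER_YEAR:
        raise ValueError(f"daily series must have length {DAYS_PER_YEAR}")
    return s


def drop_leap_days(values: np.ndarray, dates) -> np.ndarray:
    """Remove Feb 29 entries so each year contributes exactly 365 values."""
    import pandas as pd

    dates = pd.DatetimeIndex(dates)
    keep = ~((dates.month == 2) & (dates.day == 29))
    return np.asarray(values)[keep]


def multi_year_daily_average(yearly_series) -> np.ndarray:
    """Mean day-of-year series over a list of per-year 365-length arrays."""
    yearly_series = list(yearly_series)
    if not yearly_series:
        raise EmptyInputError("no yearly series supplied")
    stack = np.stack([_as_series(s) for s in yearly_series])
    return stack.mean(axis=0)


def seasonal_means(series) -> dict[str, float]:
    """Mean FNR over each meteorological season (DJF wraps the year)."""
    s = _as_series(series)
    return {
        name: float(s[..., days - 1].mean(axis=-1))
        if s.ndim == 1
        else s[..., days - 1].mean(axis=-1)
        for name, days in SEASON_DAYS.items()
    }


def season_transitions(means: dict[str, float]) -> dict[str, float]:
    """Differences between successive seasonal means, cyclic over the year.

    The four transitions telescope: their cyclic sum is zero.
    """
    m = [means[k] for k in SEASON_ORDER]
    diffs = [m[(i + 1) % 4] - m[i] for i in range(4)]
    return dict(zip(TRANSITION_ORDER, diffs))


def _window_sums(s: np.ndarray, length: int) -> np.ndarray:
    """Sums of all 365 circular windows of a given length."""
    ext = np.concatenate([s, s[: length - 1]]) if length > 1 else s
    c = np.concatenate([[0.0], np.cumsum(ext)])
    return c[length : length + DAYS_PER_YEAR] - c[:DAYS_PER_YEAR]


def season_diameter(series, mass: float = 0.95, circular: bool = True) -> tuple[int, int]:
    """Length d and 1-based start day of the shortest contiguous window
    whose summed FNR reaches ``mass`` of the series total.

    The search is circular by default (invariant to calendar origin);
    ``circular=False`` restricts windows to within the Jan 1 - Dec 31 year.
    Ties between equal-length windows break to the earliest start day.
    Returns ``(d, start_day)``; seasonality score is ``1/d``.
    """
    s = _as_series(series)
    total = s.sum()
    if total <= 0:
        raise UndefinedSeasonError("series has no mass; season undefined")
    target = mass * total
    for length in range(1, DAYS_PER_YEAR + 1):
        sums = _window_sums(s, length)
        if not circular:
            sums = sums[: DAYS_PER_YEAR - length + 1]
        hit = sums >= target - 1e-12 * total
        if hit.any():
            return length, int(np.argmax(hit)) + 1
    return DAYS_PER_YEAR, 1  # unreachable: the full year always qualifies


def season_midpoint(series, mass: float = 0.95) -> int:
    """Day of year splitting the cumulative FNR in half.

    Starting at the diameter window's start day, the midpoint is the first
    day at which the running circular cumulative sum reaches 50% of the
    series total, reported on the 1–365 circle.
    """
    s = _as_series(series)
    _, start = season_diameter(s, mass=mass)
    rolled = np.roll(s, -(start - 1))
    cum = np.cumsum(rolled)
    k = int(np.argmax(cum >= 0.5 * s.sum() - 1e-12 * s.sum()))
    return (start - 1 + k) % DAYS_PER_YEAR + 1


def summarize(series, mass: float = 0.95) -> SeasonalSummary:
    """Full seasonal summary of one daily risk series."""
    s = _as_series(series)
    means = seasonal_means(s)
    d, _ = season_diameter(s, mass=mass)
    return SeasonalSummary(
        means=means,
        transitions=season_transitions(means),
        diameter=d,
        seasonality=1.0 / d,
        midpoint=season_midpoint(s, mass=mass),
    )


def exclusion_mask(midpoints, window_days: int = 10) -> np.ndarray:
    """True where a season midpoint lies within ``window_days`` of Jan 1
    (circular distance), flagging cells with negligible-mass artifacts."""
    mp = np.asarray(midpoints, dtype=float)
    dist = np.minimum((mp - 1) % DAYS_PER_YEAR, (1 - mp) % DAYS_PER_YEAR)
    return dist <= window_days


def difference_map(recent: np.ndarray, historical: np.ndarray) -> np.ndarray:
    """Cellwise change in mean risk: recent epoch minus historical epoch."""
    recent, historical = np.asarray(recent, float), np.asarray(historical, float)
    if recent.shape != historical.shape:
        raise AlignmentError(
            f"epoch rasters differ in shape: {recent.shape} vs {historical.shape}"
        )
    return recent - historical


def transition_anomaly(
    current: dict[str, float],
    historical: dict[str, float],
    signed: bool = False,
) -> dict[str, float]:
    """Change in the strength of each seasonal transition.

    Default: |current| - |historical| per transition, so negative values
    mark temporal homogenization (seasons more alike than historically) and
    positive values temporal diversification. ``signed=True`` switches to
    raw signed differences instead.
    """
    out = {}
    for key in TRANSITION_ORDER:
        if signed:
            out[key] = current[key] - historical[key]
        else:
            out[key] = abs(current[key]) - abs(historical[key])
    return out
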