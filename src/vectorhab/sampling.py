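"""Presence ingestion, pseudo-absence generation and train/test splitting.

True presences come from citizen-science occurrence CSVs (latitude,
longitude, observation date). Because no true absence data exist,
pseudo-absences are drawn area-uniformly over land — latitude by inverse-CDF
sampling in sin(latitude), which makes the latitude density proportional to
cos(latitude) — with a random date inside the presence observation window.
A draw whose nearest grid cell is occupied by any presence is rejected and
redrawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .climate import nearest_grid_cell, normalize_longitude
from .errors import (
    ConfigurationError,
    EmptyInputError,
    OutOfDomainError,
    SamplingError,
)

log = logging.getLogger(__name__)

PRESENCE = "presence"
PSEUDO_ABSENCE = "pseudo_absence"

DEFAULT_COLUMNS = {
    "latitude": "latitude",
    "longitude": "longitude",
    "date": "observed_on",
    "species": "scientific_name",
}


@dataclass
class ObservationRecord:
    """One presence or pseudo-absence record."""

    id: str
    species: str
    latitude: float
    longitude: float
    date: pd.Timestamp
    label: str = PRESENCE

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"record {self.id}: latitude {self.latitude} out of range")


@dataclass
class SplitAssignment:
    """Disjoint, exhaustive train/test partition with optional CV folds."""

    train_ids: list[str]
    test_ids: list[str]
    fold_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def load_observations(
    path,
    species: str | None = None,
    window: tuple | None = None,
    columns: dict[str, str] | None = None,
) -> list[ObservationRecord]:
    """Load presence records from an occurrence CSV.

    Rows with unparseable dates or coordinates, out-of-range latitudes,
    mismatched species or dates outside ``window`` are dropped; the dropped
    count is logged. Raises :class:`EmptyInputError` if nothing survives.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path)
    for key in ("latitude", "longitude", "date"):
        if cols[key] not in df.columns:
            raise ConfigurationError(f"missing column {cols[key]!r} in {path}")
    n_raw = len(df)
    lat = pd.to_numeric(df[cols["latitude"]], errors="coerce")
    lon = pd.to_numeric(df[cols["longitude"]], errors="coerce")
    dates = pd.to_datetime(df[cols["date"]], errors="coerce")
    ok = lat.notna() & lon.notna() & dates.notna() & lat.between(-90, 90)
    if species is not None and cols["species"] in df.columns:
        ok &= df[cols["species"]].astype(str).str.strip() == species
    if window is not None:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        ok &= (dates >= lo) & (dates <= hi)
    dropped = n_raw - int(ok.sum())
    if dropped:
        log.info("load_observations: dropped %d of %d rows", dropped, n_raw)
    records = [
        ObservationRecord(
            id=f"obs{idx}",
            species=species or str(df[cols["species"]].iloc[idx])
            if cols["species"] in df.columns
            else "unknown",
            latitude=float(lat.iloc[idx]),
            longitude=normalize_longitude(float(lon.iloc[idx])),
            date=dates.iloc[idx],
            label=PRESENCE,
        )
        for idx in np.flatnonzero(ok.to_numpy())
    ]
    if not records:
        raise EmptyInputError(f"no valid observation rows in {path}")
    return records


# ---------------------------------------------------------------------------
# Pseudo-absence generation
# ---------------------------------------------------------------------------


def presence_cells(presences, grid) -> set[tuple[int, int]]:
    """Set of nearest grid cells occupied by any presence."""
    cells = set()
    for rec in presences:
        try:
            cells.add(nearest_grid_cell(rec.latitude, rec.longitude, grid))
        except OutOfDomainError:
            continue
    return cells


def generate_pseudo_absences(
    presences,
    grid,
    n: int,
    rng_seed: int,
    max_attempts_per_record: int = 1000,
) -> list[ObservationRecord]:
    """Draw ``n`` pseudo-absences on land, area-uniformly on the sphere.

    Latitude is drawn by inverse-CDF sampling in sin(latitude) restricted to
    the grid's latitude span (density proportional to cos(latitude));
    longitude uniformly over the grid's span; the date uniformly over the
    presence observation window. A draw is rejected when its nearest grid
    cell is ocean or is shared with any presence.
    """
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    if n == 0:
        return []
    rng = np.random.default_rng(rng_seed)
    occupied = presence_cells(presences, grid)
    land = np.asarray(grid.land_mask, dtype=bool)
    free_land = [
        (i, j)
        for i in range(land.shape[0])
        for j in range(land.shape[1])
        if land[i, j] and (i, j) not in occupied
    ]
    if not free_land:
        raise SamplingError("no land cell is free of presences")

    dates = pd.DatetimeIndex([rec.date for rec in presences])
    t0, t1 = dates.min(), dates.max()
    n_days = (t1 - t0).days + 1

    lat_step = (
        abs(float(np.diff(grid.lat_centers)[0])) if grid.lat_centers.size > 1 else 0.25
    )
    lon_step = (
        abs(float(np.diff(grid.lon_centers)[0])) if grid.lon_centers.size > 1 else 0.25
    )
    lat_lo = max(-90.0, float(grid.lat_centers.min()) - lat_step / 2)
    lat_hi = min(90.0, float(grid.lat_centers.max()) + lat_step / 2)
    lon_lo = float(grid.lon_centers.min()) - lon_step / 2
    lon_hi = float(grid.lon_centers.max()) + lon_step / 2
    s_lo, s_hi = np.sin(np.radians(lat_lo)), np.sin(np.radians(lat_hi))

    out: list[ObservationRecord] = []
    attempts = 0
    budget = max_attempts_per_record * n
    while len(out) < n:
        if attempts >= budget:
            raise SamplingError(
                f"pseudo-absence sampling exhausted after {attempts} attempts "
                f"({len(out)}/{n} accepted)"
            )
        attempts += 1
        lat = float(np.degrees(np.arcsin(rng.uniform(s_lo, s_hi))))
        lon = float(rng.uniform(lon_lo, lon_hi))
        cell = nearest_grid_cell(lat, lon, grid)
        if not land[cell] or cell in occupied:
            continue
        date = t0 + pd.Timedelta(days=int(rng.integers(0, n_days)))
        out.append(
            ObservationRecord(
                id=f"abs{len(out)}",
                species=presences[0].species if presences else "unknown",
                latitude=lat,
                longitude=normalize_longitude(lon),
                date=date,
                label=PSEUDO_ABSENCE,
            )
        )
    log.info(
        "generated %d pseudo-absences in %d attempts (%.1f%% accepted)",
        n,
        attempts,
        100.0 * n / attempts,
    )
    return out


def count_absences(n_presence: int, absence_ratio: float = 0.2) -> int:
    """Number of pseudo-absences for a presence count and absence ratio.

    The ratio is presences-per-absence: a ratio of 0.2 yields five
    pseudo-absences per presence, ``round(n_presence / absence_ratio)``.
    """
    if not (0.0 < absence_ratio <= 1.0):
        raise ConfigurationError("absence_ratio must be in (0, 1]")
    return int(round(n_presence / absence_ratio))


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def _partition(records):
    pres = [r for r in records if r.label == PRESENCE]
    abs_ = [r for r in records if r.label == PSEUDO_ABSENCE]
    return pres, abs_


def split_random(records, test_fraction: float = 0.2, rng_seed: int = 0) -> SplitAssignment:
    """Random split: ``test_fraction`` of presences plus an equal number of
    random pseudo-absences go to test; everything else trains."""
    rng = np.random.default_rng(rng_seed)
    pres, abs_ = _partition(records)
    n_test = int(round(test_fraction * len(pres)))
    if n_test > len(abs_):
        raise SamplingError(
            f"need {n_test} test pseudo-absences, only {len(abs_)} available"
        )
    test_pres = set(rng.choice([r.id for r in pres], size=n_test, replace=False))
    test_abs = set(rng.choice([r.id for r in abs_], size=n_test, replace=False))
    test = test_pres | test_abs
    return SplitAssignment(
        train_ids=[r.id for r in records if r.id not in test],
        test_ids=[r.id for r in records if r.id in test],
    )


def split_chronological(records, test_fraction: float = 0.2, rng_seed: int = 0) -> SplitAssignment:
    """Chronological split: the most recent ``test_fraction`` of presences go
    to test, paired with an equal number of pseudo-absences drawn from the
    test presences' date span where possible (topped up randomly if short).
    Boundary-date ties are broken by record id."""
    rng = np.random.default_rng(rng_seed)
    pres, abs_ = _partition(records)
    n_test = int(round(test_fraction * len(pres)))
    if n_test > len(abs_):
        raise SamplingError(
            f"need {n_test} test pseudo-absences, only {len(abs_)} available"
        )
    order = sorted(pres, key=lambda r: (r.date, r.id))
    test_pres = {r.id for r in order[len(order) - n_test:]}
    cutoff = order[len(order) - n_test].date if n_test else None
    in_span = [r for r in abs_ if cutoff is not None and r.date >= cutoff]
    chosen = [r.id for r in in_span[:n_test]]
    if len(chosen) < n_test:
        pool = [r.id for r in abs_ if r.id not in set(chosen)]
        top_up = rng.choice(pool, size=n_test - len(chosen), replace=False)
        chosen.extend(str(x) for x in top_up)
    test = test_pres | set(chosen)
    return SplitAssignment(
        train_ids=[r.id for r in records if r.id not in test],
        test_ids=[r.id for r in records if r.id in test],
    )


def kfold(train_records, k: int = 5, rng_seed: int = 0) -> dict[str, int]:
    """Label-stratified k-fold assignment (fold indices 1..k) for the
    training pool; per-fold presence fractions match the pool to rounding."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if len(train_records) < k:
        raise ConfigurationError(f"need at least {k} records for {k}-fold CV")
    labels = np.array([r.label == PRESENCE for r in train_records], dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    fold_of: dict[str, int] = {}
    for fold_idx, (_, val_idx) in enumerate(skf.split(labels, labels), start=1):
        for i in val_idx:
            fold_of[train_records[i].id] = fold_idx
    return fold_of


def records_to_frame(records) -> pd.DataFrame:
    """Serialize records to a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "species": [r.species for r in records],
            "latitude": [r.latitude for r in records],
            "longitude": [r.longitude for r in records],
            "date": [r.date for r in records],
            "label": [r.label for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[ObservationRecord]:
    return [
        ObservationRecord(
            id=str(row.id),
            species=str(row.species),
            latitude=float(row.latitude),
            longitude=float(row.longitude),
            date=pd.Timestamp(row.date),
            label=str(row.label),
        )
        for row in df.itertuples(index=False)
    ]
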