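"""Stage orchestration: each stage reads its upstream artifacts, writes its
declared outputs plus a metadata sidecar (config hash, seed), and is
idempotent given identical inputs."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .calibration import CalibrationTable, build_calibration, calibrate_map, score_to_fnr
from .climate import DerivedFeatureGrid, derive_daily_features, load_climate_netcdf
from .config import RunConfig
from .errors import ConfigurationError, DependencyError
from .evaluation import roc_auc
from .nn import (
    ModelSpec,
    TrainedModel,
    predict_scores,
    sequences_to_matrix,
    train,
)
from .climate import extract_sequences
from .evaluation import stratified_holdout
from .sampling import (
    PRESENCE,
    count_absences,
    generate_pseudo_absences,
    load_observations,
    records_from_frame,
    records_to_frame,
    split_chronological,
    split_random,
)
from .seasonal import exclusion_mask, season_diameter, season_midpoint, seasonal_means
from .burden import population_days_at_risk, trend_regression
from .synthetic import (
    WorldParams,
    generate_population,
    generate_world,
    sample_presences,
    world_to_netcdf,
)

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "features",
    "sample",
    "train",
    "predict",
    "seasonality",
    "burden",
    "evaluate",
)


def _sidecar(path: Path, config: RunConfig, extra: dict | None = None) -> None:
    meta = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        **(extra or {}),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} needs missing artifact {path}")
    return path


def run_stage(stage: str, config: RunConfig) -> dict:
    """Run one pipeline stage; returns a dict of artifact paths/metrics."""
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return globals()[f"_stage_{stage}"](config, out)


def _stage_simulate(config: RunConfig, out: Path) -> dict:
    params = WorldParams(**config.world)
    world = generate_world(params, seed=config.seed)
    world_to_netcdf(world, out / "world.nc")
    min_prior = max(config.seq_len, 1)
    presences = sample_presences(
        world, config.n_presences, rng_seed=config.seed + 1, min_prior_days=min_prior,
        species=config.species,
    )
    records_to_frame(presences).to_csv(out / "observations.csv", index=False)
    pop = generate_population(world, seed=config.seed + 2)
    pd.DataFrame(pop).to_csv(out / "population.csv", index=False, header=False)
    for name in ("world.nc", "observations.csv", "population.csv"):
        _sidecar(out / name, config)
    log.info("simulate: %d presences on a %s grid", len(presences), world.grid.shape)
    return {"world": out / "world.nc", "observations": out / "observations.csv"}


def _load_world_grid(config: RunConfig, out: Path, stage: str):
    path = Path(config.climate_path) if config.climate_path else out / "world.nc"
    _require(path, stage)
    return load_climate_netcdf(path)


def _stage_features(config: RunConfig, out: Path) -> dict:
    grid = _load_world_grid(config, out, "features")
    feats = derive_daily_features(grid)
    feats.to_netcdf(out / "features.nc")
    _sidecar(out / "features.nc", config)
    return {"features": out / "features.nc"}


def _stage_sample(config: RunConfig, out: Path) -> dict:
    obs_path = Path(config.observations_csv or out / "observations.csv")
    _require(obs_path, "sample")
    grid = _load_world_grid(config, out, "sample")
    presences = load_observations(
        obs_path,
        species=config.species,
        columns={"date": "date", "species": "species"},
    )
    n_abs = count_absences(len(presences), config.absence_ratio)
    absences = generate_pseudo_absences(presences, grid, n_abs, rng_seed=config.seed + 3)
    records = presences + absences
    split_fn = split_random if config.split == "random" else split_chronological
    split = split_fn(records, config.test_fraction, rng_seed=config.seed + 4)
    df = records_to_frame(records)
    df["subset"] = ["test" if r in set(split.test_ids) else "train" for r in df["id"]]
    df.to_csv(out / "records.csv", index=False)
    _sidecar(out / "records.csv", config, {"n_presence": len(presences), "n_absence": n_abs})
    log.info("sample: %d presences + %d pseudo-absences", len(presences), n_abs)
    return {"records": out / "records.csv"}


def _load_records(out: Path, stage: str):
    path = _require(out / "records.csv", stage)
    df = pd.read_csv(path)
    return records_from_frame(df), df


def _stage_train(config: RunConfig, out: Path) -> dict:
    feats = DerivedFeatureGrid.from_netcdf(_require(out / "features.nc", "train"))
    records, df = _load_records(out, "train")
    subset = dict(zip(df["id"], df["subset"]))
    train_recs = [r for r in records if subset[r.id] == "train"]
    seqs, kept = extract_sequences(train_recs, feats, config.seq_len)
    X = sequences_to_matrix(seqs)
    y = np.array([r.label == PRESENCE for r in kept], dtype=float)
    val = stratified_holdout(y, config.val_fraction, config.seed + 5)
    spec = ModelSpec(
        input_dim=X.shape[1],
        hidden=config.hidden,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience_final,
    )
    model = train(spec, X[~val], y[~val], X[val], y[val], rng_seed=config.seed + 6)
    model.variable_names = feats.variable_names
    model.seq_len = config.seq_len
    model.save(out / "model.npz")
    # calibration on training-set true positives
    pos = y.astype(bool)
    table = build_calibration(predict_scores(model, X[pos]), provenance="train")
    table.save(out / "calibration.json")
    for name in ("model.npz", "calibration.json"):
        _sidecar(out / name, config, {"best_epoch": model.best_epoch})
    log.info("train: best val AUC %.4f", max(model.val_auc_trace))
    return {"model": out / "model.npz", "val_auc": max(model.val_auc_trace)}


def _stage_predict(config: RunConfig, out: Path) -> dict:
    feats = DerivedFeatureGrid.from_netcdf(_require(out / "features.nc", "predict"))
    model = TrainedModel.load(_require(out / "model.npz", "predict"))
    table = CalibrationTable.load(_require(out / "calibration.json", "predict"))
    dates = feats.dates[config.seq_len :]
    maps = [calibrate_map(model, table, feats, d) for d in dates]
    fnr = np.stack([m.fnr for m in maps])
    ds = xr.Dataset(
        {"fnr": (("time", "lat", "lon"), fnr)},
        coords={"time": dates, "lat": feats.lat_centers, "lon": feats.lon_centers},
    )
    ds.to_netcdf(out / "risk.nc", engine="scipy")
    _sidecar(out / "risk.nc", config, {"n_days": len(dates)})
    return {"risk": out / "risk.nc", "n_days": len(dates)}


def _load_risk(out: Path, stage: str):
    ds = xr.open_dataset(_require(out / "risk.nc", stage), engine="scipy")
    return ds["fnr"].values, pd.DatetimeIndex(ds["time"].values)


def _stage_seasonality(config: RunConfig, out: Path) -> dict:
    fnr, dates = _load_risk(out, "seasonality")
    doy = dates.dayofyear.to_numpy()
    keep = ~((dates.month == 2) & (dates.day == 29))
    fnr, doy = fnr[keep], doy[keep]
    # day-of-year means; days absent from the risk stack fall back to the
    # all-days mean so every cell has a full 365-entry series
    sums = np.zeros((365,) + fnr.shape[1:])
    counts = np.zeros(365)
    for k, d in enumerate(doy):
        sums[d - 1] += fnr[k]
        counts[d - 1] += 1
    series = np.where(
        counts[:, None, None] > 0,
        sums / np.maximum(counts, 1)[:, None, None],
        fnr.mean(axis=0),
    )
    nlat, nlon = series.shape[1:]
    diam = np.zeros((nlat, nlon))
    mid = np.zeros((nlat, nlon))
    for i in range(nlat):
        for j in range(nlon):
            s = series[:, i, j]
            if s.sum() <= 0:
                diam[i, j], mid[i, j] = np.nan, np.nan
                continue
            d, _ = season_diameter(s, mass=config.season_mass)
            diam[i, j] = d
            mid[i, j] = season_midpoint(s, mass=config.season_mass)
    means = seasonal_means(np.moveaxis(series, 0, -1))
    excl = exclusion_mask(np.nan_to_num(mid, nan=1.0), config.exclusion_days)
    ds = xr.Dataset(
        {
            "diameter": (("lat", "lon"), diam),
            "seasonality": (("lat", "lon"), 1.0 / diam),
            "midpoint": (("lat", "lon"), mid),
            "excluded": (("lat", "lon"), excl.astype(np.int8)),
        }
        | {f"mean_{k}": (("lat", "lon"), v) for k, v in means.items()},
    )
    ds.to_netcdf(out / "seasonality.nc", engine="scipy")
    _sidecar(out / "seasonality.nc", config)
    return {"seasonality": out / "seasonality.nc"}


def _stage_burden(config: RunConfig, out: Path) -> dict:
    fnr, dates = _load_risk(out, "burden")
    pop_path = Path(config.population_path or out / "population.csv")
    pop = pd.read_csv(_require(pop_path, "burden"), header=None).to_numpy(dtype=float)
    rows = []
    for year in sorted(set(dates.year)):
        sel = dates.year == year
        rows.append(
            {
                "year": int(year),
                "person_days": population_days_at_risk(
                    fnr[sel], pop, threshold=config.fnr_threshold
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "burden.csv", index=False)
    result = {"burden": out / "burden.csv"}
    if len(df) >= 3:
        fit = trend_regression(df["year"], df["person_days"])
        Path(out / "trend.json").write_text(
            json.dumps({"slope": fit.slope, "intercept": fit.intercept}, indent=1)
        )
        result["trend"] = out / "trend.json"
    _sidecar(out / "burden.csv", config)
    return result


def _stage_evaluate(config: RunConfig, out: Path) -> dict:
    feats = DerivedFeatureGrid.from_netcdf(_require(out / "features.nc", "evaluate"))
    model = TrainedModel.load(_require(out / "model.npz", "evaluate"))
    table = CalibrationTable.load(_require(out / "calibration.json", "evaluate"))
    records, df = _load_records(out, "evaluate")
    subset = dict(zip(df["id"], df["subset"]))
    test_recs = [r for r in records if subset[r.id] == "test"]
    seqs, kept = extract_sequences(test_recs, feats, config.seq_len)
    scores = predict_scores(model, sequences_to_matrix(seqs))
    fnr = np.asarray(score_to_fnr(table, scores))
    labels = np.array([r.label == PRESENCE for r in kept])
    curve = roc_auc(fnr, labels)
    payload = {
        "test_auc": curve.auc,
        "n_test": len(kept),
        "fpr": curve.fpr.tolist(),
        "tpr": curve.tpr.tolist(),
    }
    Path(out / "roc.json").write_text(json.dumps(payload, indent=1))
    _sidecar(out / "roc.json", config, {"test_auc": curve.auc})
    return {"roc": out / "roc.json", "test_auc": curve.auc}
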