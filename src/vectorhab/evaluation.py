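"""Evaluation harness: ROC/AUC, map agreement, and variable ablation.

``roc_auc`` sweeps the FNR (or score) threshold for positive labelling over
all unique values and integrates the sensitivity/1-specificity curve by the
trapezoid rule, which equals the Mann-Whitney pairwise concordance fraction
with ties counted one half. ``jaccard_binary_maps`` compares two
suitability rasters as the intersection-over-union of their
threshold-exceedance cell sets. ``leave_k_out_experiment`` retrains the
classifier with one or two climate variable groups removed, across sequence
lengths and split types, to rank variable importance by the drop in test
AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from .climate import extract_sequences
from .errors import AlignmentError, InvalidInputError
from .nn import ModelSpec, sequences_to_matrix, train, _rank_auc
from .sampling import PRESENCE, split_random, split_chronological

log = logging.getLogger(__name__)

#: The four ablatable climate variable groups; temperature covers both the
#: daily range and the daily mean layers.
VARIABLE_GROUPS = {
    "temperature": ("temp_range", "temp_mean"),
    "humidity": ("rel_humidity",),
    "precipitation": ("precip_total",),
    "wind": ("wind_speed",),
}

DEFAULT_SEQ_LENS = (30, 60, 90, 365)


@dataclass
class RocCurve:
    """Threshold-swept ROC curve with scalar AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class AblationResult:
    """Test AUC for one (variable subset, sequence length, split) cell."""

    left_out: tuple[str, ...]
    seq_len: int
    split: str
    auc: float


def roc_auc(values, labels) -> RocCurve:
    """ROC curve and AUC from risk values and binary labels.

    Thresholds sweep the unique values; a point is labelled positive when
    its value meets or exceeds the threshold. The trapezoidal AUC equals
    the exhaustive pairwise Mann-Whitney count with ties counted half.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    if values.size != labels.size:
        raise InvalidInputError("values and labels differ in length")
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("AUC undefined: both classes must be present")
    order = np.argsort(-values, kind="stable")
    v, y = values[order], labels[order]
    # cut after the last of each tied block of values
    distinct = np.r_[np.flatnonzero(np.diff(v) != 0), v.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=np.r_[np.inf, v[distinct]], auc=auc)


def jaccard_binary_maps(map_a, map_b, threshold, threshold_b=None) -> float:
    """Jaccard similarity of the cells exceeding a threshold in each map.

    Both empty exceedance sets count as identical (similarity 1; logged).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError(f"map grids differ: {a.shape} vs {b.shape}")
    tb = threshold if threshold_b is None else threshold_b
    in_a, in_b = a > threshold, b > tb
    union = (in_a | in_b).sum()
    if union == 0:
        log.info("jaccard: both exceedance sets empty; similarity defined as 1")
        return 1.0
    return float((in_a & in_b).sum() / union)


def jaccard_matrix(map_a, map_b, thresholds_a, thresholds_b=None) -> np.ndarray:
    """Jaccard similarity at every pair of per-map thresholds.

    Entry (i, j) compares map A at thresholds_a[i] with map B at
    thresholds_b[j].
    """
    thresholds_b = thresholds_a if thresholds_b is None else thresholds_b
    out = np.empty((len(thresholds_a), len(thresholds_b)))
    for i, ta in enumerate(thresholds_a):
        for j, tb in enumerate(thresholds_b):
            out[i, j] = jaccard_binary_maps(map_a, map_b, ta, threshold_b=tb)
    return out


def read_maxent_asc(path) -> tuple[np.ndarray, dict]:
    """Read a MaxEnt ASCII grid (.asc, 6-line header).

    Cumulative output (0-100) is rescaled to [0, 1]; nodata cells become
    NaN. Returns (raster, header dict).
    """
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    if np.nanmax(data) > 1.0:  # cumulative dialect reports 0-100
        data = data / 100.0
    return data, header


def stratified_holdout(y: np.ndarray, fraction: float, rng_seed: int) -> np.ndarray:
    """Seeded boolean mask holding out ``fraction`` of rows per class
    (at least one row of each class)."""
    y = np.asarray(y).astype(bool)
    rng = np.random.default_rng(rng_seed)
    mask = np.zeros(y.size, dtype=bool)
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        n_take = max(1, int(round(fraction * idx.size)))
        mask[rng.choice(idx, size=n_take, replace=False)] = True
    return mask


def ablation_subsets(groups=tuple(VARIABLE_GROUPS)) -> list[tuple[str, ...]]:
    """Full model plus all leave-one-out and leave-two-out subsets."""
    out: list[tuple[str, ...]] = [()]
    out += [(g,) for g in groups]
    out += [tuple(pair) for pair in combinations(groups, 2)]
    return out


def leave_k_out_experiment(
    records,
    features,
    seq_lens=DEFAULT_SEQ_LENS,
    splits=("random", "chronological"),
    spec_kwargs: dict | None = None,
    val_fraction: float = 0.1,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Train one model per (variable subset, seq_len, split) and record test AUC.

    Subsets are the full model, the four leave-one-out and the six
    leave-two-out combinations of the climate variable groups. Results are
    ordered by each subset's best AUC across sequence lengths, descending.
    """
    spec_kwargs = spec_kwargs or {}
    results: list[AblationResult] = []
    for split_name in splits:
        split_fn = split_random if split_name == "random" else split_chronological
        split = (
            split_fn(records, rng_seed=rng_seed)
            if split_name == "random"
            else split_fn(records)
        )
        test_ids = set(split.test_ids)
        for seq_len in seq_lens:
            for left_out in ablation_subsets():
                kept_vars = tuple(
                    v
                    for g, members in VARIABLE_GROUPS.items()
                    if g not in left_out
                    for v in members
                )
                seqs, kept = extract_sequences(records, features, seq_len, kept_vars)
                X = sequences_to_matrix(seqs)
                y = np.array([r.label == PRESENCE for r in kept], dtype=float)
                in_test = np.array([r.id in test_ids for r in kept])
                Xtr, ytr = X[~in_test], y[~in_test]
                Xte, yte = X[in_test], y[in_test]
                val = stratified_holdout(ytr, val_fraction, rng_seed)
                spec = ModelSpec(input_dim=X.shape[1], **spec_kwargs)
                model = train(
                    spec, Xtr[~val], ytr[~val], Xtr[val], ytr[val], rng_seed=rng_seed
                )
                auc = _rank_auc(model.predict_logits(Xte), yte.astype(bool))
                results.append(
                    AblationResult(
                        left_out=left_out, seq_len=seq_len, split=split_name, auc=auc
                    )
                )
                log.info(
                    "ablation split=%s seq_len=%d left_out=%s AUC=%.3f",
                    split_name,
                    seq_len,
                    left_out,
                    auc,
                )
    df = pd.DataFrame([asdict(r) for r in results])
    best = df.groupby(["split", "left_out"])["auc"].transform("max")
    return (
        df.assign(best_auc=best)
        .sort_values(["split", "best_auc", "left_out"], ascending=[True, False, True])
        .reset_index(drop=True)
    )
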