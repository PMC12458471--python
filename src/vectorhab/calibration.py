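"""False-negative-rate calibration of raw suitability scores.

Raw classifier scores depend on hyperparameters such as the
presence/pseudo-absence ratio, so maps built from different models are not
directly comparable. Calibration replaces each raw score with the false
negative rate (FNR) that would result from using that score as the decision
threshold against the empirical distribution of true-positive scores:
the score's midrank percentile among true-positive calibration scores.
An FNR of 0.5 marks a date-location more suitable than half of all
date-locations where the species was actually observed ("risk percentile").
The mapping is a monotone rank transform, so cell rankings are invariant to
any strictly increasing transformation of the raw scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError
from .nn import predict_scores


@dataclass
class CalibrationTable:
    """Sorted true-positive score distribution with provenance."""

    scores: np.ndarray
    provenance: str = "train"

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))

    def __len__(self) -> int:
        return self.scores.size

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"scores": self.scores.tolist(), "provenance": self.provenance}, fh
            )

    @classmethod
    def load(cls, path) -> "CalibrationTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(scores=np.asarray(d["scores"]), provenance=d["provenance"])


@dataclass
class RiskMap:
    """One day's FNR raster."""

    date: object
    lat_centers: np.ndarray
    lon_centers: np.ndarray
    fnr: np.ndarray

    def __post_init__(self) -> None:
        self.fnr = np.asarray(self.fnr, dtype=float)
        finite = self.fnr[np.isfinite(self.fnr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("FNR values must lie in [0, 1]")


def build_calibration(true_positive_scores, provenance: str = "train") -> CalibrationTable:
    """Build the calibration table from true-positive scores (>= 2 values).

    Duplicates are retained (multiset semantics); building twice from the
    same scores yields an identical table.
    """
    scores = np.asarray(true_positive_scores, dtype=float).ravel()
    if scores.size < 2:
        raise InsufficientDataError("need at least 2 true-positive scores")
    if not np.isfinite(scores).all():
        raise InvalidInputError("non-finite calibration scores")
    return CalibrationTable(scores=scores, provenance=provenance)


def score_to_fnr(table: CalibrationTable, score):
    """Midrank empirical CDF of the calibration table at ``score``.

    FNR = (count strictly below + 0.5 x count equal) / table size. The
    median of an odd-length distinct table maps to exactly 0.5; scores
    outside the table's range map to 0 or 1.
    """
    score = np.asarray(score, dtype=float)
    if not np.isfinite(score).all():
        raise InvalidInputError("non-finite score")
    below = np.searchsorted(table.scores, score, side="left")
    below_or_eq = np.searchsorted(table.scores, score, side="right")
    fnr = (below + 0.5 * (below_or_eq - below)) / len(table)
    return fnr if fnr.ndim else float(fnr)


def calibrate_map(model, table: CalibrationTable, features, date, seq_len=None) -> RiskMap:
    """Predict a full-grid FNR raster for one date.

    Extracts the model's feature sequence at every grid cell (ocean cells
    included — the land mask gates visualization, not calculation), scores
    it, and converts scores to FNR. Cell ranking equals raw-score ranking.
    """
    import pandas as pd

    seq_len = seq_len if seq_len is not None else model.seq_len
    if not seq_len or seq_len < 1:
        raise InvalidInputError("seq_len must be a positive day count")
    names = model.variable_names or features.variable_names
    date = pd.Timestamp(date)
    offset = (date - features.dates[0]).days
    if offset - seq_len < 0 or offset - 1 >= len(features.dates):
        raise InsufficientDataError(
            f"feature coverage does not span the {seq_len} days before {date.date()}"
        )
    rows = np.arange(offset - 1, offset - seq_len - 1, -1)
    # (seq_len, n_vars, nlat, nlon) -> (ncell, seq_len * n_vars)
    stack = np.stack([features.features[name][rows] for name in names], axis=1)
    nlat, nlon = stack.shape[-2:]
    X = stack.reshape(seq_len * len(names), nlat * nlon).T
    scores = predict_scores(model, X)
    fnr = np.asarray(score_to_fnr(table, scores)).reshape(nlat, nlon)
    return RiskMap(
        date=date,
        lat_centers=features.lat_centers,
        lon_centers=features.lon_centers,
        fnr=fnr,
    )
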