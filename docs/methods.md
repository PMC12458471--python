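# Methods

## Model and assumptions

`vectorhab` estimates the relative suitability of a date-location for a
mosquito species from climate alone. The statistical object is a binary
classifier trained on presences (occurrence records) against
pseudo-absences (synthetic negatives), so its output is *not* an absolute
occupancy probability: it ranks date-locations by how similar their recent
climate is to climates where the species was observed. All downstream
statistics are therefore built on ranks (FNR calibration) rather than raw
scores. The approach assumes that (i) the species' short-term climate
envelope — the preceding 30–365 days of temperature, humidity,
precipitation and wind — carries the habitat signal; (ii) observation
effort is informative about presence but absences can be proxied by
area-uniform random locations; and (iii) vector population size, pathogen
range, and human-driven land change are out of scope.

## Derived climate covariates

Five covariates per cell per day, from raw daily (or hourly-averaged)
rasters:

| covariate | formula | units |
|---|---|---|
| `temp_range` | T_max − T_min | °C |
| `temp_mean` | daily mean 2-m temperature | °C |
| `rel_humidity` | August–Roche–Magnus: 100·exp(17.625·T_d/(243.04+T_d))/exp(17.625·T_m/(243.04+T_m)) | % |
| `precip_total` | 24 × hourly-average precipitation | mm/day |
| `wind_speed` | √(u² + v²) | m/s |

Conventions: temperatures are converted from Kelvin on load when flagged;
longitudes are canonicalized to [−180, 180); grid coordinates are cell
centers with nearest-cell ties rounding to the lower index. Relative
humidity is deliberately *not* clipped at 100% — the conversion has no
clip, and supersaturated dew-point inputs are physically meaningful as
data artifacts worth seeing; an optional `clip` flag caps it. Surface
pressure may be carried as an extra input channel but feeds no derived
covariate. Ocean cells are included in every calculation (sequences,
maps); the land mask gates only pseudo-absence placement and
visualization. A record whose prior days are not fully covered is dropped
with a logged count, never zero-filled.

## Sampling

Pseudo-absence locations are drawn exactly area-uniformly on the sphere by
inverse-CDF sampling in sin(latitude) (density ∝ cos φ), restricted to the
grid's span, with uniform longitude and a date uniform over the presence
window. A draw is rejected when its nearest grid cell is ocean or is
occupied by any presence; rejection keys on the cell only, not the date.
The absence ratio 0.2 is interpreted as presences-per-absence, i.e.
`round(n_presence / 0.2)` absences (five per presence); it is a config
knob. Duplicate presences in one cell-date are retained.

Splits: the random split holds out 20% of presences plus an equal count of
random pseudo-absences. The chronological split holds out the most recent
20% of presences (boundary ties broken by record id) and pairs them with
absences dated inside the test span where available, topping up randomly —
the time-restriction of test absences is a choice the data cannot settle,
made to preserve temporal separation where possible. Cross-validation
folds are label-stratified (via scikit-learn's StratifiedKFold behind the
module surface).

## Classifier and training

A fully connected network: input seq_len × n_vars flattened, hidden
layers 128/64/32 with ReLU, one output logit. Optimization is Adam at
learning rate 10⁻³ on binary cross-entropy with logits; inputs are
z-scored with a scaler fitted on training rows only (population-sd
convention; zero-variance dimensions get sd 1 and a logged warning).
Early stopping monitors validation AUC — patience 10 epochs during
cross-validation, 100 for the final model — and restores the *best*
epoch's weights, not the last. The final model's early-stopping monitor is
a seeded stratified 10% holdout of the training pool. Batch size 256,
epoch cap 1000, seeded uniform (fan-in-scaled) initialization; all three
are config values since nothing in the problem pins them. Class imbalance
is handled by the data ratio alone — no loss reweighting. The
implementation is plain numpy, single-threaded, so a (seed, data) pair
reproduces weights bit-for-bit; the seed is stored in the checkpoint
metadata.

## FNR calibration

The calibration table is the multiset of suitability scores of
*training-set* true positives (train/test/both selectable — the choice is
not derivable from first principles; training positives avoid touching the
test set). A query score maps to its midrank empirical percentile:
(count below + ½·count equal) / n. Midrank is the single tie rule for
which the median of any odd-length distinct table maps to exactly 0.5.
No interpolation between table entries: the mapping's purpose is ranking,
which a step function preserves; two maps built from any strictly
increasing rescaling of the same scores are identical.

## Seasonality statistics

All seasonal statistics run on 365-entry day-of-year series (Feb 29
dropped before averaging — fixed-length series keep the circular
arithmetic simple and the bias is negligible; day 1 = Jan 1, 1-based).
Seasons are meteorological: MAM, JJA, SON, DJF (wrapping the year; day
counts 92/92/91/90). Transitions are successive cyclic differences of
seasonal means, so they telescope to zero.

The season window search is **circular** by default: it is the only
definition invariant to calendar origin, and a wrap-around (Dec–Jan)
season is physically real in the Southern hemisphere. A `circular=False`
mode restricts windows to a single calendar year. Ties between
equal-length windows break to the earliest start day. The midpoint is the
first day at which the running cumulative sum *from the window's start
day* reaches half the series total. Because of the earliest-start
tie-break the midpoint of an exactly symmetric peak can land one day past
the peak; the definition is kept because it is deterministic and matches
the "roughly 50% before and after" reading. Cells whose midpoint falls
within 10 days (circular distance) of Jan 1 are flagged by the exclusion
mask — such midpoints are artifacts of negligible cumulative mass. Mass
threshold (0.95) and exclusion window (10 days) are config parameters.

Transition anomalies default to differences of absolute transition
magnitudes (|current| − |historical|): negative = homogenization, positive
= diversification. A `signed=True` flag switches to raw signed
differences.

## Burden accounting

Person-days at risk = Σ_cells,days population × 1(FNR ≥ threshold), with
the inclusive inequality and threshold default 0.5. Population rasters are
downsampled to the risk grid by mass-conserving block sums (persons, not
density interpolation — person-days must conserve total population).
Census anchors are piecewise-linearly interpolated; extrapolation is
refused. Year length is 365 days, consistent with the seasonal
statistics. Trends are OLS fits of burden against year (statsmodels behind
the module surface) with the standard t-based 90% prediction interval for
a new observation. The shipped region rectangles (Americas, Western
Europe, SE Asia) are deliberately crude bounding boxes, documented as
approximations; real analyses should supply polygon masks.

## Evaluation harness

ROC curves sweep the positive-labelling threshold over all unique values;
the trapezoidal AUC equals the Mann–Whitney pairwise concordance with ties
counted one half (asserted against an O(n²) oracle in the tests). Map
agreement is the Jaccard similarity of threshold-exceedance cell sets,
with both-empty defined as 1 (identical emptiness, logged when
triggered); a MaxEnt ASCII-grid import (6-line header, cumulative 0–100
output divided by 100) lets externally produced suitability rasters be
compared on the same footing. The ablation experiment retrains over the
full model, four leave-one-out and six leave-two-out subsets of the four
climate variable groups — temperature (range + mean), humidity,
precipitation, wind — crossed with sequence lengths {30, 60, 90, 365} and
both split types, and reports test AUC sorted by each subset's best AUC.

## Synthetic world

The generator emulates the qualitative structure the pipeline's statistics
assume, not climatological realism: a latitudinal temperature gradient
(0.55 °C/deg from a 28 °C equatorial base), sinusoidal seasonality
(amplitude 10 °C) peaking ~Jul 1 in the North and 182 days later in the
South, iid daily noise (sd 2 °C), dew point a stochastic depression below
the mean temperature, gamma precipitation and Gaussian wind components.
Habitability is a known logistic in the derived covariates,
logit(h) = −7.2 + 0.25·T_mean + 0.03·RH + 0.02·P + (−0.05)·W, chosen to be
temperature-dominated with a wide dynamic range of h across the grid.
Presences are drawn ∝ habitability over eligible cell-dates; population is
a seeded gamma field. The reference world is 20×40 cells × 730 days with
2000 presences at absence ratio 0.2 and seq_len 30 — small enough that the
full end-to-end recovery check runs in well under a minute on one CPU.

What passing the recovery tests shows: the pipeline can learn a smooth,
stationary, noiseless-in-truth logistic habitability from its own feature
set. What it does not show: robustness to observation effort bias, spatial
autocorrelation of errors, non-stationary climate drift, or misspecified
covariates — all properties of real occurrence data the generator omits.

## Numerical choices and degenerate inputs

* Window search tolerance: a window qualifies at ≥ mass·total − 1e-12·total,
  guarding against accumulated floating-point error in cumulative sums.
* All-zero daily series have no season: an explicit undefined-season error,
  mapped to exclusion at pipeline level.
* t_max < t_min, non-finite inputs, single-class validation sets, < 2
  calibration scores, < 3 regression years, and patience 0 all raise typed
  errors rather than propagating silently.
* Determinism: every stochastic step takes an explicit seed; pipeline
  stages derive per-stage seeds as fixed offsets from the run seed and
  record them in artifact sidecars.

## Known limitations

Raster I/O uses plain float32 TIFF (no CRS tags; grid axes ride in JSON
sidecars) and NetCDF3; outputs are grids of numbers, not cartography.
The FNR calibration is a rank transform, not a Platt/isotonic probability
calibration, and carries no uncertainty intervals. Burden estimates count
exposure to suitable climate, not infections.
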