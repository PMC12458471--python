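"""Observation loading, pseudo-absence geometry, splits and folds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vectorhab as vh
from vectorhab.errors import ConfigurationError, EmptyInputError, SamplingError
from vectorhab.sampling import (
    PRESENCE,
    PSEUDO_ABSENCE,
    ObservationRecord,
    presence_cells,
)


def _toy_csv(tmp_path, rows):
    df = pd.DataFrame(
        rows, columns=["latitude", "longitude", "observed_on", "scientific_name"]
    )
    path = tmp_path / "obs.csv"
    df.to_csv(path, index=False)
    return path


class TestLoadObservations:
    def test_all_valid_rows_loaded(self, tmp_path):
        path = _toy_csv(
            tmp_path,
            [
                (10.0, 20.0, "2020-05-01", "Aedes aegypti"),
                (11.0, 21.0, "2020-06-01", "Aedes aegypti"),
                (12.0, 22.0, "2020-07-01", "Aedes aegypti"),
            ],
        )
        recs = vh.load_observations(path, species="Aedes aegypti")
        assert len(recs) == 3
        assert all(r.label == PRESENCE for r in recs)

    def test_invalid_rows_dropped(self, tmp_path):
        path = _toy_csv(
            tmp_path,
            [
                (95.0, 20.0, "2020-05-01", "Aedes aegypti"),  # latitude out of range
                (11.0, 21.0, "not-a-date", "Aedes aegypti"),  # unparseable date
                (12.0, 22.0, "2020-07-01", "Aedes aegypti"),
            ],
        )
        assert len(vh.load_observations(path, species="Aedes aegypti")) == 1

    def test_window_filter_and_empty_error(self, tmp_path):
        path = _toy_csv(tmp_path, [(10.0, 20.0, "2020-05-01", "Aedes aegypti")])
        recs = vh.load_observations(
            path, species="Aedes aegypti", window=("2020-01-01", "2020-12-31")
        )
        assert len(recs) == 1
        with pytest.raises(EmptyInputError):
            vh.load_observations(
                path, species="Aedes aegypti", window=("2021-01-01", "2021-12-31")
            )


def _all_land_grid(n_lat=45, n_lon=90):
    """A coarse global all-land grid."""
    step_lat, step_lon = 180.0 / n_lat, 360.0 / n_lon
    lat = np.linspace(90 - step_lat / 2, -90 + step_lat / 2, n_lat)
    lon = np.linspace(-180 + step_lon / 2, 180 - step_lon / 2, n_lon)

    class G:
        lat_centers = lat
        lon_centers = lon
        land_mask = np.ones((n_lat, n_lon), dtype=bool)

    return G()


def _presences(n=5, seed=0):
    rng = np.random.default_rng(seed)
    return [
        ObservationRecord(
            id=f"p{i}",
            species="t",
            latitude=float(rng.uniform(-50, 50)),
            longitude=float(rng.uniform(-170, 170)),
            date=pd.Timestamp("2020-06-01") + pd.Timedelta(days=int(rng.integers(0, 100))),
        )
        for i in range(n)
    ]


class TestPseudoAbsences:
    def test_zero_requested_gives_empty_list(self):
        assert vh.generate_pseudo_absences(_presences(), _all_land_grid(), 0, 0) == []

    def test_area_proportional_latitudes(self):
        """On an all-land sphere, |lat| < 30 deg should hold half the draws."""
        grid = _all_land_grid()
        draws = vh.generate_pseudo_absences(_presences(), grid, 5000, rng_seed=1)
        frac = np.mean([abs(r.latitude) < 30 for r in draws])
        assert frac == pytest.approx(0.5, abs=0.03)  # sin(30 deg) = 0.5

    def test_no_collision_with_presence_cells(self):
        grid = _all_land_grid()
        pres = _presences(20, seed=3)
        occupied = presence_cells(pres, grid)
        draws = vh.generate_pseudo_absences(pres, grid, 500, rng_seed=2)
        for rec in draws:
            assert vh.nearest_grid_cell(rec.latitude, rec.longitude, grid) not in occupied

    def test_dates_within_presence_window(self):
        pres = _presences(10, seed=4)
        lo = min(r.date for r in pres)
        hi = max(r.date for r in pres)
        draws = vh.generate_pseudo_absences(pres, _all_land_grid(), 200, rng_seed=5)
        assert all(lo <= r.date <= hi for r in draws)
        assert all(r.label == PSEUDO_ABSENCE for r in draws)

    def test_same_seed_bit_identical(self):
        pres = _presences(10, seed=6)
        a = vh.generate_pseudo_absences(pres, _all_land_grid(), 50, rng_seed=9)
        b = vh.generate_pseudo_absences(pres, _all_land_grid(), 50, rng_seed=9)
        assert [(r.latitude, r.longitude, r.date) for r in a] == [
            (r.latitude, r.longitude, r.date) for r in b
        ]

    def test_exhaustion_error_when_all_cells_occupied(self):
        grid = _all_land_grid(3, 3)
        pres = [
            ObservationRecord(
                id=f"p{i}{j}",
                species="t",
                latitude=float(grid.lat_centers[i]),
                longitude=float(grid.lon_centers[j]),
                date=pd.Timestamp("2020-06-01"),
            )
            for i in range(3)
            for j in range(3)
        ]
        with pytest.raises(SamplingError):
            vh.generate_pseudo_absences(pres, grid, 5, rng_seed=0)

    def test_cosine_latitude_density_chi_square(self):
        """Latitude histogram of 50,000 draws fits a cos(lat) density."""
        grid = _all_land_grid()
        draws = vh.generate_pseudo_absences(_presences(1), grid, 50_000, rng_seed=13)
        lats = np.array([r.latitude for r in draws])
        edges = np.linspace(-90, 90, 19)
        observed, _ = np.histogram(lats, bins=edges)
        expected = np.diff(np.sin(np.radians(edges))) / 2.0 * lats.size
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=observed.size - 1)
        assert p > 0.01


class TestCountAbsences:
    @pytest.mark.parametrize("n, ratio, expected", [(100, 0.2, 500), (100, 1.0, 100), (0, 0.2, 0)])
    def test_presences_per_absence_interpretation(self, n, ratio, expected):
        assert vh.count_absences(n, ratio) == expected

    def test_invalid_ratio(self):
        with pytest.raises(ConfigurationError):
            vh.count_absences(10, 0.0)


def _labeled_records(n_pres=100, n_abs=500, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_pres):
        recs.append(
            ObservationRecord(
                id=f"p{i}", species="t", latitude=0.0, longitude=0.0,
                date=pd.Timestamp("2020-01-01") + pd.Timedelta(days=int(rng.integers(0, 365))),
                label=PRESENCE,
            )
        )
    for i in range(n_abs):
        recs.append(
            ObservationRecord(
                id=f"a{i}", species="t", latitude=0.0, longitude=0.0,
                date=pd.Timestamp("2020-01-01") + pd.Timedelta(days=int(rng.integers(0, 365))),
                label=PSEUDO_ABSENCE,
            )
        )
    return recs


class TestSplits:
    def test_random_split_counts(self):
        recs = _labeled_records()
        split = vh.split_random(recs, 0.2, rng_seed=1)
        test = [r for r in recs if r.id in set(split.test_ids)]
        assert sum(r.label == PRESENCE for r in test) == 20
        assert sum(r.label == PSEUDO_ABSENCE for r in test) == 20
        assert len(split.train_ids) == 560

    def test_random_split_partitions_and_is_deterministic(self):
        recs = _labeled_records()
        a = vh.split_random(recs, 0.2, rng_seed=5)
        b = vh.split_random(recs, 0.2, rng_seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert set(a.train_ids) | set(a.test_ids) == {r.id for r in recs}
        assert set(a.train_ids) & set(a.test_ids) == set()

    def test_chronological_split_orders_presences(self):
        recs = _labeled_records(n_pres=10, n_abs=50, seed=2)
        split = vh.split_chronological(recs, 0.2)
        by_id = {r.id: r for r in recs}
        test_pres = [by_id[i] for i in split.test_ids if by_id[i].label == PRESENCE]
        train_pres = [by_id[i] for i in split.train_ids if by_id[i].label == PRESENCE]
        assert len(test_pres) == 2
        assert max(r.date for r in train_pres) <= min(r.date for r in test_pres)

    def test_chronological_boundary_tie_broken_by_id(self):
        recs = [
            ObservationRecord(
                id=f"p{i}", species="t", latitude=0.0, longitude=0.0,
                date=pd.Timestamp("2020-06-01"), label=PRESENCE,
            )
            for i in range(5)
        ] + _labeled_records(n_pres=0, n_abs=10)
        split = vh.split_chronological(recs, 0.2)
        test_pres = [i for i in split.test_ids if i.startswith("p")]
        assert test_pres == ["p4"]  # highest id wins the all-tied boundary

    def test_insufficient_absences_raise(self):
        recs = _labeled_records(n_pres=100, n_abs=10)
        with pytest.raises(SamplingError):
            vh.split_random(recs, 0.2, rng_seed=0)


class TestKfold:
    def test_fold_sizes_and_determinism(self):
        recs = _labeled_records(n_pres=10, n_abs=0)
        folds = vh.kfold(recs, k=5, rng_seed=3)
        sizes = [sum(1 for f in folds.values() if f == k) for k in range(1, 6)]
        assert sizes == [2] * 5
        assert folds == vh.kfold(recs, k=5, rng_seed=3)

    def test_stratification_within_one(self):
        recs = _labeled_records(n_pres=20, n_abs=100)
        folds = vh.kfold(recs, k=5, rng_seed=4)
        by_id = {r.id: r for r in recs}
        for k in range(1, 6):
            n_pres = sum(
                by_id[i].label == PRESENCE for i, f in folds.items() if f == k
            )
            assert abs(n_pres - 4) <= 1

    def test_k_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            vh.kfold(_labeled_records(10, 0), k=1)
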