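"""Climate feature derivation: scalar formulas, grids, sequence extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vectorhab as vh
from vectorhab.climate import ClimateGrid, normalize_longitude
from vectorhab.errors import (
    ConfigurationError,
    DataIntegrityError,
    IncompleteSequenceError,
    InvalidInputError,
    OutOfDomainError,
)
from vectorhab.sampling import ObservationRecord


class TestScalarFormulas:
    def test_saturated_air_gives_100_percent(self):
        assert vh.relative_humidity(15.0, 15.0) == pytest.approx(100.0, rel=1e-12)

    @given(st.floats(-50, 50))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_rh_identity_over_temperature_range(self, t):
        assert vh.relative_humidity(t, t) == pytest.approx(100.0, rel=1e-9)

    def test_rh_magnus_value(self):
        # direct evaluation of the Magnus constants 17.625 / 243.04
        expected = 100.0 * np.exp(17.625 * 10 / 253.04) / np.exp(17.625 * 20 / 263.04)
        assert vh.relative_humidity(10.0, 20.0) == pytest.approx(expected, rel=1e-12)
        assert vh.relative_humidity(10.0, 20.0) == pytest.approx(52.5, abs=0.1)

    def test_supersaturation_not_clipped_by_default(self):
        assert vh.relative_humidity(20.0, 10.0) > 100.0
        assert vh.relative_humidity(20.0, 10.0, clip=True) == 100.0

    def test_rh_strictly_increasing_in_dewpoint(self):
        t_dew = np.linspace(-30, 29, 100)
        rh = np.array([vh.relative_humidity(td, 30.0) for td in t_dew])
        assert np.all(np.diff(rh) > 0)

    def test_rh_rejects_nonfinite(self):
        with pytest.raises(InvalidInputError):
            vh.relative_humidity(np.nan, 10.0)

    @pytest.mark.parametrize("hourly, expected", [(1.0, 24.0), (0.0, 0.0), (0.5, 12.0)])
    def test_daily_precip_is_24x_hourly_average(self, hourly, expected):
        assert vh.daily_precip_total(hourly) == expected

    def test_negative_precip_rejected(self):
        with pytest.raises(InvalidInputError):
            vh.daily_precip_total(-0.1)

    @pytest.mark.parametrize("u, v, expected", [(3, 4, 5), (0, 0, 0), (-3, 4, 5)])
    def test_wind_speed_euclidean_and_sign_invariant(self, u, v, expected):
        assert vh.wind_speed(u, v) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "tmax, tmin, expected", [(30, 20, 10), (20, 20, 0), (-5, -15, 10)]
    )
    def test_temp_range(self, tmax, tmin, expected):
        assert vh.temp_range(tmax, tmin) == expected

    def test_inverted_temperatures_raise_integrity_error(self):
        with pytest.raises(DataIntegrityError):
            vh.temp_range(10.0, 20.0)


def _one_cell_grid():
    return ClimateGrid(
        lat_centers=np.array([0.0]),
        lon_centers=np.array([0.0]),
        dates=pd.date_range("2020-01-01", periods=1),
        variables={
            "t2m_max": np.full((1, 1, 1), 30.0),
            "t2m_min": np.full((1, 1, 1), 20.0),
            "t2m_mean": np.full((1, 1, 1), 25.0),
            "dewpoint": np.full((1, 1, 1), 25.0),
            "precip_hourly_avg": np.full((1, 1, 1), 1.0),
            "wind_u": np.zeros((1, 1, 1)),
            "wind_v": np.zeros((1, 1, 1)),
        },
    )


class TestDeriveDailyFeatures:
    def test_single_cell_composition(self):
        feats = vh.derive_daily_features(_one_cell_grid())
        got = {k: float(v[0, 0, 0]) for k, v in feats.features.items()}
        assert got["temp_range"] == 10.0
        assert got["temp_mean"] == 25.0
        assert got["rel_humidity"] == pytest.approx(100.0)
        assert got["precip_total"] == 24.0
        assert got["wind_speed"] == 0.0

    def test_missing_layer_names_the_absent_variable(self):
        grid = _one_cell_grid()
        del grid.variables["dewpoint"]
        with pytest.raises(ConfigurationError, match="dewpoint"):
            vh.derive_daily_features(grid)

    def test_vectorized_path_matches_scalar_loop(self, tiny_world):
        """Cellwise oracle: loop the scalar formulas over every cell/day."""
        feats = tiny_world.features
        v = tiny_world.grid.variables
        n_days, nlat, nlon = tiny_world.grid.shape
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = int(rng.integers(n_days))
            i = int(rng.integers(nlat))
            j = int(rng.integers(nlon))
            assert feats.features["temp_range"][d, i, j] == pytest.approx(
                vh.temp_range(v["t2m_max"][d, i, j], v["t2m_min"][d, i, j]), rel=1e-9
            )
            assert feats.features["rel_humidity"][d, i, j] == pytest.approx(
                vh.relative_humidity(v["dewpoint"][d, i, j], v["t2m_mean"][d, i, j]),
                rel=1e-9,
            )
            assert feats.features["precip_total"][d, i, j] == pytest.approx(
                vh.daily_precip_total(v["precip_hourly_avg"][d, i, j]), rel=1e-9
            )
            assert feats.features["wind_speed"][d, i, j] == pytest.approx(
                vh.wind_speed(v["wind_u"][d, i, j], v["wind_v"][d, i, j]), rel=1e-9
            )

    def test_temperature_ordering_enforced_on_load(self):
        grid = _one_cell_grid()
        with pytest.raises(DataIntegrityError):
            ClimateGrid(
                lat_centers=grid.lat_centers,
                lon_centers=grid.lon_centers,
                dates=grid.dates,
                variables={**grid.variables, "t2m_min": np.full((1, 1, 1), 40.0)},
            )


class TestNearestGridCell:
    @staticmethod
    def _grid(lats, lons):
        class G:
            lat_centers = np.asarray(lats, dtype=float)
            lon_centers = np.asarray(lons, dtype=float)

        return G()

    def test_quarter_degree_rounding(self):
        g = self._grid(np.arange(-1.0, 1.01, 0.25), np.arange(-1.0, 1.01, 0.25))
        i, j = vh.nearest_grid_cell(0.1, 0.1, g)
        assert (g.lat_centers[i], g.lon_centers[j]) == (0.0, 0.0)

    def test_exact_midpoint_ties_to_lower_index(self):
        g = self._grid(np.arange(-1.0, 1.01, 0.25), np.arange(-1.0, 1.01, 0.25))
        i, j = vh.nearest_grid_cell(0.125, 0.0, g)
        assert g.lat_centers[i] == 0.0

    def test_out_of_domain_raises(self):
        g = self._grid([0.0, 0.25], [0.0, 0.25])
        with pytest.raises(OutOfDomainError):
            vh.nearest_grid_cell(45.0, 0.0, g)

    def test_matches_exhaustive_search(self):
        """Brute-force oracle over all centers, 100 random points."""
        rng = np.random.default_rng(12)
        lats = np.linspace(-45, 45, 10)
        lons = np.linspace(-90, 90, 10)
        g = self._grid(lats, lons)
        for _ in range(100):
            lat = float(rng.uniform(-45, 45))
            lon = float(rng.uniform(-90, 90))
            i, j = vh.nearest_grid_cell(lat, lon, g)
            assert i == int(np.argmin(np.abs(lats - lat)))
            assert j == int(np.argmin(np.abs(lons - lon)))

    def test_longitude_normalization(self):
        assert normalize_longitude(270.0) == -90.0
        assert normalize_longitude(-180.0) == -180.0
        assert normalize_longitude(180.0) == -180.0


class TestExtractSequence:
    @staticmethod
    def _record(world, day_index, i=2, j=3):
        return ObservationRecord(
            id="r0",
            species="test",
            latitude=float(world.grid.lat_centers[i]),
            longitude=float(world.grid.lon_centers[j]),
            date=world.grid.dates[day_index],
        )

    def test_shape_contract(self, tiny_world, tiny_features):
        seq = vh.extract_sequence(self._record(tiny_world, 40), tiny_features, 30)
        assert seq.matrix.shape == (30, 5)

    def test_first_day_record_has_no_prior_data(self, tiny_world, tiny_features):
        with pytest.raises(IncompleteSequenceError):
            vh.extract_sequence(self._record(tiny_world, 0), tiny_features, 5)

    def test_rows_match_direct_raster_lookup(self, tiny_world, tiny_features):
        """Row k equals the derived raster at the cell on day (date - k - 1)."""
        seq = vh.extract_sequence(self._record(tiny_world, 50, 1, 4), tiny_features, 10)
        for k in range(10):
            for c, name in enumerate(tiny_features.variable_names):
                assert seq.matrix[k, c] == tiny_features.features[name][50 - k - 1, 1, 4]

    def test_time_translation_invariance(self, tiny_world):
        """Shifting the climate series and the record date together leaves
        the extracted matrix unchanged."""
        feats = tiny_world.features
        shifted = vh.DerivedFeatureGrid(
            lat_centers=feats.lat_centers,
            lon_centers=feats.lon_centers,
            dates=feats.dates + pd.Timedelta(days=17),
            features=feats.features,
        )
        rec_a = self._record(tiny_world, 60)
        rec_b = ObservationRecord(
            id="r1",
            species="test",
            latitude=rec_a.latitude,
            longitude=rec_a.longitude,
            date=rec_a.date + pd.Timedelta(days=17),
        )
        a = vh.extract_sequence(rec_a, feats, 20)
        b = vh.extract_sequence(rec_b, shifted, 20)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_pipeline_extraction_drops_incomplete_records(self, tiny_world, tiny_features):
        records = [self._record(tiny_world, 0), self._record(tiny_world, 50)]
        seqs, kept = vh.extract_sequences(records, tiny_features, 10)
        assert len(seqs) == len(kept) == 1


class TestNetcdfRoundTrip:
    def test_derived_features_roundtrip(self, tiny_features, tmp_path):
        path = tmp_path / "feat.nc"
        tiny_features.to_netcdf(path)
        back = vh.DerivedFeatureGrid.from_netcdf(path)
        assert set(back.variable_names) == set(tiny_features.variable_names)
        np.testing.assert_allclose(
            back.features["temp_mean"], tiny_features.features["temp_mean"]
        )

    def test_kelvin_and_0_360_longitude_conversion(self, tmp_path):
        import xarray as xr

        lon = np.array([0.0, 90.0, 180.0, 270.0])
        ds = xr.Dataset(
            {"t2m_mean": (("time", "lat", "lon"), np.full((1, 2, 4), 300.0))},
            coords={
                "time": pd.date_range("2020-01-01", periods=1),
                "lat": [10.0, 0.0],
                "lon": lon,
            },
        )
        path = tmp_path / "raw.nc"
        ds.to_netcdf(path, engine="scipy")
        grid = vh.climate.load_climate_netcdf(path, kelvin=True)
        assert grid.lon_centers.min() >= -180 and grid.lon_centers.max() < 180
        assert np.all(np.diff(grid.lon_centers) > 0)
        assert grid.variables["t2m_mean"][0, 0, 0] == pytest.approx(300.0 - 273.15)
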