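import numpy as np
import pytest

from ozcra.geo_io import GridSpec, StationRecord, haversine_km, haversine_matrix
from ozcra.interpolation import (
    EmpiricalVariogram,
    IDWParams,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    idw_predict,
    kriging_predict,
    kriging_weights,
    predict_grid,
    weighted_sse,
)
from ozcra.synthetic import FieldSpec, sample_stations, simulate_field


def station(i, lon, lat, conc):
    return StationRecord(f"S{i}", lon, lat, conc)


class TestIDW:
    def test_single_station_returns_its_value(self):
        s = [station(0, 100.0, 15.0, 77.7)]
        assert idw_predict(s, (103.0, 12.0)) == 77.7

    def test_exact_at_coincident_target(self):
        s = [station(0, 100.0, 15.0, 58.94), station(1, 101.0, 16.0, 120.0)]
        assert idw_predict(s, (100.0, 15.0)) == 58.94

    def test_equidistant_pair_averages(self):
        s = [station(0, 100.0, 15.0, 100.0), station(1, 102.0, 15.0, 120.0)]
        assert idw_predict(s, (101.0, 15.0)) == pytest.approx(110.0, abs=1e-6)

    def test_matches_direct_formula(self, five_stations):
        target = (100.3, 14.6)
        p = 2.0
        # independent one-liner evaluation of the weighted mean
        d = np.array([haversine_km((s.lon, s.lat), target) for s in five_stations])
        z = np.array([s.conc for s in five_stations])
        expected = np.sum(z * d**-p) / np.sum(d**-p)
        assert idw_predict(five_stations, target, IDWParams(power=p)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_bounded_by_data_range(self, five_stations):
        vals = [s.conc for s in five_stations]
        rng = np.random.default_rng(7)
        for _ in range(20):
            target = (float(rng.uniform(97, 103)), float(rng.uniform(12, 18)))
            z = idw_predict(five_stations, target)
            assert min(vals) - 1e-9 <= z <= max(vals) + 1e-9

    def test_empty_station_list_rejected(self):
        with pytest.raises(ValueError):
            idw_predict([], (0.0, 0.0))


class TestEmpiricalVariogram:
    def test_two_station_single_pair(self):
        # gamma = (14-10)^2 / 2 = 8 for the only pair
        a = station(0, 100.0, 15.0, 10.0)
        b_lat = 15.0 + 50.0 / 111.195  # ~50 km north
        b = station(1, 100.0, b_lat, 14.0)
        emp = empirical_variogram([a, b])
        assert len(emp.bin_centers) == 1
        assert emp.semivariance[0] == pytest.approx(8.0)
        assert emp.pair_counts[0] == 1

    def test_constant_field_gives_zero_everywhere(self, five_stations):
        const = [StationRecord(s.station_id, s.lon, s.lat, 50.0) for s in five_stations]
        emp = empirical_variogram(const)
        assert np.all(emp.semivariance == 0.0)

    def test_tracks_generating_model(self):
        # one GRF draw: empirical semivariance should follow the model curve
        model = VariogramModel("exponential", nugget=0.0, partial_sill=100.0, range_km=400.0)
        spec = GridSpec(lon0=98.0, lat0=6.0, cell_size=0.5, n_lon=14, n_lat=14)
        grid, _ = simulate_field(FieldSpec(model, mean_ppb=100.0, seed=11, spec=spec))
        stations = sample_stations(grid, n=120, noise_sd=0.0, seed=3)
        emp = empirical_variogram(stations, n_bins=8)
        expected = model.gamma(emp.bin_centers)
        # generous binwise Monte-Carlo band: one realisation is noisy
        assert np.all(np.abs(emp.semivariance - expected) < 0.8 * model.sill)
        # and the short-lag structure is genuinely smaller than the long-lag one
        assert emp.semivariance[0] < emp.semivariance[-2:].mean()


class TestFitVariogram:
    @pytest.mark.parametrize("family", ["spherical", "exponential", "gaussian"])
    def test_recovers_noise_free_curve_within_1pct(self, family):
        truth = VariogramModel(family, nugget=5.0, partial_sill=95.0, range_km=350.0)
        h = np.linspace(10, 800, 25)
        emp = EmpiricalVariogram(h, truth.gamma(h), np.full(len(h), 100.0))
        fit = fit_variogram(emp, family)
        assert fit.nugget == pytest.approx(truth.nugget, rel=0.01, abs=0.05)
        assert fit.partial_sill == pytest.approx(truth.partial_sill, rel=0.01)
        assert fit.range_km == pytest.approx(truth.range_km, rel=0.01)

    def test_too_few_bins_instructs_fallback(self):
        emp = EmpiricalVariogram([10.0, 20.0], [5.0, 8.0], [4, 4])
        with pytest.raises(ValueError, match="IDW"):
            fit_variogram(emp)

    def test_all_zero_semivariance_not_fittable(self):
        emp = EmpiricalVariogram([10.0, 20.0, 30.0], [0.0, 0.0, 0.0], [4, 4, 4])
        with pytest.raises(ValueError, match="nugget"):
            fit_variogram(emp)

    def test_correct_family_wins_weighted_sse(self):
        truth = VariogramModel("exponential", nugget=0.0, partial_sill=100.0, range_km=300.0)
        h = np.linspace(10, 700, 20)
        emp = EmpiricalVariogram(h, truth.gamma(h), np.full(len(h), 50.0))
        sse_exp = weighted_sse(emp, fit_variogram(emp, "exponential"))
        sse_sph = weighted_sse(emp, fit_variogram(emp, "spherical"))
        assert sse_exp < sse_sph


class TestKriging:
    @pytest.fixture
    def model(self):
        return VariogramModel("spherical", nugget=0.0, partial_sill=150.0, range_km=400.0)

    def test_exact_at_station_with_zero_nugget(self, model):
        s = [station(0, 100.0, 15.0, 90.0), station(1, 101.5, 15.5, 110.0)]
        pred, var = kriging_predict(s, (100.0, 15.0), model)
        assert pred == 90.0
        assert var == 0.0

    def test_weights_sum_to_one(self, five_stations, model):
        rng = np.random.default_rng(3)
        for _ in range(10):
            target = (float(rng.uniform(97, 103)), float(rng.uniform(12, 18)))
            w, _ = kriging_weights(five_stations, target, model)
            assert w.sum() == pytest.approx(1.0, abs=1e-8)

    def test_matches_dense_solve_oracle(self, model):
        # explicit matrix-inversion solve of the ordinary-kriging system
        s = [
            station(0, 100.0, 15.0, 80.0),
            station(1, 101.0, 16.0, 95.0),
            station(2, 99.5, 14.2, 105.0),
            station(3, 102.0, 14.8, 88.0),
        ]
        target = (100.7, 15.1)
        n = len(s)
        lons = [st_.lon for st_ in s]
        lats = [st_.lat for st_ in s]
        gmat = model.gamma(haversine_matrix(lons, lats, lons, lats))
        a = np.ones((n + 1, n + 1))
        a[:n, :n] = gmat
        a[n, n] = 0.0
        b = np.ones(n + 1)
        b[:n] = model.gamma(
            np.array([haversine_km((lo, la), target) for lo, la in zip(lons, lats)])
        )
        w = np.linalg.inv(a) @ b
        expected = float(w[:n] @ np.array([st_.conc for st_ in s]))
        pred, var = kriging_predict(s, target, model)
        assert pred == pytest.approx(expected, rel=1e-10)
        assert var >= 0.0

    def test_duplicate_locations_named_in_error(self, model):
        s = [station(0, 100.0, 15.0, 80.0), station(1, 100.0, 15.0, 95.0),
             station(2, 101.0, 16.0, 90.0)]
        with pytest.raises(ValueError, match="S0.*S1"):
            kriging_predict(s, (100.5, 15.5), model)


class TestPredictGrid:
    def test_single_cell_single_station(self):
        spec = GridSpec(lon0=100.0, lat0=15.0, cell_size=0.1, n_lon=1, n_lat=1)
        grid, summary = predict_grid([station(0, 101.0, 14.0, 88.0)], spec, method="idw")
        assert grid.values[0, 0] == 88.0
        assert summary["mean"] == 88.0

    def test_idw_mean_around_single_station(self, small_spec):
        grid, summary = predict_grid([station(0, 100.0, 15.0, 73.0)], small_spec, method="idw")
        assert summary["mean"] == pytest.approx(73.0)
        assert summary["sd"] == 0.0

    def test_kriging_grid_matches_pointwise_predictor(self, five_stations, small_spec):
        model = VariogramModel("spherical", nugget=2.0, partial_sill=150.0, range_km=400.0)
        grid, _ = predict_grid(five_stations, small_spec, method="kriging", variogram=model)
        r, c = 2, 3
        target = small_spec.cell_center(r, c)
        pred, _ = kriging_predict(five_stations, target, model)
        assert grid.values[r, c] == pytest.approx(pred, rel=1e-10)

    def test_mask_respected(self, five_stations, small_spec):
        mask = np.zeros(small_spec.shape, bool)
        mask[1, 1] = True
        grid, summary = predict_grid(five_stations, small_spec, mask=mask, method="idw")
        assert summary["n_cells"] == 1
        assert np.isnan(grid.values[0, 0])

    def test_kriging_beats_idw_on_synthetic_fields(self, recovery_study):
        mean_k = np.mean(recovery_study["grid_rmse"]["kriging"])
        mean_i = np.mean(recovery_study["grid_rmse"]["idw"])
        assert mean_k < mean_i
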