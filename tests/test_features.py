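import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pm_gridsense.features import (IDWConfig, KDAConfig, _deg_to_km,
                                   _discretize_lines, _plane, checkin_feature,
                                   idw_interpolate, idw_values,
                                   pm_spatial_feature,
                                   pm_spatial_loo_at_stations,
                                   pm_temporal_at_stations,
                                   pm_temporal_feature, poi_buffer_counts,
                                   road_density, traffic_kernel_density)
from pm_gridsense.grid import GridSpec


def brute_idw(src_xy, vals, tgt, power=2.0, eps_km=1e-6 * 110.574):
    """Independent loop-based IDW oracle (same plane metric)."""
    num = den = 0.0
    for (x, y), v in zip(src_xy, vals):
        d = ((tgt[0] - x) ** 2 + (tgt[1] - y) ** 2) ** 0.5
        if d <= eps_km:
            return v
        w = 1.0 / max(d, eps_km) ** power
        num += w * v
        den += w
    return num / den


class TestIDW:
    def test_single_point_fills_grid(self, tiny_grid):
        pts = pd.DataFrame({"lon": [114.05], "lat": [30.04], "value": [50.0]})
        out = idw_interpolate(pts, tiny_grid)
        assert np.allclose(out.values, 50.0)

    def test_symmetric_pair_midpoint(self):
        out, ok = idw_values([[0, 0], [2, 0]], [10.0, 30.0], [[1.0, 0.0]],
                             IDWConfig())
        assert ok[0] and out[0] == pytest.approx(20.0)

    def test_power_two_hand_value(self):
        # weights 1/0.25 and 1/2.25 -> (40 + 13.33)/(4 + 0.444) = 12.0
        out, _ = idw_values([[0, 0], [2, 0]], [10.0, 30.0], [[0.5, 0.0]],
                            IDWConfig(power=2))
        assert out[0] == pytest.approx(12.0)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        cfg = IDWConfig()
        for _ in range(25):
            n = rng.integers(2, 8)
            src = rng.random((n, 2)) * 10
            vals = rng.normal(50, 10, n)
            tgt = rng.random((3, 2)) * 10
            got, _ = idw_values(src, vals, tgt, cfg)
            want = [brute_idw(src, vals, t) for t in tgt]
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-10)

    def test_empty_points_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            idw_interpolate(pd.DataFrame({"lon": [], "lat": [], "value": []}),
                            tiny_grid)

    def test_search_radius_masks_unreached_cells(self):
        grid = GridSpec(0.0, 0.0, 10, 1, 0.01)
        pts = pd.DataFrame({"lon": [0.005], "lat": [0.005], "value": [9.0]})
        out = idw_interpolate(pts, grid, IDWConfig(search_radius=0.02))
        assert out.mask[0, 0] and not out.mask[0, 9]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(1, 6), st.integers(0, 2**31 - 1))
    def test_bounded_by_input_range_and_exact_at_sources(self, n, seed):
        r = np.random.default_rng(seed)
        src = r.random((n, 2))
        vals = r.normal(0, 5, n)
        tgts = np.vstack([r.random((5, 2)), src])
        out, ok = idw_values(src, vals, tgts, IDWConfig())
        assert ok.all()
        assert (out >= vals.min() - 1e-12).all()
        assert (out <= vals.max() + 1e-12).all()
        np.testing.assert_allclose(out[5:], vals, atol=1e-12)


class TestSpatialPMFeature:
    def test_exact_at_the_only_station(self, tiny_grid):
        obs = pd.DataFrame({"station_id": ["A"], "lon": [114.035],
                            "lat": [30.025], "pm25": [42.0]})
        out = pm_spatial_feature(obs, tiny_grid)
        r, c = tiny_grid.cell_of(114.035, 30.025)
        assert out.values[r, c] == pytest.approx(42.0, abs=1e-9)

    def test_leave_one_out_equidistant_pair(self, tiny_grid):
        # the two remaining stations are equidistant from the target's
        # cell center (114.055, 30.045)
        obs = pd.DataFrame({
            "station_id": ["T", "L", "R"],
            "lon": [114.055, 114.035, 114.075],
            "lat": [30.045, 30.045, 30.045],
            "pm25": [99.0, 40.0, 60.0],
        })
        out = pm_spatial_feature(obs, tiny_grid, exclude_station="T")
        r, c = tiny_grid.cell_of(114.055, 30.045)
        assert out.values[r, c] == pytest.approx(50.0)

    def test_all_excluded_rejected(self, tiny_grid):
        obs = pd.DataFrame({"station_id": ["A"], "lon": [114.03],
                            "lat": [30.03], "pm25": [10.0]})
        with pytest.raises(ValueError):
            pm_spatial_feature(obs, tiny_grid, exclude_station="A")

    def test_loo_matrix_matches_per_station_brute_force(self, tiny_grid, rng):
        n_st, n_h = 5, 4
        stations = pd.DataFrame({
            "station_id": [f"S{i}" for i in range(n_st)],
            "lon": 114.0 + rng.random(n_st) * 0.09,
            "lat": 30.0 + rng.random(n_st) * 0.07,
        })
        obs = rng.normal(50, 10, (n_h, n_st))
        got = pm_spatial_loo_at_stations(stations, obs, tiny_grid)
        kx, ky = tiny_grid.km_per_degree()
        xy = np.column_stack([stations["lon"] * kx, stations["lat"] * ky])
        for h in range(n_h):
            for i in range(n_st):
                others = [j for j in range(n_st) if j != i]
                want = brute_idw(xy[others], obs[h, others], xy[i])
                assert got[h, i] == pytest.approx(want, abs=1e-10)


class TestTemporalPMFeature:
    def _obs(self, value):
        return pd.DataFrame({"station_id": ["A"], "lon": [114.05],
                             "lat": [30.04], "pm25": [value]})

    def test_hand_computed_lag_weighting(self, tiny_grid):
        hist = {1: self._obs(60.0), 2: self._obs(50.0), 3: self._obs(40.0)}
        out = pm_temporal_feature(hist, tiny_grid)
        want = (60 + 50 * 0.5 + 40 / 3) / (1 + 0.5 + 1 / 3)
        assert np.allclose(out.values, want)
        assert want == pytest.approx(53.636363, abs=1e-4)

    def test_identical_lags_passthrough(self, tiny_grid):
        hist = {lag: self._obs(47.5) for lag in (1, 2, 3)}
        out = pm_temporal_feature(hist, tiny_grid)
        assert np.allclose(out.values, 47.5)

    def test_single_available_lag_renormalizes(self, tiny_grid):
        hist = {1: self._obs(60.0), 2: self._obs(np.nan), 3: self._obs(np.nan)}
        out = pm_temporal_feature(hist, tiny_grid)
        assert np.allclose(out.values, 60.0)

    def test_no_data_yields_masked_field(self, tiny_grid):
        with pytest.warns(UserWarning):
            out = pm_temporal_feature({1: self._obs(np.nan)}, tiny_grid)
        assert not out.mask.any()

    def test_station_matrix_uses_own_past_observation(self, tiny_grid):
        stations = pd.DataFrame({"station_id": ["A", "B"],
                                 "lon": [114.02, 114.08],
                                 "lat": [30.02, 30.06]})
        obs = np.array([[10.0, 20.0], [30.0, 40.0], [50.0, 60.0],
                        [70.0, 80.0]])
        out = pm_temporal_at_stations(stations, obs, tiny_grid)
        assert np.isnan(out[0]).all()  # no history at the first hour
        # exact IDW hit at the station's own location dominates each lag
        want = (50 + 30 * 0.5 + 10 / 3) / (1 + 0.5 + 1 / 3)
        assert out[3, 0] == pytest.approx(want, rel=1e-6)


class TestCheckinFeature:
    def test_single_snapshot_count_lands_in_cell(self, tiny_grid):
        snap = pd.DataFrame({"lon": [114.015], "lat": [30.015], "count": [7.0]})
        out = checkin_feature([snap], tiny_grid)
        r, c = tiny_grid.cell_of(114.015, 30.015)
        assert out.values[r, c] == pytest.approx(7.0)

    def test_two_snapshots_average(self, tiny_grid):
        mk = lambda n: pd.DataFrame({"lon": [114.015], "lat": [30.015],
                                     "count": [n]})
        out = checkin_feature([mk(4.0), mk(6.0)], tiny_grid)
        r, c = tiny_grid.cell_of(114.015, 30.015)
        assert out.values[r, c] == pytest.approx(5.0)

    def test_gap_fill_between_equal_cells(self, tiny_grid):
        snap = pd.DataFrame({"lon": [114.015, 114.035], "lat": [30.015] * 2,
                             "count": [8.0, 8.0]})
        out = checkin_feature([snap], tiny_grid)
        r, c = tiny_grid.cell_of(114.025, 30.015)  # empty cell in between
        assert out.values[r, c] == pytest.approx(8.0)
        assert (out.values >= 0).all()

    def test_zero_snapshots_all_masked(self, tiny_grid):
        with pytest.warns(UserWarning):
            out = checkin_feature([], tiny_grid)
        assert not out.mask.any()


def brute_kda(lines_with_index, grid, cfg):
    """Loop-based kernel-density oracle using the same discretization."""
    h = _deg_to_km(cfg.bandwidth)
    step = _deg_to_km(cfg.segment_step)
    lon, lat = grid.center_mesh()
    cx, cy = _plane(lon.ravel(), lat.ravel(), grid)
    out = np.zeros(grid.n_cells)
    geoms = [c for c, _ in lines_with_index]
    weights = [w for _, w in lines_with_index]
    mids, lens, idx = _discretize_lines(geoms, grid, step)
    for (mx, my), ln, li in zip(mids, lens, idx):
        for k in range(grid.n_cells):
            d = ((cx[k] - mx) ** 2 + (cy[k] - my) ** 2) ** 0.5
            if d < h:
                out[k] += weights[li] * ln * (3 / np.pi) * (1 - (d / h) ** 2) ** 2 / h**2
    return out.reshape(grid.n_rows, grid.n_cols)


class TestTrafficKernelDensity:
    def test_empty_line_set_is_zero_field(self, tiny_grid):
        out = traffic_kernel_density([], tiny_grid)
        assert np.array_equal(out.values, np.zeros((8, 10)))
        assert out.mask.all()

    def test_matches_brute_force_oracle(self, rng):
        grid = GridSpec(0.0, 0.0, 12, 10, 0.01)
        cfg = KDAConfig(bandwidth=0.02)
        for _ in range(3):
            lines = []
            for i in range(3):
                pts = np.column_stack([rng.uniform(0.02, 0.1, 3),
                                       rng.uniform(0.02, 0.08, 3)])
                lines.append((pts, float(rng.integers(1, 7))))
            got = traffic_kernel_density(lines, grid, cfg)
            want = brute_kda(lines, grid, cfg)
            np.testing.assert_allclose(got.values, want, atol=1e-10)

    def test_mass_conservation_away_from_edges(self):
        grid = GridSpec(0.0, 0.0, 40, 40, 0.01)
        # a line well inside the domain (> bandwidth from every edge)
        coords = np.array([[0.1, 0.2], [0.3, 0.21], [0.28, 0.1]])
        lines = [(coords, 4.0)]
        cfg = KDAConfig(bandwidth=0.01)
        out = traffic_kernel_density(lines, grid, cfg)
        mids, lens, _ = _discretize_lines([coords], grid,
                                          _deg_to_km(cfg.segment_step))
        mass_in = 4.0 * lens.sum()
        mass_out = out.values.sum() * grid.cell_area_km2()
        assert mass_out == pytest.approx(mass_in, rel=0.02)

    def test_linearity_in_index(self, tiny_grid):
        coords = np.array([[114.02, 30.02], [114.06, 30.05]])
        one = traffic_kernel_density([(coords, 2.0)], tiny_grid)
        two = traffic_kernel_density([(coords, 4.0)], tiny_grid)
        np.testing.assert_allclose(two.values, 2 * one.values, atol=1e-12)

    def test_translation_equivariance(self):
        # same-latitude shift, so the local km-per-degree metric is unchanged
        cfg = KDAConfig(bandwidth=0.02)
        g1 = GridSpec(0.0, 0.0, 12, 10, 0.01)
        g2 = GridSpec(0.05, 0.0, 12, 10, 0.01)
        coords = np.array([[0.03, 0.02], [0.07, 0.06]])
        shifted = coords + np.array([0.05, 0.0])
        a = traffic_kernel_density([(coords, 3.0)], g1, cfg)
        b = traffic_kernel_density([(shifted, 3.0)], g2, cfg)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)


class TestRoadDensity:
    def test_empty_road_set(self, tiny_grid):
        out = road_density([], tiny_grid)
        assert np.array_equal(out.values, np.zeros((8, 10)))

    def test_segment_inside_one_cell_length_over_area(self, tiny_grid):
        kx, ky = tiny_grid.km_per_degree()
        # a 0.004-degree-long north-south segment inside one cell
        coords = np.array([[114.035, 30.032], [114.035, 30.036]])
        out = road_density([(coords, "main")], tiny_grid)
        r, c = tiny_grid.cell_of(114.035, 30.034)
        want = (0.004 * ky) / tiny_grid.cell_area_km2()
        assert out.values[r, c] == pytest.approx(want, rel=1e-9)

    def test_partition_additivity_across_cells(self, tiny_grid):
        kx, ky = tiny_grid.km_per_degree()
        coords = np.array([[114.012, 30.015], [114.078, 30.062]])
        out = road_density([(coords, "highway")], tiny_grid)
        seg_km = np.hypot((114.078 - 114.012) * kx, (30.062 - 30.015) * ky)
        total = out.values.sum() * tiny_grid.cell_area_km2()
        assert total == pytest.approx(seg_km, rel=1e-9)

    def test_level_filter(self, tiny_grid):
        coords = np.array([[114.02, 30.02], [114.03, 30.02]])
        out = road_density([(coords, "branch")], tiny_grid, levels=("highway",))
        assert out.values.sum() == 0.0


class TestPoiBufferCounts:
    def test_no_pois_zero_fields(self, tiny_grid):
        empty = pd.DataFrame({"lon": [], "lat": [], "poi_class": []})
        out = poi_buffer_counts(empty, tiny_grid)
        assert out["PS"].values.sum() == 0 and out["SCEN"].values.sum() == 0

    def test_single_ps_poi_classing(self, tiny_grid):
        pois = pd.DataFrame({"lon": [114.035], "lat": [30.035],
                             "poi_class": ["PS"]})
        out = poi_buffer_counts(pois, tiny_grid, radius_km=2.0)
        r, c = tiny_grid.cell_of(114.035, 30.035)
        assert out["PS"].values[r, c] >= 1
        assert out["SCEN"].values[r, c] == 0

    def test_unknown_class_rejected_with_label(self, tiny_grid):
        pois = pd.DataFrame({"lon": [114.03], "lat": [30.03],
                             "poi_class": ["factory"]})
        with pytest.raises(ValueError, match="factory"):
            poi_buffer_counts(pois, tiny_grid)

    def test_matches_double_loop_oracle(self, tiny_grid, rng):
        n = 30
        pois = pd.DataFrame({
            "lon": 114.0 + rng.random(n) * 0.1,
            "lat": 30.0 + rng.random(n) * 0.08,
            "poi_class": rng.choice(["PS", "Scen", "other"], n),
        })
        radius = 1.3
        out = poi_buffer_counts(pois, tiny_grid, radius_km=radius)
        kx, ky = tiny_grid.km_per_degree()
        lon, lat = tiny_grid.center_mesh()
        for cls, key in (("PS", "PS"), ("Scen", "SCEN")):
            sub = pois[pois["poi_class"] == cls]
            for r in range(tiny_grid.n_rows):
                for c in range(tiny_grid.n_cols):
                    cnt = sum(
                        np.hypot((lon[r, c] - p.lon) * kx,
                                 (lat[r, c] - p.lat) * ky) <= radius
                        for p in sub.itertuples())
                    assert out[key].values[r, c] == cnt
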