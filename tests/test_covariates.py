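"""Terrain, current and temporal covariates."""

import numpy as np
import pandas as pd
import pytest

from shorewatch.covariates import (CurrentSnapshot, EnvironmentBundle,
                                   TideTable, decompose_current,
                                   interpolate_current, mean_stratification,
                                   neighborhood_sd, sample_covariates,
                                   spatial_sd_speed, stratification_regime,
                                   temporal_covariates, terrain_aspect,
                                   terrain_slope, tidal_stratification)
from shorewatch.raster import RasterGrid, read_ascii_grid, write_ascii_grid
from shorewatch.synthetic import SyntheticScenario, make_tide_table


def grid_from(values, cell=50.0, x0=0.0, y0=0.0):
    return RasterGrid(x0, y0, cell, np.asarray(values, dtype=float))


def plane_grid(slope_per_m_east=0.0, slope_per_m_north=0.0, n=9, cell=10.0):
    """Depth plane h = gx*east + gy*north (row 0 = north)."""
    g = grid_from(np.zeros((n, n)), cell=cell)
    gx, gy = g.center_mesh()
    return g.copy_with(slope_per_m_east * gx + slope_per_m_north * gy + 100.0)


class TestTerrain:
    def test_flat_grid_zero_slope(self):
        s = terrain_slope(grid_from(np.full((5, 5), 20.0)))
        inner = s.values[1:-1, 1:-1]
        assert np.allclose(inner, 0.0)
        assert np.isnan(s.values[0, 0])  # border is nodata

    def test_analytic_plane_slope(self):
        # 1 m depth change per 10 m horizontally -> atan(0.1) = 5.71 deg
        s = terrain_slope(plane_grid(slope_per_m_east=0.1, cell=10.0))
        assert np.nanmax(np.abs(s.values[1:-1, 1:-1] - 5.710593)) < 0.01

    def test_hand_computed_horn_window(self):
        # 3x3 window, cell 10 m:  a b c / d e f / g h i
        z = np.array([[1.0, 2.0, 3.0],
                      [4.0, 5.0, 6.0],
                      [7.0, 8.0, 9.0]])
        # Horn: dz/dx = ((c+2f+i)-(a+2d+g))/(8*10) = ((3+12+9)-(1+8+7))/80
        # = 8/80 = 0.1 ; dz/dy(north) = ((a+2b+c)-(g+2h+i))/80 = (8-32)/80
        # = -0.3 ; slope = atan(sqrt(0.01+0.09)) = 17.548 deg
        s = terrain_slope(grid_from(z, cell=10.0))
        assert s.values[1, 1] == pytest.approx(17.5484, abs=1e-3)

    @pytest.mark.parametrize("ge, gn, expected", [
        (0.0, 0.1, 0.0),     # deepening northwards -> downslope faces north
        (0.1, 0.0, 90.0),    # deepening eastwards -> faces east
    ])
    def test_aspect_axis_aligned(self, ge, gn, expected):
        a = terrain_aspect(plane_grid(ge, gn))
        inner = a.values[1:-1, 1:-1]
        assert np.allclose(inner, expected, atol=1e-6)

    def test_aspect_oblique_plane(self):
        az = np.radians(37.0)
        a = terrain_aspect(plane_grid(0.1 * np.sin(az), 0.1 * np.cos(az)))
        assert np.nanmax(np.abs(a.values[1:-1, 1:-1] - 37.0)) < 0.5

    def test_flat_cells_flagged(self):
        a = terrain_aspect(grid_from(np.full((5, 5), 10.0)))
        assert np.isnan(a.values[2, 2])

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(10, 40, (8, 8))
        g1 = grid_from(z, x0=0.0, y0=0.0)
        g2 = grid_from(z, x0=12345.0, y0=-999.0)
        for op in (terrain_slope, terrain_aspect,
                   lambda g: neighborhood_sd(g, 5)):
            np.testing.assert_array_equal(op(g1).values, op(g2).values)


class TestNeighborhoodSD:
    def test_constant_grid_zero(self):
        sd = neighborhood_sd(grid_from(np.full((5, 5), 7.0)), 5)
        assert np.allclose(sd.values[1:-1, 1:-1][:, :-1], 0.0)

    def test_hand_computed_stencil(self):
        # centre 10; k=5 neighbours in order N,E,S,W,NE = 2,4,6,8,10
        z = np.array([[0.0, 2.0, 10.0],
                      [8.0, 10.0, 4.0],
                      [0.0, 6.0, 0.0]])
        sd = neighborhood_sd(grid_from(z), 5)
        expected = np.std([10, 2, 4, 6, 8, 10], ddof=1)
        assert sd.values[1, 1] == pytest.approx(expected)

    def test_scale_homogeneity(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 30, (6, 6))
        sd1 = neighborhood_sd(grid_from(z), 5).values
        sd2 = neighborhood_sd(grid_from(-2.5 * z), 5).values
        np.testing.assert_allclose(sd2, 2.5 * sd1)

    def test_incomplete_stencil_is_nodata(self):
        sd = neighborhood_sd(grid_from(np.full((4, 4), 1.0)), 5)
        assert np.isnan(sd.values[0, :]).all()      # no northern neighbour
        assert np.isnan(sd.values[:, -1]).all()     # NE neighbour missing


class TestCurrents:
    @pytest.mark.parametrize("speed, direction, exp", [
        (1.0, 0.0, (0.0, 1.0)),
        (2.0, 90.0, (2.0, 0.0)),
        (3.0, 225.0, (-2.121, -2.121)),
    ])
    def test_decompose(self, speed, direction, exp):
        u, v = decompose_current(speed, direction)
        assert u == pytest.approx(exp[0], abs=1e-3)
        assert v == pytest.approx(exp[1], abs=1e-3)

    def test_decompose_recompose_round_trip(self):
        rng = np.random.default_rng(2)
        speed = rng.uniform(0.01, 3.0, 200)
        direction = rng.uniform(0, 360, 200)
        u, v = decompose_current(speed, direction)
        np.testing.assert_allclose(np.hypot(u, v), speed, atol=1e-9)
        back = np.degrees(np.arctan2(u, v)) % 360
        np.testing.assert_allclose(back, direction, atol=1e-9)

    def test_spatial_sd_pythagoras(self):
        # u alternates +-3 east, v alternates +-4 north around zero mean:
        # the 3-4-5 construction
        u = grid_from(3.0 * (-1.0) ** np.add.outer(np.arange(5), np.arange(5)))
        v = grid_from(4.0 * (-1.0) ** np.add.outer(np.arange(5), np.arange(5)))
        sd = spatial_sd_speed(u, v, k_neighbors=5)
        sdu = neighborhood_sd(u, 5).values
        sdv = neighborhood_sd(v, 5).values
        np.testing.assert_allclose(sd.values, np.hypot(sdu, sdv))
        valid = np.isfinite(sd.values)
        assert (sd.values[valid] >= np.maximum(sdu, sdv)[valid] - 1e-12).all()

    def test_uniform_flow_zero_sd(self):
        u = grid_from(np.full((5, 5), 1.2))
        v = grid_from(np.full((5, 5), -0.4))
        sd = spatial_sd_speed(u, v)
        assert np.allclose(sd.values[np.isfinite(sd.values)], 0.0)


class TestStratification:
    def test_arithmetic(self):
        assert tidal_stratification(10, 1) == pytest.approx(1.0)
        assert tidal_stratification(50, 0.5) == pytest.approx(2.602, abs=1e-3)

    def test_floor_engaged_at_slack(self):
        assert tidal_stratification(10, 0.0, floor_U=0.01) == pytest.approx(7.0)

    def test_monotone_in_depth_and_current(self):
        assert tidal_stratification(20, 1) > tidal_stratification(10, 1)
        assert tidal_stratification(10, 2) < tidal_stratification(10, 1)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            tidal_stratification(-5, 1)

    @pytest.mark.parametrize("value, regime", [
        (1.0, "mixed"), (2.29, "mixed"), (2.5, "switching"),
        (2.75, "frontal_boundary"), (3.0, "stratified"),
        (3.5, "stratified"), (4.0, "strongly_stratified"),
    ])
    def test_regime_bins(self, value, regime):
        assert stratification_regime(value) == regime

    def test_regime_monotone(self):
        order = ["mixed", "switching", "frontal_boundary", "stratified",
                 "strongly_stratified"]
        vals = [stratification_regime(v) for v in np.linspace(0.5, 4.5, 200)]
        assert [order.index(v) for v in vals] == sorted(
            order.index(v) for v in vals)

    def test_mean_stratification_two_snapshots(self):
        h = grid_from(np.full((4, 4), 40.0), cell=300.0)
        mk = lambda s: CurrentSnapshot(
            0.0 if s == 1 else 3.0,
            grid_from(np.full((4, 4), float(s)), cell=300.0),
            grid_from(np.zeros((4, 4)), cell=300.0))
        m = mean_stratification(h, [mk(1), mk(3)])
        # Ubar = 2 -> log10(40/8) = log10(5)
        inner = m.values[1:-1, 1:-1]
        assert np.allclose(inner, np.log10(5.0), atol=1e-9)

    def test_constant_current_degenerates_to_pointwise(self):
        h = grid_from(np.full((4, 4), 30.0), cell=300.0)
        snap = lambda t: CurrentSnapshot(
            t, grid_from(np.full((4, 4), 1.5), cell=300.0),
            grid_from(np.zeros((4, 4)), cell=300.0))
        m = mean_stratification(h, [snap(-3.0), snap(3.0)])
        assert m.values[1, 1] == pytest.approx(tidal_stratification(30, 1.5))


@pytest.fixture(scope="module")
def tide():
    return make_tide_table(SyntheticScenario(seed=0, days=32))


class TestTemporal:

    def test_hw_instant_is_zero(self, tide):
        tc = temporal_covariates(tide.hw_times[10], tide)
        assert tc.tidal_state == pytest.approx(0.0, abs=1e-9)

    def test_three_hours_after_hw(self, tide):
        t = tide.hw_times[10] + pd.Timedelta(hours=3)
        assert temporal_covariates(t, tide).tidal_state == pytest.approx(3.0)

    def test_neap_noon_is_zero_lunar(self, tide):
        tc = temporal_covariates(tide.neap_dates[0], tide)
        assert abs(tc.lunar_cycle) < 0.6

    def test_three_days_after_neap(self, tide):
        t = tide.neap_dates[0] + pd.Timedelta(days=3)
        assert temporal_covariates(t, tide).lunar_cycle == pytest.approx(
            3.0, abs=0.6)

    def test_periodicity(self, tide):
        t = tide.hw_times[5] + pd.Timedelta(hours=2)
        a = temporal_covariates(t, tide)
        b = temporal_covariates(t + pd.Timedelta(hours=12.42), tide)
        assert abs(a.tidal_state - b.tidal_state) < 1.0 / 60.0
        c = temporal_covariates(t + pd.Timedelta(days=14.77), tide)
        assert abs(a.lunar_cycle - c.lunar_cycle) < 0.05

    def test_out_of_span_rejected(self, tide):
        with pytest.raises(ValueError):
            temporal_covariates(tide.hw_times[0] - pd.Timedelta(days=30), tide)


class TestInterpolateCurrent:
    def _snaps(self):
        mk = lambda t, val: CurrentSnapshot(
            t, grid_from(np.full((3, 3), val), cell=300.0),
            grid_from(np.zeros((3, 3)), cell=300.0))
        return [mk(-1.0, 0.0), mk(0.0, 1.0)]

    def test_exact_snapshot(self):
        u, _ = interpolate_current(self._snaps(), -1.0)
        assert np.allclose(u.values, 0.0)

    def test_midpoint(self):
        u, _ = interpolate_current(self._snaps(), -0.5)
        assert np.allclose(u.values, 0.5)

    def test_quarter_point(self):
        u, _ = interpolate_current(self._snaps(), -0.25)
        assert np.allclose(u.values, 0.75)

    def test_outside_range_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            u, _ = interpolate_current(self._snaps(), 5.0)
        assert np.allclose(u.values, 1.0)


class TestSampling:
    def test_full_vector_on_constructed_scene(self, small_study):
        """Field-by-field check of the sampled vector against the grids."""
        env = small_study["env"]
        scans = small_study["scans"]
        t = scans["start_time"].iloc[100]
        x, y = 2000.0, -1500.0
        cov = sample_covariates((x, y), t, env)
        assert cov.depth == pytest.approx(env.depth.sample_bilinear(x, y))
        assert cov.slope == pytest.approx(env.slope.sample_bilinear(x, y))
        assert cov.mean_stratification == pytest.approx(
            env.mean_strat.sample_bilinear(x, y))
        # stratification recomputes from sampled depth and interpolated speed
        assert cov.tidal_stratification == pytest.approx(
            np.log10(cov.depth / max(cov.current_speed, env.floor_U) ** 3))
        assert cov.valid

    def test_bilinear_midpoint(self):
        g = grid_from(np.array([[10.0, 30.0], [10.0, 30.0]]), cell=100.0)
        assert g.sample_bilinear(100.0, 100.0) == pytest.approx(20.0)
        assert g.sample_bilinear(50.0, 100.0) == pytest.approx(10.0)

    def test_nodata_point_flagged(self, small_study):
        env = small_study["env"]
        t = small_study["scans"]["start_time"].iloc[0]
        cov = sample_covariates((0.0, 0.0), t, env)  # island centre
        assert not cov.valid


class TestAsciiGrid:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        vals = rng.uniform(5, 50, (7, 9))
        vals[0, 0] = np.nan
        g = RasterGrid(-1000.0, 2000.0, 50.0, vals)
        path = tmp_path / "depth.asc"
        write_ascii_grid(g, path, fmt="%.8g")
        back = read_ascii_grid(path)
        assert back.congruent(g)
        np.testing.assert_allclose(back.values, g.values, rtol=1e-6)
        header = path.read_text().splitlines()[:6]
        assert header[0].startswith("ncols") and header[5].startswith("NODATA")
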