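"""Kernel utilisation distributions and percent-volume contours."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from shorewatch.kde import (WeightedPointSet, balance_effort,
                            core_area_percentage, kde_surface, scv_bandwidth,
                            scv_criterion, surface_correlation,
                            volume_contours, weight_overlap_sightings)
from shorewatch.raster import RasterGrid


def pointset(points, weights=None):
    points = np.asarray(points, dtype=float)
    w = np.ones(len(points)) if weights is None else np.asarray(weights)
    return WeightedPointSet(points, w)


class TestBalanceEffort:
    def _scans(self, n_per=30):
        rows = []
        times = pd.date_range("2004-08-01 08:00", periods=n_per, freq="10min")
        for sector in "ABCD":
            for i, t in enumerate(times):
                rows.append({"id": f"{sector}{i}", "sector": sector,
                             "start_time": t})
        return pd.DataFrame(rows)

    def test_exact_counts_per_sector(self):
        scans = self._scans()
        sightings = pd.DataFrame({"scan_id": ["A0", "B3", "C5"]})
        sub, _ = balance_effort(scans, sightings, n_per_sector=20, seed=1)
        assert sub.groupby("sector").size().eq(20).all()

    def test_identity_when_already_balanced(self):
        scans = self._scans(n_per=15)
        sub, _ = balance_effort(scans, pd.DataFrame({"scan_id": []}),
                                n_per_sector=15, seed=9)
        assert sorted(sub["id"]) == sorted(scans["id"])

    def test_seeds_differ_but_counts_match(self):
        scans = self._scans()
        s1, _ = balance_effort(scans, pd.DataFrame({"scan_id": []}), 20, seed=1)
        s2, _ = balance_effort(scans, pd.DataFrame({"scan_id": []}), 20, seed=2)
        assert set(s1["id"]) != set(s2["id"])
        assert s1.groupby("sector").size().eq(20).all()
        s1b, _ = balance_effort(scans, pd.DataFrame({"scan_id": []}), 20, seed=1)
        assert s1["id"].tolist() == s1b["id"].tolist()

    def test_insufficient_coverage_names_sector(self):
        scans = self._scans(n_per=10)
        with pytest.raises(ValueError, match="'A'"):
            balance_effort(scans, pd.DataFrame({"scan_id": []}), 20, seed=1)


class TestOverlapWeights:
    def test_enumerated_scene(self):
        from shapely.geometry import box
        sectors = {"L": box(0, 0, 10, 10), "R": box(5, 0, 15, 10)}
        pts = [(2, 5), (3, 5), (12, 5), (13, 5), (7, 5), (8, 5)]
        ws, orphan = weight_overlap_sightings(pts, sectors)
        np.testing.assert_array_equal(ws.weights, [1, 1, 1, 1, 0.5, 0.5])
        assert not orphan.any()

    def test_point_outside_all_sectors_flagged(self):
        from shapely.geometry import box
        ws, orphan = weight_overlap_sightings([(50, 50)], {"A": box(0, 0, 1, 1)})
        assert orphan[0] and ws.weights[0] == 1.0


class TestSCV:
    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 100, (40, 2))
        h1, _ = scv_bandwidth(pointset(pts))
        h2, _ = scv_bandwidth(pointset(pts + [5000.0, -3000.0]))
        np.testing.assert_allclose(h1, h2, rtol=1e-6)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 50, (40, 2))
        h1, _ = scv_bandwidth(pointset(pts))
        h2, _ = scv_bandwidth(pointset(3.0 * pts))
        np.testing.assert_allclose(h2, 9.0 * h1, rtol=0.05)

    def test_matches_brute_force_grid_search(self):
        """n=8 points: the optimiser beats an exhaustive criterion grid.

        The oracle re-implements the SCV criterion with scipy's mvn pdf
        and scans diagonal-plus-correlation bandwidths.
        """
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1.0, (8, 2))
        ps = pointset(pts)
        w = np.ones(8) / 8.0
        S = np.cov(pts.T)
        G = S * (8.0) ** (-1.0 / 3.0)

        def oracle(H):
            var = 1.0 / (4 * np.pi * 8 * np.sqrt(np.linalg.det(H)))
            bias = 0.0
            for Sigma, sign in ((2 * H + 2 * G, 1), (H + 2 * G, -2),
                                (2 * G, 1)):
                pdf = multivariate_normal(mean=[0, 0], cov=Sigma).pdf
                for i in range(8):
                    for j in range(8):
                        bias += sign * w[i] * w[j] * pdf(pts[i] - pts[j])
            return var + bias

        h_opt, meta = scv_bandwidth(ps)
        assert meta["method"] == "normal_reference" or meta["converged"]
        best = np.inf
        for s1 in np.linspace(0.2, 1.5, 12):
            for s2 in np.linspace(0.2, 1.5, 12):
                for rho in (-0.4, 0.0, 0.4):
                    H = np.array([[s1 ** 2, rho * s1 * s2],
                                  [rho * s1 * s2, s2 ** 2]])
                    best = min(best, oracle(H))
        if meta["method"] == "scv":
            assert oracle(h_opt) <= best + 1e-6

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            scv_bandwidth(pointset([[0, 0]] * 12))


class TestSurface:
    def test_single_point_peak_closed_form(self):
        sigma = 200.0
        surf = kde_surface(pointset([[0.0, 0.0]]),
                           sigma ** 2 * np.eye(2), cell_size=10.0)
        peak = np.nanmax(surf.grid.values)
        assert peak == pytest.approx(1 / (2 * np.pi * sigma ** 2), rel=1e-3)

    def test_mass_conservation_and_symmetry(self):
        pts = [[-500.0, 0.0], [500.0, 0.0]]
        surf = kde_surface(pointset(pts), 150.0 ** 2 * np.eye(2),
                           cell_size=25.0)
        assert surf.mass() == pytest.approx(1.0, abs=0.01)
        v = surf.grid.values
        np.testing.assert_allclose(v, v[:, ::-1], atol=1e-12)

    def test_doubling_weights_leaves_surface_unchanged(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 300, (30, 2))
        H = 100.0 ** 2 * np.eye(2)
        s1 = kde_surface(pointset(pts), H, cell_size=50.0)
        s2 = kde_surface(pointset(pts, 2 * np.ones(30)), H,
                         grid=s1.grid)
        np.testing.assert_allclose(s1.grid.values, s2.grid.values, atol=1e-15)

    def test_small_grid_warns(self):
        tiny = RasterGrid(-100, -100, 50.0, np.zeros((4, 4)))
        with pytest.warns(UserWarning, match="kernel mass"):
            kde_surface(pointset([[0.0, 0.0]]), 500.0 ** 2 * np.eye(2),
                        grid=tiny)


class TestContours:
    def test_nesting(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 400, (100, 2))
        surf = kde_surface(pointset(pts), 150.0 ** 2 * np.eye(2),
                           cell_size=50.0)
        areas = {c.level: c.area_km2
                 for c in volume_contours(surf, trace_polygons=False)}
        assert areas[50] <= areas[60] <= areas[75] <= areas[95]

    def test_gaussian_half_volume_area(self):
        # 50% volume of an isotropic normal covers 2*pi*sigma^2*ln 2
        sigma = 1.0
        surf = kde_surface(pointset([[0.0, 0.0]]), sigma ** 2 * np.eye(2),
                           cell_size=0.04, margin_sigmas=5.0)
        c50 = volume_contours(surf, levels=[50], trace_polygons=False)[0]
        expected = 2 * np.pi * sigma ** 2 * np.log(2) / 1e6  # km^2
        assert c50.area_km2 == pytest.approx(expected, rel=0.03)

    def test_uniform_surface_proportional_area(self):
        g = RasterGrid(0, 0, 50.0, np.full((20, 20), 1.0 / (20 * 20 * 2500)))
        from shorewatch.kde import DensitySurface
        surf = DensitySurface(g, 1.0)
        for level in (50, 60, 75, 95):
            c = volume_contours(surf, levels=[level],
                                trace_polygons=False)[0]
            assert c.area_km2 == pytest.approx(level / 100 * 1.0, rel=0.02)

    def test_bad_level_rejected(self):
        g = RasterGrid(0, 0, 50.0, np.full((5, 5), 1.0))
        from shorewatch.kde import DensitySurface
        with pytest.raises(ValueError):
            volume_contours(DensitySurface(g, 1.0), levels=[120])

    def test_polygon_area_matches_mask(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 300, (50, 2))
        surf = kde_surface(pointset(pts), 120.0 ** 2 * np.eye(2),
                           cell_size=50.0)
        c = volume_contours(surf, levels=[50])[0]
        assert c.polygons.area / 1e6 == pytest.approx(c.area_km2, rel=1e-9)

    def test_fifty_percent_contour_covers_true_hpd(self):
        """2-component mixture, n=500: Jaccard with the true 50% HPD >= 0.7."""
        rng = np.random.default_rng(7)
        n = 500
        comp = rng.uniform(size=n) < 0.5
        pts = np.where(comp[:, None],
                       rng.normal([-800, 0], 250, (n, 2)),
                       rng.normal([800, 300], 250, (n, 2)))
        ps = pointset(pts)
        H, _ = scv_bandwidth(ps)
        surf = kde_surface(ps, H, cell_size=50.0)
        c50 = volume_contours(surf, levels=[50], trace_polygons=False)[0]
        # true density on the same grid
        gx, gy = surf.grid.center_mesh()
        cells = np.column_stack([gx.ravel(), gy.ravel()])
        true = 0.5 * (multivariate_normal([-800, 0], 250 ** 2 * np.eye(2)).pdf(cells)
                      + multivariate_normal([800, 300], 250 ** 2 * np.eye(2)).pdf(cells))
        order = np.argsort(true)[::-1]
        csum = np.cumsum(true[order])
        k = np.searchsorted(csum, 0.5 * csum[-1]) + 1
        true_mask = np.zeros(len(true), dtype=bool)
        true_mask[order[:k]] = True
        est_mask = c50.mask.ravel()
        jaccard = (true_mask & est_mask).sum() / (true_mask | est_mask).sum()
        assert jaccard >= 0.7


class TestReporting:
    @pytest.mark.parametrize("contour, survey, expected", [
        (2.8, 14.6, 19), (0.9, 14.6, 6), (2.6, 34.31, 8)])
    def test_core_area_percentages(self, contour, survey, expected):
        assert core_area_percentage(contour, survey) == expected

    def test_surface_correlation_identity_and_affine(self):
        rng = np.random.default_rng(8)
        g = RasterGrid(0, 0, 50.0, rng.uniform(0, 1, (10, 10)))
        from shorewatch.kde import DensitySurface
        s1 = DensitySurface(g, 1.0)
        s2 = DensitySurface(g.copy_with(3.0 * g.values + 0.5), 1.0)
        assert surface_correlation(s1, s1) == pytest.approx(1.0)
        assert surface_correlation(s1, s2) == pytest.approx(1.0)

    def test_surface_correlation_hand_computed(self):
        from shorewatch.kde import DensitySurface
        a = RasterGrid(0, 0, 50.0, np.array([[1.0, 2.0], [3.0, 4.0]]))
        b = RasterGrid(0, 0, 50.0, np.array([[2.0, 1.0], [4.0, 5.0]]))
        r = np.corrcoef([1, 2, 3, 4], [2, 1, 4, 5])[0, 1]
        assert surface_correlation(DensitySurface(a, 1), DensitySurface(b, 1)) \
            == pytest.approx(r)
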