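import numpy as np
import pytest
from shapely.geometry import Point

from fptnsd.winter import (RegionRule, assign_winter_area, delineate_areas,
                           fit_ud, href, select_bandwidth_adhoc)


def gaussian_cluster(rng, center, sd, n):
    return rng.normal(0, sd, (n, 2)) + np.asarray(center)


class TestHref:
    def test_large_sample_limit(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(0, 1.0, (1_000_000, 2))
        n = len(pts)
        assert href(pts) == pytest.approx(n ** (-1 / 6), rel=0.01)

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(0, 500.0, (200, 2))
        assert href(pts * 3.0) == pytest.approx(3.0 * href(pts), rel=1e-12)

    def test_duplicating_points_shrinks_by_sixth_root_of_two(self):
        rng = np.random.default_rng(18)
        pts = rng.normal(0, 500.0, (300, 2))
        doubled = np.vstack([pts, pts])
        # same spread, doubled n: h shrinks by 2^(-1/6) (up to the tiny
        # ddof=1 variance correction)
        assert href(doubled) / href(pts) == pytest.approx(2 ** (-1 / 6),
                                                          rel=0.005)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            href(np.zeros((10, 2)))
        with pytest.raises(ValueError):
            href(np.zeros((3, 2)))


class TestFitUd:
    def test_unit_mass_and_mode_at_cluster(self):
        rng = np.random.default_rng(19)
        pts = gaussian_cluster(rng, (5_000.0, -3_000.0), 800.0, 400)
        ud = fit_ud(pts, bandwidth_m=600.0, cell_m=250.0)
        assert ud.total_mass == pytest.approx(1.0, abs=1e-6)
        iy, ix = np.unravel_index(np.argmax(ud.density), ud.density.shape)
        cx, cy = ud.cell_centers()
        assert abs(cx[ix] - pts[:, 0].mean()) <= 2 * ud.cell_m
        assert abs(cy[iy] - pts[:, 1].mean()) <= 2 * ud.cell_m

    def test_matches_direct_kernel_sum_oracle(self):
        rng = np.random.default_rng(20)
        pts = rng.normal(0, 2_000.0, (50, 2))
        h = 900.0
        ud = fit_ud(pts, h, cell_m=500.0)
        cx, cy = ud.cell_centers()
        # oracle: plain per-point kernel sums, grid-renormalized the same way
        direct = np.zeros_like(ud.density)
        for iy in range(len(cy)):
            for ix in range(len(cx)):
                d2 = (pts[:, 0] - cx[ix]) ** 2 + (pts[:, 1] - cy[iy]) ** 2
                direct[iy, ix] = np.sum(np.exp(-0.5 * d2 / h**2))
        direct /= direct.sum() * ud.cell_m**2
        probes = [(rng.integers(0, len(cy)), rng.integers(0, len(cx)))
                  for _ in range(25)]
        for iy, ix in probes:
            assert ud.density[iy, ix] == pytest.approx(
                direct[iy, ix], rel=1e-8, abs=1e-300)

    def test_isopleth_nesting_and_mass(self):
        rng = np.random.default_rng(21)
        pts = np.vstack([gaussian_cluster(rng, (0, 0), 3_000.0, 300),
                         gaussian_cluster(rng, (40_000, 0), 3_000.0, 200)])
        ud = fit_ud(pts, 2_500.0, cell_m=1_000.0)
        thr50 = ud.isopleth_threshold(0.50)
        thr85 = ud.isopleth_threshold(0.85)
        assert thr50 >= thr85  # smaller mass -> higher density cut
        mass85 = float(ud.density[ud.density >= thr85].sum() * ud.cell_m**2)
        assert mass85 == pytest.approx(0.85, abs=0.02)
        polys50 = ud.isopleth_polygons(0.50)
        polys85 = ud.isopleth_polygons(0.85)
        for p in polys50:  # every 50% polygon sits inside some 85% polygon
            assert any(q.buffer(2 * ud.cell_m).contains(p) for q in polys85)


class TestAdHocBandwidth:
    def test_step_zero_returns_href(self):
        rng = np.random.default_rng(22)
        pts = gaussian_cluster(rng, (0, 0), 4_000.0, 300)
        assert select_bandwidth_adhoc(pts, step=0.0) == pytest.approx(href(pts))

    def test_stopping_rule_contract_on_single_cluster(self):
        """The selected h is the smallest step that keeps the isopleth as
        whole as at h_ref; the next step down fragments, grows holes, or
        falls below the 50% floor."""
        rng = np.random.default_rng(23)
        pts = gaussian_cluster(rng, (0, 0), 4_000.0, 400)
        h0 = href(pts)
        step, cell = 0.1, 800.0
        h = select_bandwidth_adhoc(pts, cell_m=cell, step=step)
        assert h >= 0.5 * h0 - 1e-9

        def frag(hh):
            polys = fit_ud(pts, hh, cell).isopleth_polygons(0.95)
            return len(polys), sum(len(p.interiors) for p in polys)

        base_n, _ = frag(h0)
        n_polys, n_holes = frag(h)
        assert n_polys <= base_n and n_holes == 0
        h_next = h - step * h0
        if h_next >= 0.5 * h0:
            n2, holes2 = frag(h_next)
            assert n2 > base_n or holes2 > 0

    def test_two_distant_clusters_keep_two_polygons(self):
        rng = np.random.default_rng(24)
        pts = np.vstack([gaussian_cluster(rng, (0, 0), 3_000.0, 250),
                         gaussian_cluster(rng, (60_000, 0), 3_000.0, 250)])
        h = select_bandwidth_adhoc(pts, isopleth=0.95, cell_m=1_000.0)
        ud = fit_ud(pts, h, 1_000.0)
        assert len(ud.isopleth_polygons(0.95)) == 2


class TestDelineateAndAssign:
    CENTERS = {"W Coastal": (-120_000.0, -60_000.0),
               "E Coastal": (100_000.0, -80_000.0),
               "W Brooks": (-250_000.0, -450_000.0),
               "E Brooks": (200_000.0, -480_000.0)}
    RULE = RegionRule(divide_y=-265_000.0, meridian_x=0.0)

    def _population_ud(self, rng, weights=(0.45, 0.25, 0.06, 0.24)):
        pts = np.vstack([
            gaussian_cluster(rng, c, 8_000.0, max(10, int(w * 2000)))
            for c, w in zip(self.CENTERS.values(), weights)])
        return fit_ud(pts, 6_000.0, cell_m=2_000.0)

    def test_four_labeled_areas_at_configured_centers(self):
        rng = np.random.default_rng(25)
        ud = self._population_ud(rng)
        areas = delineate_areas(ud, self.RULE)
        assert sorted(a.label for a in areas.areas) == sorted(self.CENTERS)
        for a in areas.areas:
            cx, cy = self.CENTERS[a.label]
            c = a.polygon.centroid
            assert np.hypot(c.x - cx, c.y - cy) < 10_000.0
            expect_level = 0.50 if "Coastal" in a.label else 0.85
            assert a.isopleth_level == expect_level

    def test_assignment_by_overlap_and_edge_distance(self):
        rng = np.random.default_rng(26)
        area_set = delineate_areas(self._population_ud(rng), self.RULE)
        # winter fixes entirely inside W Coastal -> overlap assignment
        inside = gaussian_cluster(rng, self.CENTERS["W Coastal"], 5_000.0, 120)
        iud = fit_ud(inside, 4_000.0, cell_m=1_000.0)
        a = assign_winter_area("X", 2004, iud, area_set)
        assert a.fine_label == "W Coastal"
        assert a.coarse_label == "Coastal"
        assert a.method == "overlap"
        assert a.overlap_fraction > 0.5
        # far-away cluster nearest E Brooks -> edge-distance assignment
        lonely = gaussian_cluster(rng, (320_000.0, -520_000.0), 3_000.0, 100)
        iud2 = fit_ud(lonely, 3_000.0, cell_m=1_000.0)
        b = assign_winter_area("Y", 2004, iud2, area_set)
        assert b.method == "edge_distance"
        assert b.fine_label == "E Brooks"
        assert b.edge_km > 0


def test_ud_raster_round_trip(tmp_path):
    import tifffile
    rng = np.random.default_rng(27)
    pts = gaussian_cluster(rng, (0, 0), 3_000.0, 200)
    ud = fit_ud(pts, 2_000.0, cell_m=1_000.0)
    from fptnsd.winter import write_ud_tiff
    out = tmp_path / "ud.tif"
    write_ud_tiff(ud, str(out), crs="test")
    img = tifffile.imread(out)
    assert img.shape == ud.density.shape
    assert np.allclose(img[::-1], ud.density, rtol=1e-6)
    assert (tmp_path / "ud.tfw").exists()
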