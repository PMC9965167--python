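"""Point-cloud surfaces: outlier filter, DSM/DTM/CHM/intensity rasterization."""

import numpy as np
import pandas as pd
import pytest

from maizefuse import lidar_surface as ls
from maizefuse import synthetic_field as sf


def make_cloud(x, y, z, ground=None, intensity=None):
    df = pd.DataFrame({"x": x, "y": y, "z": z})
    if ground is not None:
        df["ground"] = ground
    if intensity is not None:
        df["intensity"] = intensity
    return df


class TestRemoveOutliers:
    def test_displaced_point_removed_matches_bruteforce(self, rng):
        pts = rng.random((400, 3))
        pts[7] = [10.0, 10.0, 10.0]  # isolated point 10 m away
        cloud = make_cloud(*pts.T)
        cleaned = ls.remove_outliers(cloud, k_neighbors=8, sigma_mult=3.0)
        assert len(cleaned) == 399
        assert not ((cleaned[["x", "y", "z"]] == [10.0, 10.0, 10.0]).all(axis=1)).any()
        # brute-force oracle: mean kNN distance threshold flags the same point
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        knn = np.sort(d, axis=1)[:, 1:9].mean(axis=1)
        flagged = knn > knn.mean() + 3 * knn.std()
        assert flagged.sum() == 1 and flagged[7]

    def test_coincident_points_untouched(self):
        # all pairwise distances identical -> zero spread -> nothing removed
        cloud = make_cloud(np.zeros(50), np.zeros(50), np.zeros(50))
        assert len(ls.remove_outliers(cloud, 4, 3.0)) == 50

    def test_infinite_sigma_is_identity(self, rng):
        pts = rng.random((50, 3))
        cloud = make_cloud(*pts.T)
        assert len(ls.remove_outliers(cloud, 5, np.inf)) == 50

    def test_too_few_points_raises(self):
        cloud = make_cloud([0, 1], [0, 1], [0, 1])
        with pytest.raises(ValueError):
            ls.remove_outliers(cloud, k_neighbors=8)


class TestDsm:
    def test_cell_takes_maximum(self):
        cloud = make_cloud([0.01, 0.02, 0.015], [0.01, 0.02, 0.015], [1.0, 2.0, 1.5],
                           ground=[False] * 3)
        dsm = ls.rasterize_dsm(cloud, cell_size=0.03)
        assert dsm.values[0, 0] == 2.0

    def test_one_point_per_cell_equals_z(self):
        xs = np.arange(5) * 0.03 + 0.015
        cloud = make_cloud(xs, np.full(5, 0.015), np.arange(5, dtype=float),
                           ground=[False] * 5)
        dsm = ls.rasterize_dsm(cloud, cell_size=0.03)
        np.testing.assert_allclose(dsm.values[0], np.arange(5))

    def test_matches_bruteforce_on_random_cloud(self, rng):
        n = 5000
        x, y = rng.random(n), rng.random(n)
        z = rng.random(n) * 3
        cloud = make_cloud(x, y, z, ground=[False] * n)
        cell = 0.1
        dsm = ls.rasterize_dsm(cloud, cell, origin=(0.0, 0.0), shape=(10, 10))
        for r in range(10):
            for c in range(10):
                sel = (x >= c * cell) & (x < (c + 1) * cell) & (y >= r * cell) & (y < (r + 1) * cell)
                expect = z[sel].max() if sel.any() else np.nan
                got = dsm.values[r, c]
                if np.isnan(expect):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect)

    def test_no_nonground_warns_all_nodata(self):
        cloud = make_cloud([0.0], [0.0], [0.0], ground=[True])
        with pytest.warns(UserWarning):
            dsm = ls.rasterize_dsm(cloud, 0.03)
        assert np.isnan(dsm.values).all()


class TestDtm:
    def test_plane_recovered_in_interpolated_cells(self, rng):
        n = 150
        x, y = rng.random(n) * 3, rng.random(n) * 3
        z = 0.2 * x - 0.1 * y + 5.0
        cloud = make_cloud(x, y, z, ground=[True] * n)
        dtm = ls.rasterize_dtm(cloud, cell_size=0.1)
        rows, cols = dtm.shape
        # cells without points are TIN-interpolated at their centers: the
        # linear interpolant of a plane is the plane (1e-6 inside the hull)
        from scipy.spatial import Delaunay

        hull = Delaunay(np.c_[x, y])
        row_idx = ((y - dtm.origin[1]) / 0.1).astype(int)
        col_idx = ((x - dtm.origin[0]) / 0.1).astype(int)
        has_point = np.zeros((rows, cols), dtype=bool)
        has_point[np.clip(row_idx, 0, rows - 1), np.clip(col_idx, 0, cols - 1)] = True
        for r in range(rows):
            for c in range(cols):
                if has_point[r, c]:
                    continue
                cx = dtm.origin[0] + (c + 0.5) * 0.1
                cy = dtm.origin[1] + (r + 0.5) * 0.1
                if hull.find_simplex([[cx, cy]])[0] < 0:
                    continue
                assert dtm.values[r, c] == pytest.approx(0.2 * cx - 0.1 * cy + 5.0, abs=1e-6)

    def test_flat_ground_identically_zero(self, rng):
        x, y = rng.random(100), rng.random(100)
        cloud = make_cloud(x, y, np.zeros(100), ground=[True] * 100)
        dtm = ls.rasterize_dtm(cloud, 0.05)
        np.testing.assert_allclose(dtm.values, 0.0, atol=1e-12)

    def test_too_few_or_collinear_ground_raises(self):
        with pytest.raises(ValueError):
            ls.rasterize_dtm(make_cloud([0, 1], [0, 1], [0, 0], ground=[True] * 2), 0.1)
        collinear = make_cloud([0, 1, 2, 3], [0, 1, 2, 3], [0, 0, 0, 0], ground=[True] * 4)
        with pytest.raises(ValueError):
            ls.rasterize_dtm(collinear, 0.1)


class TestChm:
    def test_difference_clip_and_nodata(self):
        dsm = ls.SurfaceRaster(np.array([[2.0, np.nan, 0.95]]), 0.03, (0, 0))
        dtm = ls.SurfaceRaster(np.array([[0.0, 0.0, 1.0]]), 0.03, (0, 0))
        chm = ls.canopy_height(dsm, dtm)
        assert chm.values[0, 0] == 2.0
        assert np.isnan(chm.values[0, 1])
        assert chm.values[0, 2] == 0.0  # negative difference clipped

    def test_grid_mismatch_raises(self):
        a = ls.SurfaceRaster(np.zeros((2, 2)), 0.03, (0, 0))
        b = ls.SurfaceRaster(np.zeros((3, 2)), 0.03, (0, 0))
        with pytest.raises(ValueError):
            ls.canopy_height(a, b)

    def test_invariant_to_constant_elevation_shift(self, rng):
        n = 300
        pts = make_cloud(rng.random(n), rng.random(n), rng.random(n) + 1.0,
                         ground=rng.random(n) < 0.5)
        dsm = ls.rasterize_dsm(pts, 0.1, (0, 0), (10, 10))
        dtm = ls.rasterize_dtm(pts, 0.1, (0, 0), (10, 10))
        chm = ls.canopy_height(dsm, dtm)
        shifted = pts.copy()
        shifted["z"] += 7.5
        dsm2 = ls.rasterize_dsm(shifted, 0.1, (0, 0), (10, 10))
        dtm2 = ls.rasterize_dtm(shifted, 0.1, (0, 0), (10, 10))
        chm2 = ls.canopy_height(dsm2, dtm2)
        np.testing.assert_allclose(chm.values, chm2.values, atol=1e-9, equal_nan=True)


class TestIntensity:
    def test_highest_point_wins(self):
        cloud = make_cloud([0.01, 0.02], [0.01, 0.02], [1.0, 2.0],
                           ground=[False, False], intensity=[10.0, 50.0])
        ras = ls.rasterize_intensity(cloud, 0.03)
        assert ras.values[0, 0] == 50.0

    def test_uniform_intensity_constant_raster(self, rng):
        n = 200
        cloud = make_cloud(rng.random(n), rng.random(n), rng.random(n),
                           ground=[False] * n, intensity=np.full(n, 7.0))
        ras = ls.rasterize_intensity(cloud, 0.2)
        vals = ras.values[np.isfinite(ras.values)]
        assert (vals == 7.0).all()

    def test_max_rule_differs_when_configured(self):
        cloud = make_cloud([0.01, 0.02], [0.01, 0.02], [2.0, 1.0],
                           ground=[False, False], intensity=[10.0, 50.0])
        by_height = ls.rasterize_intensity(cloud, 0.03, rule="max_height")
        by_max = ls.rasterize_intensity(cloud, 0.03, rule="max")
        assert by_height.values[0, 0] == 10.0
        assert by_max.values[0, 0] == 50.0


class TestEndToEnd:
    def test_planted_canopy_height_recovered(self, small_scene):
        _, _, scene = small_scene
        pc = sf.generate_pointcloud(scene, density=1600, seed=13, z_noise_sd=0.02)
        dsm = ls.rasterize_dsm(pc, scene.gsd, tuple(scene.origin), scene.height.shape)
        dtm = ls.rasterize_dtm(pc, scene.gsd, tuple(scene.origin), scene.height.shape)
        chm = ls.canopy_height(dsm, dtm)
        for plot in scene.plots[:5]:
            rs, cs = scene.plot_pixel_window(plot)
            mask = scene.truth_mask[rs, cs]
            vals = chm.values[rs, cs][mask]
            vals = vals[np.isfinite(vals)]
            planted = scene.height[rs, cs][mask].max()
            assert np.percentile(vals, 90) == pytest.approx(planted, abs=0.15)
        # canopy intensity surface exceeds the ground returns, as planted
        inten = ls.rasterize_intensity(pc, scene.gsd, tuple(scene.origin),
                                       scene.height.shape)
        canopy_mean = inten.values[np.isfinite(inten.values)].mean()
        ground_mean = pc.loc[pc["ground"], "intensity"].mean()
        assert canopy_mean > ground_mean
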