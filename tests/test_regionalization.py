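"""Hotspots, DBSCAN, alpha hulls, per-region MMRR, ensemble, gradient."""

import numpy as np
import pytest
from shapely.geometry import MultiPoint

import phenoasync as pa
from phenoasync.regionalization import RegionHull, EnsembleRecord, sample_points_in_region


class TestHotspot:
    def test_percentile_zero_selects_all_valid(self):
        v = np.array([1.0, 2.0, np.nan, 3.0])
        mask = pa.hotspot_mask(v, 0.0)
        assert mask.tolist() == [True, True, False, True]

    def test_uniform_map_all_tie_at_threshold(self):
        mask = pa.hotspot_mask(np.full(20, 7.0), 95.0)
        assert mask.all()

    def test_top_five_of_hundred(self):
        rng = np.random.default_rng(0)
        v = rng.permutation(np.arange(100.0))
        mask = pa.hotspot_mask(v, 95.0)
        assert set(v[mask].astype(int)) == {95, 96, 97, 98, 99}


class TestDbscan:
    def test_two_blobs_no_noise(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(5, 0.1, (30, 2))])
        labels = pa.density_cluster(pts, eps=0.5, min_samples=3)
        assert np.unique(labels[labels >= 0]).size == 2
        assert np.all(labels >= 0)

    def test_tiny_eps_all_noise(self):
        rng = np.random.default_rng(2)
        pts = rng.random((20, 2))
        labels = pa.density_cluster(pts, eps=1e-9, min_samples=3)
        assert np.all(labels == -1)

    def test_fractional_min_samples_absolute_interpretation(self):
        # ceil(0.3) = 1: any point with a neighbor within eps is core
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0]])
        labels = pa.density_cluster(pts, eps=0.5, min_samples=0.3)
        assert labels[0] == labels[1] and labels[0] >= 0

    def test_agrees_with_reachability_oracle(self):
        """Brute-force DBSCAN over 50 points must match sklearn's labels."""
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.3, (25, 2)), rng.normal(3, 0.3, (25, 2))])
        eps, ms = 0.6, 4
        labels = pa.density_cluster(pts, eps, ms)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        core = (D <= eps).sum(axis=1) >= ms  # self-inclusive neighbor count
        # grow clusters by core-reachability
        oracle = np.full(50, -1)
        cid = 0
        for s in range(50):
            if not core[s] or oracle[s] != -1:
                continue
            stack = [s]
            oracle[s] = cid
            while stack:
                u = stack.pop()
                if not core[u]:
                    continue
                for v in np.flatnonzero(D[u] <= eps):
                    if oracle[v] == -1:
                        oracle[v] = cid
                        if core[v]:
                            stack.append(v)
            cid += 1
        # compare as partitions of the non-noise points
        assert (labels == -1).tolist() == (oracle == -1).tolist()
        both = labels >= 0
        assert pa.pairwise_jaccard(labels[both], oracle[both]).J == 1.0


class TestAlphaHull:
    def test_small_alpha_recovers_convex_hull(self):
        rng = np.random.default_rng(4)
        pts = rng.random((40, 2))
        hull = pa.alpha_hull(pts, alpha=1e-9)
        convex = MultiPoint([tuple(p) for p in pts]).convex_hull
        assert hull.area == pytest.approx(convex.area, rel=1e-9)

    def test_c_shape_concave_hull_smaller_than_convex(self):
        theta = np.linspace(0.3, 2 * np.pi - 0.3, 60)
        ring = np.column_stack([np.cos(theta), np.sin(theta)])
        rng = np.random.default_rng(5)
        pts = ring + rng.normal(0, 0.02, ring.shape)
        concave = pa.alpha_hull(pts, alpha=2.0)
        convex = MultiPoint([tuple(p) for p in pts]).convex_hull
        assert concave.area < 0.8 * convex.area

    def test_all_points_covered(self):
        rng = np.random.default_rng(6)
        pts = rng.random((30, 2))
        hull = pa.alpha_hull(pts, alpha=1e-9)
        from shapely.geometry import Point

        assert all(hull.buffer(1e-9).covers(Point(*p)) for p in pts)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            pa.alpha_hull(pts, alpha=0.5)


class TestRegionMmrr:
    @staticmethod
    def _scene(coupling):
        grid = pa.GridSpec(20, 20, 0.05, (0.5, 0.0))
        return grid, pa.gen_harmonic_field(
            grid, "gradient", noise_sd=0.0, seed=8, climate_coupling=coupling
        )

    @staticmethod
    def _hull(grid):
        lat, lon = grid.pixel_latlon()
        pts = np.column_stack([lon, lat])
        return pa.alpha_hull(pts, alpha=1e-9)

    def test_climate_driven_scene_gives_beta_c(self):
        grid, scene = self._scene(coupling=1.0)
        fits = pa.fit_cube(scene.cube)
        valid = np.array([f.ok for f in fits])
        curves = pa.standardized_curves(fits, valid)
        out = pa.region_mmrr(self._hull(grid), curves, scene.climate, grid, valid,
                             n_points=80, seed=0, n_perm=99)
        res, _, _ = out
        assert res.coefficients["climate"] > 3 * abs(res.coefficients["geography"])
        assert res.perm_p["climate"] <= 0.05

    def test_isoclimatic_scene_gives_small_beta_c(self):
        """Phenology varies spatially but climate is decoupled: beta_c ~ 0."""
        grid, scene = self._scene(coupling=0.0)
        fits = pa.fit_cube(scene.cube)
        valid = np.array([f.ok for f in fits])
        curves = pa.standardized_curves(fits, valid)
        out = pa.region_mmrr(self._hull(grid), curves, scene.climate, grid, valid,
                             n_points=80, seed=1, n_perm=99)
        res, _, _ = out
        assert abs(res.coefficients["climate"]) < 0.25
        assert res.coefficients["geography"] > 0.5

    def test_fixed_seed_reproducible(self):
        grid, scene = self._scene(coupling=1.0)
        fits = pa.fit_cube(scene.cube)
        valid = np.array([f.ok for f in fits])
        curves = pa.standardized_curves(fits, valid)
        hull = self._hull(grid)
        a = pa.region_mmrr(hull, curves, scene.climate, grid, valid, n_points=40, seed=5)
        b = pa.region_mmrr(hull, curves, scene.climate, grid, valid, n_points=40, seed=5)
        np.testing.assert_array_equal(a[2], b[2])
        assert a[0].coefficients == b[0].coefficients

    def test_sampled_points_inside_polygon_and_valid(self):
        grid, scene = self._scene(coupling=1.0)
        valid = np.ones(grid.n_pixels, bool)
        valid[::3] = False
        hull = self._hull(grid)
        coords, pixels = sample_points_in_region(
            hull, grid, valid, 50, np.random.default_rng(0)
        )
        assert np.all(valid[pixels])
        from shapely.geometry import Point

        assert all(hull.intersects(Point(lo, la)) for la, lo in coords)


@pytest.fixture(scope="module")
def ensemble_inputs():
    grid = pa.GridSpec(20, 20, 0.05, (0.5, 0.0))
    scene = pa.gen_harmonic_field(grid, "gradient", noise_sd=0.0, seed=9,
                                  climate_coupling=0.8)
    fits = pa.fit_cube(scene.cube)
    valid = np.array([f.ok for f in fits])
    curves = pa.standardized_curves(fits, valid)
    amap = pa.asynchrony_map(curves, grid, 16.0, valid=valid, min_neighbors=10)
    return grid, scene, curves, valid, amap


class TestEnsemble:

    def test_single_combination_single_record(self, ensemble_inputs):
        grid, scene, curves, valid, amap = ensemble_inputs
        recs = pa.run_ensemble(
            amap.value, curves, scene.climate, grid, valid=valid,
            hotspot_percentile=80.0, eps_grid=(0.3,), min_samples_grid=(0.3,),
            alpha_grid=(0.5,), n_points=30, n_perm=9, seed=0,
        )
        assert len(recs) == 1

    def test_full_grid_gives_27_records(self, ensemble_inputs):
        grid, scene, curves, valid, amap = ensemble_inputs
        recs = pa.run_ensemble(
            amap.value, curves, scene.climate, grid, valid=valid,
            hotspot_percentile=80.0,
            eps_grid=(0.2, 0.35, 0.5), min_samples_grid=(0.3, 0.45, 0.6),
            alpha_grid=(0.25, 0.75, 1.25), n_points=20, n_perm=9, seed=0,
        )
        assert len(recs) == 27

    def test_region_members_inside_hotspot_mask(self, ensemble_inputs):
        grid, scene, curves, valid, amap = ensemble_inputs
        hot = pa.hotspot_mask(amap.value, 80.0, valid)
        recs = pa.run_ensemble(
            amap.value, curves, scene.climate, grid, valid=valid,
            hotspot_percentile=80.0, eps_grid=(0.3,), min_samples_grid=(0.3,),
            alpha_grid=(0.5,), n_points=20, n_perm=9, seed=0,
        )
        for rec in recs:
            for region in rec.regions:
                assert hot[region.member_pixels].all()

    def test_reproducible_under_master_seed(self, ensemble_inputs):
        grid, scene, curves, valid, amap = ensemble_inputs
        kw = dict(valid=valid, hotspot_percentile=80.0, eps_grid=(0.3,),
                  min_samples_grid=(0.3,), alpha_grid=(0.5,), n_points=20,
                  n_perm=9, seed=4)
        a = pa.run_ensemble(amap.value, curves, scene.climate, grid, **kw)
        b = pa.run_ensemble(amap.value, curves, scene.climate, grid, **kw)
        assert [r.beta_c for rec in a for r in rec.regions] == \
               [r.beta_c for rec in b for r in rec.regions]


class TestGradient:
    @staticmethod
    def _synthetic_records(rng, n_regions, a, b, noise):
        """Regions with planted beta_c = a + b*|lat| + noise."""
        lats = rng.uniform(0, 60, n_regions)
        regions = [
            RegionHull(polygon=None, member_pixels=np.array([]), mean_abs_lat=la,
                       beta_c=a + b * la + noise * rng.standard_normal())
            for la in lats
        ]
        return [EnsembleRecord(eps=1, min_samples=1, alpha=1, regions=regions)]

    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(10)
        recs = self._synthetic_records(rng, 200, a=0.1, b=0.006, noise=0.05)
        res = pa.latitudinal_gradient(recs, n_mc=500, seed=0)
        se = res.gamma_lat / max(np.sqrt(200), 1)  # rough scale check below
        assert res.gamma_lat == pytest.approx(0.006, abs=0.0015)
        assert res.mc_p < 0.05

    def test_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_runs = 60
        for i in range(n_runs):
            recs = self._synthetic_records(rng, 40, a=0.2, b=0.0, noise=0.05)
            res = pa.latitudinal_gradient(recs, n_mc=199, seed=i)
            rejections += res.mc_p <= 0.05
        rate = rejections / n_runs
        se = np.sqrt(0.05 * 0.95 / n_runs)
        assert rate <= 0.05 + 3 * se

    def test_no_mc_still_reports_ols(self):
        rng = np.random.default_rng(12)
        recs = self._synthetic_records(rng, 30, a=0.1, b=0.01, noise=0.02)
        res = pa.latitudinal_gradient(recs, n_mc=0, seed=0)
        assert res.mc_p is None and np.isfinite(res.gamma_lat)

    def test_zero_lat_variance_rejected(self):
        regions = [
            RegionHull(polygon=None, member_pixels=np.array([]), mean_abs_lat=10.0,
                       beta_c=float(i))
            for i in range(5)
        ]
        with pytest.raises(ValueError):
            pa.latitudinal_gradient([EnsembleRecord(1, 1, 1, regions)], n_mc=0)
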