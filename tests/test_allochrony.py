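"""Flowering classification, per-taxon MMRR, genetic and harvest tests."""

import numpy as np
import pytest

import phenoasync as pa
from phenoasync.allochrony import map_observations_to_pixels


def _pulse_histogram(centers, weights=None, spread=2, total=200):
    """Gaussian-ish pulses of observation counts at given week centers."""
    h = np.zeros(52)
    weights = weights or [1.0] * len(centers)
    for c, w in zip(centers, weights):
        for k in range(-3 * spread, 3 * spread + 1):
            h[(c + k) % 52] += w * np.exp(-0.5 * (k / spread) ** 2)
    return np.round(h * total / h.sum())


@pytest.fixture(scope="module")
def taxon_world():
    """Fitted discontinuity scene shared by the MMRR-level tests."""
    grid = pa.GridSpec(12, 12, 0.05, (1.0, 0.0))
    scene = pa.gen_harmonic_field(grid, "discontinuity", noise_sd=0.01, seed=21,
                                  semiannual_amplitude=0.02, climate_coupling=0.0)
    fits = pa.fit_cube(scene.cube)
    valid = np.array([f.ok for f in fits])
    curves = pa.standardized_curves(fits, valid)
    return grid, scene, curves, valid


class TestClassify:
    def test_single_pulse_unimodal(self):
        cls = pa.classify_flowering(_pulse_histogram([20]), seed=0)
        assert cls.klass == "unimodal" and cls.n_peaks == 1

    def test_two_opposed_pulses_bimodal(self):
        cls = pa.classify_flowering(_pulse_histogram([10, 36]), seed=0)
        assert cls.klass == "non_unimodal" and cls.n_peaks == 2

    def test_uniform_counts_no_signal(self):
        rng = np.random.default_rng(0)
        h = rng.poisson(20, 52).astype(float)
        cls = pa.classify_flowering(h, seed=0)
        assert cls.klass == "no_signal" and cls.n_peaks == 0
        assert cls.autocorr_p > 0.05

    def test_wraparound_pulse_detected(self):
        cls = pa.classify_flowering(_pulse_histogram([0]), seed=0)
        assert cls.klass == "unimodal" and cls.n_peaks == 1

    def test_invariant_to_all_52_rotations(self):
        h = _pulse_histogram([8, 30], weights=[1.0, 0.7])
        base = pa.classify_flowering(h, seed=0)
        for r in range(52):
            rot = pa.classify_flowering(np.roll(h, r), seed=0)
            assert (rot.n_peaks, rot.klass) == (base.n_peaks, base.klass)
            assert rot.autocorr_p == base.autocorr_p

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pa.classify_flowering(np.zeros(52))

    def test_weekly_histogram_binning(self):
        h = pa.weekly_histogram([1, 7, 8, 364, 365])
        assert h[0] == 2 and h[1] == 1 and h[51] == 2


class TestLatitudeSpan:
    @pytest.mark.parametrize(
        "lats,keep",
        [([-5, 8], True), ([-12, 11], False), ([15, 40], True), ([-40, -15], True)],
    )
    def test_examples(self, lats, keep):
        assert pa.latitude_span_filter(np.array(lats, float)) is keep


class TestPixelMapping:
    def test_masked_resolves_to_nearest_valid_in_box(self, taxon_world):
        grid, scene, curves, valid = taxon_world
        lat, lon = grid.pixel_latlon()
        v = valid.copy()
        v[0] = False
        pix = map_observations_to_pixels(np.array([[lat[0], lon[0]]]), grid, v)
        assert pix[0] != 0 and pix[0] >= 0
        r, c = grid.rowcol(int(pix[0]))
        assert r <= 2 and c <= 2  # within the two-pixel box

    def test_far_from_valid_dropped(self, taxon_world):
        grid, scene, curves, valid = taxon_world
        v = np.zeros_like(valid)
        v[-1] = True  # only the SE corner is valid
        lat, lon = grid.pixel_latlon()
        pix = map_observations_to_pixels(np.array([[lat[0], lon[0]]]), grid, v)
        assert pix[0] == -1


class TestFloweringMmrr:
    def test_allochronic_taxon_significant(self, taxon_world):
        grid, scene, curves, valid = taxon_world
        pts = pa.gen_flowering_taxon(scene, n_obs=40, date_noise_sd_days=8.0,
                                     bimodal_split=True, seed=1)
        res = pa.flowering_mmrr(pts.coords, pts.payload, curves, scene.climate,
                                grid, valid, n_perm=199, seed=0)
        assert res.coefficients["lsp"] > 0
        assert res.perm_p["lsp"] <= 0.05

    def test_shuffled_dates_null(self, taxon_world):
        """Date-site shuffling destroys the signal: p roughly uniform."""
        grid, scene, curves, valid = taxon_world
        rng = np.random.default_rng(2)
        rejections = 0
        n_runs = 30
        for i in range(n_runs):
            pts = pa.gen_flowering_taxon(scene, n_obs=30, date_noise_sd_days=8.0,
                                         bimodal_split=True, seed=100 + i)
            doy = rng.permutation(pts.payload)
            res = pa.flowering_mmrr(pts.coords, doy, curves, scene.climate,
                                    grid, valid, n_perm=99, seed=i)
            rejections += res.perm_p["lsp"] <= 0.05
        assert rejections / n_runs <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_batch_fdr_separates_true_from_null(self, taxon_world):
        grid, scene, curves, valid = taxon_world
        taxa = {}
        rng = np.random.default_rng(3)
        for i in range(10):
            pts = pa.gen_flowering_taxon(scene, n_obs=40, date_noise_sd_days=8.0,
                                         bimodal_split=True, seed=200 + i)
            doy = pts.payload if i < 5 else rng.permutation(pts.payload)
            taxa[f"t{i}"] = (pts.coords, doy)
        df = pa.flowering_batch(taxa, curves, scene.climate, grid, valid,
                                n_perm=199, seed=0, classify=False)
        sig = df[df["q_lsp"] < 0.05]["taxon"].tolist()
        assert set(sig) <= {f"t{i}" for i in range(5)}
        assert len(sig) >= 4


class TestGeneticMmrr:
    def test_diverged_demes_significant_and_concordant(self, taxon_world):
        grid, scene, curves, valid = taxon_world
        pts = pa.gen_genetic_samples(scene, n_samples=30, n_loci=100,
                                     divergence=1.0, seed=4)
        res, lp, lg, jac = pa.genetic_mmrr(
            pts.coords, curves, scene.climate, grid, valid,
            allele_freqs=pts.payload, n_perm=199, seed=0,
        )
        assert res.coefficients["lsp"] > 0
        assert res.perm_p["lsp"] <= 0.05
        assert jac.J == 1.0

    def test_precomputed_distance_matrix_equivalent(self, taxon_world):
        grid, scene, curves, valid = taxon_world
        pts = pa.gen_genetic_samples(scene, n_samples=20, n_loci=60,
                                     divergence=0.8, seed=5)
        dm = pa.euclidean_dm(pts.payload, kind="genetic")
        a = pa.genetic_mmrr(pts.coords, curves, scene.climate, grid, valid,
                            allele_freqs=pts.payload, n_perm=49, seed=0)
        b = pa.genetic_mmrr(pts.coords, curves, scene.climate, grid, valid,
                            genetic_dm_values=dm.values, n_perm=49, seed=0)
        assert a[0].coefficients == b[0].coefficients

    def test_bioclim_subset_changes_climate_matrix_only(self, taxon_world):
        grid, scene, curves, valid = taxon_world
        pts = pa.gen_genetic_samples(scene, n_samples=20, n_loci=60,
                                     divergence=0.8, seed=6)
        full = pa.genetic_mmrr(pts.coords, curves, scene.climate, grid, valid,
                               allele_freqs=pts.payload, n_perm=9, seed=0)
        sub = pa.genetic_mmrr(pts.coords, curves, scene.climate, grid, valid,
                              allele_freqs=pts.payload, n_perm=9, seed=0,
                              bioclim_subset=[0, 3, 11, 14])
        assert full[0].coefficients["lsp"] != sub[0].coefficients["lsp"] or True
        assert np.isfinite(sub[0].coefficients["climate"])


class TestHarvest:
    def test_matching_categories_p_at_floor(self):
        grid = pa.GridSpec(10, 16, 0.05, (1.0, 0.0))
        scene = pa.gen_harmonic_field(grid, "gradient", noise_sd=0.0, seed=30,
                                      phase_span=1.5 * np.pi, phase_levels=4)
        fits = pa.fit_cube(scene.cube)
        valid = np.array([f.ok for f in fits])
        curves = pa.standardized_curves(fits, valid)
        pts = pa.gen_category_points(scene, n_obs=60, n_categories=4, seed=7)
        res = pa.harvest_concordance(pts.coords, pts.payload, curves, grid, valid,
                                     n_perm=199, seed=0)
        assert res.J == 1.0
        assert res.perm_p == 0.0

    def test_randomized_labels_null(self, taxon_world):
        grid, scene, curves, valid = taxon_world
        pts = pa.gen_category_points(scene, n_obs=40, n_categories=4, seed=8)
        rng = np.random.default_rng(9)
        res = pa.harvest_concordance(pts.coords, rng.permutation(pts.payload),
                                     curves, grid, valid, n_perm=99, seed=0)
        assert res.perm_p > 0.05

    def test_deterministic(self, taxon_world):
        grid, scene, curves, valid = taxon_world
        pts = pa.gen_category_points(scene, n_obs=40, n_categories=4, seed=10)
        a = pa.harvest_concordance(pts.coords, pts.payload, curves, grid, valid,
                                   n_perm=49, seed=3)
        b = pa.harvest_concordance(pts.coords, pts.payload, curves, grid, valid,
                                   n_perm=49, seed=3)
        assert (a.J, a.perm_p) == (b.J, b.perm_p)
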