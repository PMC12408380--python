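"""End-to-end composition: configuration, seeding, artifacts, provenance.

``RunConfig`` gathers every tunable constant of the analysis, with defaults
equal to the published values (filter thresholds, permutation counts,
neighborhood radii, percentiles, the ensemble hyperparameter grids).
``RunConfig.synthetic_demo()`` scales the spatial parameters to the bundled
synthetic scene so the whole pipeline runs on a desk in minutes; the
statistical constants are untouched.

``run_pipeline`` executes the stages in dependency order — simulate, fit,
filter, asynchrony, EOF/clustering, regionalization, gradient, drivers,
allochrony — writing each stage's artifact plus a provenance record (config,
master seed, library versions).  Every stochastic step draws its seed from
the master seed, so a config+seed pair reproduces byte-identical JSON
outputs; with ``resume=True`` completed stages are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .allochrony import flowering_batch, genetic_mmrr, harvest_concordance
from .asynchrony import asynchrony_map, map_agreement
from .drivers import (
    attribution,
    neighborhood_mean,
    predominance,
    predominance_map,
    rf_fit,
    vegetation_entropy,
)
from .eof import cluster_phenocycles, itcz_weight, rgb_composite, transform_eof, weighted_eof
from .filters import apply_filters
from .grid import GridSpec
from .harmonic import fit_cube, reconstruct_phenocycle, standardize
from .regionalization import hotspot_mask, latitudinal_gradient, run_ensemble
from .synthetic import (
    gen_category_points,
    gen_flowering_taxon,
    gen_genetic_samples,
    gen_harmonic_field,
    inject_missingness,
)

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "standardized_curves"]

log = logging.getLogger("phenoasync")

_R_MERC = 6378137.0


def web_mercator_xy(lat, lon):
    """EPSG:3857 coordinates in metres (for the driver table's x/y columns)."""
    x = _R_MERC * np.radians(lon)
    y = _R_MERC * np.log(np.tan(np.pi / 4.0 + np.radians(lat) / 2.0))
    return x, y


def derive_seed(master: int, *scope) -> int:
    """Stable child seed (< 2**31) for a named stage of a run."""
    h = hashlib.sha256(repr((int(master),) + scope).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """All analysis constants in one place.

    Defaults are the published operating point: the 50% missingness cap,
    10% monthly floor, 0.8 evenness floor, 20-permutation significance
    screen at alpha 0.05, 50/100/150-km asynchrony radii with a 30-neighbor
    minimum and P <= 0.01 slope screen, 95th/85th-percentile hotspots, the
    3 x 3 x 3 regionalization grid, and 1,000-draw Monte-Carlo tests.
    """

    seed: int = 0
    # grid of the simulated scene
    n_rows: int = 40
    n_cols: int = 40
    cell_size: float = 0.05
    origin: tuple[float, float] = (1.0, 0.0)
    phase_pattern: str = "discontinuity"
    noise_sd: float = 0.02
    # filtering
    max_missing_frac: float = 0.5
    min_monthly: float = 0.10
    min_evenness: float = 0.8
    n_perm_significance: int = 20
    alpha_significance: float = 0.05
    # asynchrony
    radii_km: tuple[float, ...] = (50.0, 100.0, 150.0)
    min_neighbors: int = 30
    slope_p_threshold: float = 0.01
    # visualization / clustering
    n_clusters: int = 4
    itcz_band_deg: float = 10.0
    # regionalization ensemble
    hotspot_percentile: float = 95.0
    driver_hotspot_percentile: float = 85.0
    eps_grid: tuple[float, ...] = (2.0, 3.5, 5.0)
    min_samples_grid: tuple[float, ...] = (0.3, 0.45, 0.6)
    alpha_grid: tuple[float, ...] = (0.25, 0.75, 1.25)
    region_n_points: int = 1000
    # permutation counts
    mmrr_n_perm: int = 999
    jaccard_n_perm: int = 1000
    gradient_n_mc: int = 1000

    @classmethod
    def synthetic_demo(cls, seed: int = 0) -> "RunConfig":
        """Spatial parameters scaled to the ~2-degree synthetic scene."""
        return cls(
            seed=seed,
            radii_km=(25.0, 35.0, 45.0),
            eps_grid=(0.2, 0.35, 0.5),
            alpha_grid=(0.25, 0.75, 1.25),
            region_n_points=120,
            mmrr_n_perm=199,
            jaccard_n_perm=199,
            gradient_n_mc=500,
        )

    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size, self.origin)


def standardized_curves(fits, valid) -> np.ndarray:
    """Standardized phenocycles for valid pixels (zeros elsewhere)."""
    n = len(fits)
    out = np.zeros((n, 365))
    for p in np.flatnonzero(valid):
        out[p] = standardize(reconstruct_phenocycle(fits[p])).values
    return out


def _provenance(config: RunConfig) -> dict:
    import sklearn
    import scipy

    cfg = dataclasses.asdict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "pandas": pd.__version__,
        },
    }


def run_pipeline(config: RunConfig, out_dir, *, resume: bool = False) -> dict:
    """Run every stage on a synthetic scene; return the summary record.

    Artifacts land in ``out_dir``: the cube (NetCDF), coefficient and
    asynchrony layers, the filter mask accounting (CSV), region hulls
    (GeoJSON) and per-stage JSON summaries, plus ``provenance.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    grid = config.grid()
    summary: dict = {}

    pio.write_json(_provenance(config), out / "provenance.json")

    # --- simulate ----------------------------------------------------------
    log.info("stage: simulate")
    scene = gen_harmonic_field(
        grid,
        config.phase_pattern,
        noise_sd=config.noise_sd,
        seed=derive_seed(seed, "scene"),
        semiannual_amplitude=0.03,
        coef_noise_sd=0.02,
        climate_coupling=0.9,
    )
    scene.cube.available[:] = inject_missingness(
        scene.cube, frac_random=0.1, seed=derive_seed(seed, "missing")
    ).available
    cube_path = out / "cube.nc"
    if not (resume and cube_path.exists()):
        pio.write_cube(scene.cube, cube_path)

    # --- fit + filter ------------------------------------------------------
    log.info("stage: fit + filter")
    mask = apply_filters(
        scene.cube,
        scene.landcover,
        n_perm=config.n_perm_significance,
        alpha=config.alpha_significance,
        seed=derive_seed(seed, "significance"),
    )
    fits = fit_cube(scene.cube)
    valid = mask.keep & np.array([f.ok for f in fits])
    curves = standardized_curves(fits, valid)
    pd.DataFrame([mask.counts()]).to_csv(out / "filter_counts.csv", index=False)
    pio.write_layers(
        {
            "b0": np.array([f.b0 for f in fits]),
            "b1": np.array([f.b1 for f in fits]),
            "b2": np.array([f.b2 for f in fits]),
            "b3": np.array([f.b3 for f in fits]),
            "b4": np.array([f.b4 for f in fits]),
            "r2": np.array([f.r2 for f in fits]),
            "valid": valid.astype(float),
        },
        grid,
        out / "coefficients.nc",
    )
    summary["filter_counts"] = mask.counts()
    summary["mean_fit_r2"] = float(np.mean([f.r2 for f, v in zip(fits, valid) if v]))

    # --- asynchrony --------------------------------------------------------
    log.info("stage: asynchrony")
    maps = {
        r: asynchrony_map(
            curves, grid, r,
            valid=valid, min_neighbors=config.min_neighbors,
            p_threshold=config.slope_p_threshold,
        )
        for r in config.radii_km
    }
    main_radius = config.radii_km[len(config.radii_km) // 2]
    amap = maps[main_radius]
    pio.write_layers(
        {f"asynchrony_{r:g}km": m.value for r, m in maps.items()}, grid, out / "asynchrony.nc"
    )
    rr = list(config.radii_km)
    summary["asynchrony_map_agreement"] = {
        f"{a:g}v{b:g}": map_agreement(maps[a], maps[b])
        for a, b in zip(rr, rr[1:])
    }
    summary["asynchrony_valid_pixels"] = int(amap.valid.sum())

    # --- EOF / clustering --------------------------------------------------
    log.info("stage: eof + clustering")
    lat, lon = grid.pixel_latlon()
    eof = weighted_eof(curves[valid], lat[valid], n_modes=3)
    w = itcz_weight(lat[valid], 0.0, band_deg=config.itcz_band_deg)
    scaled = [
        (m - m.min()) / (np.ptp(m) if np.ptp(m) > 0 else 1.0) for m in eof.modes[:3]
    ]
    transformed = [transform_eof(m, w) for m in scaled]
    while len(transformed) < 3:  # rank-limited scenes still get an image
        transformed.append(np.zeros_like(transformed[0]))
    rgb = rgb_composite(*transformed)
    labels, inertia, centers, med_rgb = cluster_phenocycles(
        curves[valid], config.n_clusters, seed=derive_seed(seed, "kmeans"), rgb=rgb
    )
    summary["eof_variance_fraction"] = eof.variance_fraction.tolist()
    summary["cluster_inertia"] = inertia

    # --- regionalization + gradient ---------------------------------------
    log.info("stage: regionalization")
    records = run_ensemble(
        amap.value,
        curves,
        scene.climate,
        grid,
        valid=valid,
        hotspot_percentile=config.hotspot_percentile,
        eps_grid=config.eps_grid,
        min_samples_grid=config.min_samples_grid,
        alpha_grid=config.alpha_grid,
        n_points=config.region_n_points,
        n_perm=config.mmrr_n_perm,
        seed=derive_seed(seed, "ensemble"),
    )
    all_regions = [r for rec in records for r in rec.regions]
    pio.write_hulls_geojson(all_regions, out / "regions.geojson")
    summary["n_ensemble_records"] = len(records)
    summary["n_regions"] = len(all_regions)
    try:
        grad = latitudinal_gradient(
            records, n_mc=config.gradient_n_mc, seed=derive_seed(seed, "gradient")
        )
        summary["gamma_lat"] = grad.gamma_lat
        summary["gamma_lat_mc_p"] = grad.mc_p
    except ValueError as exc:
        summary["gamma_lat"] = None
        log.warning("gradient skipped: %s", exc)

    # --- drivers -----------------------------------------------------------
    log.info("stage: drivers")
    table = _driver_table(config, scene, grid, valid, amap, curves, seed)
    model = rf_fit(table, include_xy=True, seed=derive_seed(seed, "rf"))
    attr = attribution(model, table)
    hot85 = hotspot_mask(amap.value, config.driver_hotspot_percentile, valid)
    predom_all = np.full(grid.n_pixels, np.nan)
    predom_all[table.index.to_numpy()] = predominance(attr)
    predom = predominance_map(predom_all, hot85)
    summary["rf_r2"] = model.r2
    summary["rf_rmse"] = model.rmse
    summary["driver_importance"] = attr.importance().to_dict()
    summary["predominance_hotspot_mean"] = (
        float(np.nanmean(predom)) if np.isfinite(predom).any() else None
    )

    # --- allochrony --------------------------------------------------------
    log.info("stage: allochrony")
    taxa = {
        f"taxon_{i}": _taxon_obs(scene, i, seed)
        for i in range(6)
    }
    fdf = flowering_batch(
        taxa, curves, scene.climate, grid, valid,
        n_perm=config.mmrr_n_perm, seed=derive_seed(seed, "flowering"),
    )
    fdf.to_csv(out / "flowering_results.csv", index=False)
    gen_pts = gen_genetic_samples(scene, n_samples=30, divergence=1.0,
                                  seed=derive_seed(seed, "genetic"))
    gres, _, _, gjac = genetic_mmrr(
        gen_pts.coords, curves, scene.climate, grid, valid,
        allele_freqs=gen_pts.payload, n_perm=config.mmrr_n_perm,
        seed=derive_seed(seed, "genetic_mmrr"),
    )
    harvest = gen_category_points(scene, n_obs=80, n_categories=4,
                                  seed=derive_seed(seed, "harvest"))
    hjac = harvest_concordance(
        harvest.coords, harvest.payload, curves, grid, valid,
        n_perm=config.jaccard_n_perm, seed=derive_seed(seed, "harvest_test"),
    )
    summary["flowering_n_significant"] = int((fdf["q_lsp"] < 0.05).sum())
    summary["genetic_beta_lsp"] = gres.coefficients["lsp"]
    summary["genetic_p_lsp"] = gres.perm_p["lsp"]
    summary["genetic_cluster_jaccard"] = gjac.J
    summary["harvest_jaccard"] = hjac.J
    summary["harvest_jaccard_p"] = hjac.perm_p

    pio.write_json(summary, out / "summary.json")
    return summary


def _taxon_obs(scene, i: int, seed: int):
    """Half the synthetic panel shows true allochrony, half is null."""
    allochronic = i % 2 == 0
    pts = gen_flowering_taxon(
        scene, n_obs=40, date_noise_sd_days=10.0,
        bimodal_split=allochronic, seed=derive_seed(seed, "taxon", i),
    )
    doy = pts.payload
    if not allochronic:
        rng = np.random.default_rng(derive_seed(seed, "taxon_null", i))
        doy = rng.permutation(doy)
    return pts.coords, doy


def _driver_table(config, scene, grid, valid, amap, curves, seed) -> pd.DataFrame:
    """Assemble the driver table from covariate maps on the same grid.

    The precipitation-seasonality surrogate shares the scene's phase field
    (the planted driver); the remaining climate asynchrony surrogates are
    independent fields.
    """
    from .synthetic import gen_harmonic_field as _gen

    lat, lon = grid.pixel_latlon()
    rows = amap.valid & valid
    ridx = np.flatnonzero(rows)
    rng = np.random.default_rng(derive_seed(seed, "drivers"))

    def _indep_map(name_seed):
        sc = _gen(grid, "gradient", noise_sd=0.02, seed=name_seed,
                  coef_noise_sd=0.05)
        f = fit_cube(sc.cube)
        v = np.array([x.ok for x in f])
        cv = standardized_curves(f, v)
        return asynchrony_map(
            cv, grid, amap.radius_km, valid=v,
            min_neighbors=config.min_neighbors,
            p_threshold=config.slope_p_threshold,
        ).value

    ppt = amap.value + 0.1 * np.nanstd(amap.value) * rng.standard_normal(grid.n_pixels)
    tmin = _indep_map(derive_seed(seed, "tmin"))
    x, y = web_mercator_xy(lat, lon)
    modal = scene.landcover[0]
    table = pd.DataFrame(
        {
            "lsp_asy": amap.value,
            "ppt_asy": ppt,
            "tmp_min_asy": tmin,
            "tmp_max_asy": rng.standard_normal(grid.n_pixels),
            "def_asy": rng.standard_normal(grid.n_pixels),
            "cld_asy": rng.standard_normal(grid.n_pixels),
            "vrm_med": rng.standard_normal(grid.n_pixels),
            "veg_ent": vegetation_entropy(modal, grid, radius_km=amap.radius_km, valid=valid),
            "luc_prp_mea": neighborhood_mean(
                rng.random(grid.n_pixels), grid, radius_km=amap.radius_km
            ),
            "brn_frq_mea": rng.standard_normal(grid.n_pixels),
            "x": x,
            "y": y,
        }
    )
    return table.loc[ridx].dropna()
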