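"""Regionalize asynchrony hotspots and test the latitudinal gradient.

Hotspot pixels (top 20% here, for a small scene) are clustered with DBSCAN,
bounded with alpha-complex hulls, and each region gets an MMRR of
phenological distance on climatic and geodesic distance (beta_c, beta_g).
A pooled regression of beta_c on mean |latitude|, with a permutation Monte
Carlo, quantifies the latitudinal gradient gamma_lat in isoclimatic
asynchrony.
"""

import numpy as np

import phenoasync as pa

grid = pa.GridSpec(20, 20, 0.05, (0.5, 0.0))
scene = pa.gen_harmonic_field(grid, "gradient", noise_sd=0.0, seed=9,
                              climate_coupling=0.8)
fits = pa.fit_cube(scene.cube)
valid = np.array([f.ok for f in fits])
curves = pa.standardized_curves(fits, valid)
amap = pa.asynchrony_map(curves, grid, 16.0, valid=valid, min_neighbors=10)

records = pa.run_ensemble(
    amap.value, curves, scene.climate, grid, valid=valid,
    hotspot_percentile=80.0, eps_grid=(0.2, 0.35, 0.5),
    min_samples_grid=(0.3, 0.45, 0.6), alpha_grid=(0.25, 0.75, 1.25),
    n_points=40, n_perm=49, seed=0,
)
regions = [r for rec in records for r in rec.regions]
print(f"{len(records)} ensemble records, {len(regions)} regions")
print("beta_c range:", round(min(r.beta_c for r in regions), 3), "to",
      round(max(r.beta_c for r in regions), 3))

# On a real-scale ensemble the gradient pools hundreds of regions spanning
# 60 degrees of latitude; here we demonstrate the inference on a synthetic
# ensemble with a planted slope of 0.006 per degree.
rng = np.random.default_rng(1)
lats = rng.uniform(0, 60, 150)
planted = [
    pa.RegionHull(polygon=None, member_pixels=np.array([]), mean_abs_lat=la,
                  beta_c=0.1 + 0.006 * la + 0.05 * rng.standard_normal())
    for la in lats
]
grad = pa.latitudinal_gradient([pa.EnsembleRecord(1, 1, 1, planted)],
                               n_mc=999, seed=0)
print(f"gamma_lat = {grad.gamma_lat:.5f} (planted 0.006), "
      f"OLS p = {grad.ols_p:.2e}, Monte-Carlo p = {grad.mc_p}")

# gamma_lat recovers the planted slope and the permutation Monte Carlo
# (robust to the non-independence of overlapping ensemble regions) agrees
# that the gradient is significant.
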