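"""Map spatial phenological asynchrony over a phase-discontinuity scene.

Asynchrony is the slope of phenological distance (between standardized
phenocycles) on geodesic distance within each pixel's neighborhood, zeroed
where the slope is not significant (P > 0.01).  A sharp phase discontinuity
produces a ridge of high asynchrony along its flanks.
"""

import numpy as np

import phenoasync as pa

grid = pa.GridSpec(10, 20, 0.05, (0.5, 0.0))
doy = np.arange(1, 366)
cols = np.tile(np.arange(20), 10)
rng = np.random.default_rng(4)
phase = np.pi * (cols >= 10) + 0.03 * cols + 0.03 * rng.standard_normal(cols.size)
raw = np.cos(2 * np.pi * doy[None, :] / 365 - phase[:, None])
curves = (raw - raw.mean(1, keepdims=True)) / raw.std(1, keepdims=True)

amap = pa.asynchrony_map(curves, grid, radius_km=25.0, min_neighbors=15)
v = amap.value.reshape(10, 20)
print("column-mean asynchrony (1e-4 standardized units / m):")
print(np.array2string(np.nanmean(v, axis=0) * 1e4, precision=2, suppress_small=True))

bigger = pa.asynchrony_map(curves, grid, radius_km=35.0, min_neighbors=15)
print("map agreement R^2 between 25 km and 35 km radii:",
      round(pa.map_agreement(amap, bigger), 3))

# The largest values cluster around columns 6-13 — the flanks of the phase
# discontinuity at column 10 — while the uniform flanks stay at ~0.  The
# inter-neighborhood R^2 shows the map is not an artifact of one radius.
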