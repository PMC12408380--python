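"""Exercise every branch of the pixel-exclusion pipeline.

Builds a one-row scene in which each pixel violates a different rule —
invalid land cover, an agricultural/non-agricultural switch, >50% missing
data, a half-year availability gap (low Pielou evenness), a dead December
(monthly floor), a constant series (insignificant regression) and an
always-agricultural pixel — and prints the first-failing reason per pixel.
"""

import phenoasync as pa

grid = pa.GridSpec(1, 7, 0.05, (0.5, 0.0))
scene = pa.gen_harmonic_field(grid, "uniform", noise_sd=0.0, seed=0)
lc = scene.landcover.copy()
lc[:, 1] = 13            # urban: invalid cover
lc[0, 2] = 12            # cropland one year, grassland later: switch
lc[:, 6] = 12            # always cropland: agricultural mask
cube = pa.inject_missingness(scene.cube, 0.6, None, seed=1, pixels=[3])
cube = pa.inject_missingness(cube, 0.0, (213, 365), seed=0, pixels=[4])
cube.values[:, 5] = 1.0  # constant: permutation test ties -> excluded

mask = pa.apply_filters(cube, lc, seed=0)
for p, (keep, reason) in enumerate(zip(mask.keep, mask.reason)):
    print(f"pixel {p}: {'kept' if keep else 'excluded: ' + reason}")
print("accounting:", mask.counts())

# Pixel 0 survives; each other pixel is charged exactly the violation it
# was built with, mirroring the per-filter accounting of the mapping
# workflow.
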