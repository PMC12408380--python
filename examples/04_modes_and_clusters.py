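"""Decompose global phenocycle variation into weighted EOF modes.

Standardized phenocycles are decomposed on the sqrt(cos latitude)-weighted
covariance; the top modes are min-max scaled, transformed across the ITCZ
so either hemisphere's matching seasons share colours, composed as RGB, and
summarized by mini-batch k-means phenocycle clusters.
"""

import numpy as np

import phenoasync as pa

grid = pa.GridSpec(20, 20, 0.05, (5.0, 0.0))
scene = pa.gen_harmonic_field(grid, "discontinuity", noise_sd=0.01, seed=2,
                              semiannual_amplitude=0.05, coef_noise_sd=0.02)
fits = pa.fit_cube(scene.cube)
valid = np.array([f.ok for f in fits])
curves = pa.standardized_curves(fits, valid)
lat, lon = grid.pixel_latlon()

eof = pa.weighted_eof(curves[valid], lat[valid], n_modes=3)
print("variance fractions:", np.round(eof.variance_fraction, 4))

w = pa.itcz_weight(lat[valid], 0.0, band_deg=10.0)
scaled = [(m - m.min()) / np.ptp(m) for m in eof.modes]
rgb = pa.rgb_composite(*[pa.transform_eof(m, w) for m in scaled])

labels, inertia, centers, med_rgb = pa.cluster_phenocycles(
    curves[valid], k=2, seed=0, rgb=rgb
)
print("cluster sizes:", np.bincount(labels), " inertia:", round(inertia, 1))
print("cluster median RGB:\n", np.round(med_rgb, 3))

scan = pa.inertia_scan(curves[valid], range(1, 7), seed=0, n_restarts=4)
print("scree (inertia by k):", {k: round(v, 1) for k, v in scan.items()})

# Mode 1 captures the two-phase structure (most of the variance); the two
# k-means clusters recover the discontinuity's halves, and the scree drops
# sharply from k=1 to k=2 then flattens — the scene truly has two regimes.
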