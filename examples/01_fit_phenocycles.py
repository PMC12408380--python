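"""Fit characteristic annual phenocycles to a synthetic vegetation-index cube.

Generates a small scene whose pixels follow a west-to-east phase gradient,
fits the harmonic model (intercept + trend + annual + semiannual terms) to
each pixel's time series, and reconstructs the detrended 365-day curves.
"""

import numpy as np

import phenoasync as pa

grid = pa.GridSpec(n_rows=1, n_cols=8, cell_size=0.05, origin=(0.5, 0.0))
scene = pa.gen_harmonic_field(grid, "gradient", noise_sd=0.01, seed=0,
                              phase_start=0.5, phase_span=np.pi)

fits = pa.fit_cube(scene.cube)
print("pixel  peak_day  r2      unimodality")
for p, fit in enumerate(fits):
    curve = pa.reconstruct_phenocycle(fit)
    peak = int(np.argmax(curve.values)) + 1
    print(f"{p:5d}  {peak:8d}  {fit.r2:.4f}  {pa.unimodality_index(curve):.3f}")

# The peak day advances monotonically along the row: the planted phase
# gradient shifts the growing season later from west to east.  r2 near 1
# reflects the low observation noise; unimodality 1.0 means a single annual
# peak (no semiannual component was planted).
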