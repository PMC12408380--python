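# phenoasync

Land-surface phenology (LSP) analysis: harmonic phenocycle fitting, spatial
asynchrony mapping, and allochrony-by-allopatry statistics.

Terrestrial plant communities differ widely in the timing and shape of
their annual growth rhythms. `phenoasync` implements a season-agnostic
pipeline for studying that variation from gridded vegetation-index time
series (NIR_V, SIF, NDVI, or any proxy of photosynthetic activity), aimed
at landscape ecologists and evolutionary biogeographers who want to connect
mapped seasonality to organismal timing — flowering dates, genetic
divergence, even crop harvest calendars.

## The model

Each pixel's time series is modelled by harmonic regression,

```
y = β₀ + βt·t + β₁ sin(t_ann) + β₂ cos(t_ann) + β₃ sin(t_sem) + β₄ cos(t_sem) + ε
```

where `t` is days since the series start and `t_ann = 2π·doy/365`,
`t_sem = 4π·doy/365` are the day of year at the annual and semiannual
frequencies. Dropping the trend `βt` and evaluating the fit on days 1–365
yields the pixel's **phenocycle** — its characteristic, detrended annual
curve, flexible enough for unimodal and (evenly or unevenly) bimodal
seasonality without over-fitting higher frequencies.

Around this core the package provides:

* **Quality filters** — land-cover validity, agricultural switches, >50%
  missingness, Pielou-evenness of monthly availability, a 10% monthly
  floor, and a 20-permutation Monte-Carlo significance screen on the fit
  R², each exclusion charged to its first failing rule.
* **Spatial asynchrony** — per pixel, the OLS slope of 365-dimensional
  Euclidean distance between *standardized* phenocycles on geodesic
  distance to all neighbors within a radius (50/100/150 km at global
  scale), zeroed where the slope has P > 0.01; tiled computation is
  bit-identical to untiled.
* **Visualization** — √cos(latitude)-weighted EOF decomposition of the
  phenocycle field, the ITCZ transform `w·EOF + (1−w)·(1−EOF)` for
  interhemispheric comparability, RGB composition, and mini-batch k-means
  phenocycle clustering.
* **Isoclimatic-asynchrony ensemble** — DBSCAN + alpha-complex hulls over
  asynchrony hotspots (≥95th percentile), per-region MMRR
  `phenology ~ β_c·climate + β_g·geography` on standardized distance
  matrices, repeated over a 3×3×3 hyperparameter grid, and a
  permutation Monte Carlo on the latitudinal gradient γ_lat of β_c.
* **Driver attribution** — a random-forest model of asynchrony on climate-
  seasonality asynchrony and physiographic covariates, with exactly
  additive per-pixel attributions and the predominance index
  `(|a_ppt| − |a_tmin|)/(|a_ppt| + |a_tmin|)` within hotspots.
* **Allochrony by allopatry** — peak classification of weekly flowering
  histograms, per-taxon MMRR of circular flowering-date distance on
  phenocycle distance with BH-FDR across taxa, genetic MMRR with k = 2
  cluster concordance, and a Jaccard permutation test for categorical
  harvest seasons.
* **Synthetic data** — generators for every input (harmonic scenes with
  uniform/gradient/discontinuity phase fields, structured missingness,
  land-cover mosaics, coupled or decoupled climate layers, flowering and
  genetic point sets) with known ground truth, so the whole pipeline is
  testable without downloads.

## Worked example

```python
import numpy as np
import phenoasync as pa

grid = pa.GridSpec(n_rows=1, n_cols=8, cell_size=0.05, origin=(0.5, 0.0))
scene = pa.gen_harmonic_field(grid, "gradient", noise_sd=0.01, seed=0,
                              phase_start=0.5, phase_span=np.pi)
for p, fit in enumerate(pa.fit_cube(scene.cube)):
    curve = pa.reconstruct_phenocycle(fit)
    print(p, int(np.argmax(curve.values)) + 1, round(fit.r2, 4))
```

prints

```
0 29 0.9925
1 54 0.9921
2 80 0.9928
3 107 0.9908
4 133 0.9907
5 160 0.9917
6 185 0.9900
7 211 0.9916
```

— the day of peak greenness advances monotonically along the planted
west-to-east phase gradient (about 26 days per pixel, π radians across the
row), and the fit explains ~99% of each pixel's variance at the simulated
noise level. The `examples/` directory has one short script per
capability, ending with `examples/07_full_pipeline.py`, which runs every
stage on the bundled synthetic scene and writes all artifacts (NetCDF
layers, CSV accounting, GeoJSON hulls, JSON summaries with provenance).

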