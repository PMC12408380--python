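# Methods

This note documents the models, conventions and design choices behind
`phenoasync`, in the order the pipeline runs them.

## Harmonic phenocycle model

A pixel's vegetation-index series is fit by ordinary least squares to an
intercept, a linear trend (per day), and annual plus semiannual harmonic
pairs. Circular time uses a 365-day year: `t_ann = 2π·doy/365` and
`t_sem = 4π·doy/365`, with `doy` 1-based (so day 365 closes the annual
cycle exactly and the semiannual term completes cycles at mid-year and
year end). Leap days in real calendars are folded in by assigning Feb 29
to day 59 and shifting later days down by one; synthetic timelines use
365-day years throughout and never contain leap days. The combination of
annual and semiannual terms spans unimodal, evenly bimodal and unevenly
bimodal annual curves while excluding unfounded higher frequencies.

Fitting conventions:

* minimum fit size: 12 available observations spanning at least one year;
  pixels below it are flagged and masked downstream;
* solver: SVD-based least squares; a rank-deficient design resolves to the
  minimum-norm solution and is flagged unless the response itself is
  constant;
* R² of an (up to float round-off) constant response is defined as 0 — a
  relative threshold (SST ≤ 1e-12 of the response's sum of squares)
  decides "constant", which keeps the permutation significance test's tie
  handling exact for constants like 0.7 that are not representable in
  binary floating point;
* the phenocycle is the fitted model without the trend term, evaluated on
  days 1..365; standardized (mean 0, SD 1) and min–max variants serve the
  distance and visualization layers.

NIR_V support: `nirv_from_reflectance` computes NDVI × NIR; values ≤ 0
(high-albedo scenes where productivity is assumed minimal) clamp to the
series' minimum positive value, and zero total reflectance yields an
unavailable observation.

The unimodality index min–max scales a curve, rotates it to start at its
minimum, finds circular local maxima (plateaus collapse to their
midpoint), and reports 1 for a single peak or the absolute difference of
the two tallest peak heights otherwise; it is invariant to rotation of the
input. Note that a pure semiannual cosine sampled at integer days scores
~4e-5 rather than exactly 0, because one of its two peaks falls on a
two-day plateau straddling day 182.5.

## Quality filtering

Pixels are excluded for the *first* failing rule, in this order: invalid
land cover (urban 13, snow/ice 15, barren 16, water 0 exceeding a 10%
subpixel fraction in any year), agricultural/non-agricultural switches
(codes 12/14 vs 1–11; always-agricultural pixels are kept here and removed
only by the later agricultural mask used for asynchrony analyses), more
than 50% missing observations, Pielou evenness `J′ = H′/ln 12` of the 12
monthly mean availabilities below 0.8, any month below 10% mean
availability, and an insignificant harmonic fit.

The evenness screen runs *before* the monthly floor: a long seasonal gap
(several dead months) is an evenness failure of the year as a whole, while
an isolated dead month with otherwise even coverage is a monthly-floor
failure. (With the opposite order the evenness code would be unreachable:
any availability pattern with mean ≥ 0.5 and every month ≥ 10% has
J′ ≥ ≈0.81, a consequence of entropy minimization over that constraint
set.)

The significance screen permutes a pixel's values across its available
time steps (timestamps fixed), refits, and takes the empirical P as the
proportion of 20 permutations whose R² is **≥** the observed R² — ties
count against the pixel, so a constant series is excluded with P = 1, and
i.i.d. noise is kept at rate 1/21 ≈ 4.8%. Each pixel draws its
permutations from an independent stream derived from the master seed.

## Spatial asynchrony

For each focal pixel with at least 30 valid neighbors within the radius,
asynchrony is the OLS slope (intercept included — under noise the
phenological distance need not vanish at zero separation) of the
365-dimensional Euclidean distance between standardized phenocycles on the
geodesic neighbor distance, in units of Δ(standardized index)/m.
Standardization nullifies amplitude so the metric responds to timing; it
makes the map invariant to affine rescaling of the raw curves. The slope
is replaced by zero when its two-tailed t-test P exceeds 0.01 (the
two-tailed choice retains significantly negative slopes as negative; a
clamp-to-zero option exists). All-equal neighbor distances make the
regression degenerate and the pixel is left unset.

Geodesic distances use a vectorized Vincenty inverse on the WGS84
ellipsoid (haversine fallback for non-convergent near-antipodal pairs —
irrelevant at neighborhood scales); pixel positions are cell centers.
Tiled computation passes exact coordinate slices of the parent grid into
each tile (plus a halo covering the radius), so tiled and untiled maps are
bit-identical. Climate-seasonality asynchrony maps are produced by running
the same harmonic + asynchrony machinery on climate series.

A caution observed in synthetic experiments: a mathematically exact step
discontinuity (identical curves within each side) defeats the significance
screen at the boundary itself, because side membership is uncorrelated
with distance in a neighborhood centered on the step; with realistic
within-region variation the flanks of a discontinuity light up as a ridge.

## EOF visualization and clustering

The standardized phenocycle field is decomposed by SVD of the
pixel-weighted, curve-centered data matrix, with weights √cos(latitude)
(the equal-area correction on a lat/lon grid). Mode curves are
orthonormal; variance fractions are non-increasing and sum to one over the
full rank; the centered data are reconstructed exactly from all modes.
Signs are fixed by making the largest-magnitude entry of each mode curve
positive (the weighted mean of the centered scores is identically zero, so
it cannot anchor a sign).

Score maps are min–max scaled *before* the interhemispheric transform
`w·EOF + (1−w)·(1−EOF)` (the formula presumes values in [0, 1]), where `w`
rises linearly from 0 to 1 across a 10° band centered on the annual-mean
ITCZ (a constant-latitude ITCZ or a per-longitude curve interpolated from
(lon, lat) samples). Three transformed modes compose into RGB after
per-band min–max scaling.

Phenocycle clustering uses mini-batch k-means (batch 1,024) with 10
seeded restarts, keeping the centers with the best *full-data* inertia so
runs are comparable across k; the scree scan additionally warm-starts each
k from the previous best centers plus the worst-served point, making the
inertia curve provably non-increasing in k. Before global clustering,
pixels south of the ITCZ may be rotated by 182 days (an integer circular
shift) so matching seasons cluster together.

## Distance-matrix statistics

Distance matrices (phenological 365-d, climatic 19-d, geographic geodesic,
genetic allele-frequency, circular flowering-date) are z-scored over their
off-diagonal entries so regression coefficients are comparable β weights.
MMRR vectorizes upper triangles, fits OLS with intercept, and assesses
each |t| against simultaneous row/column permutations of the response
matrix; P values use the (1 + count)/(n_perm + 1) convention with a
default of 999 permutations (the floor 1/1000 guards against reporting
zero). The flowering-date distance is the shorter of forward and backward
time, min(|Δ|, 365 − |Δ|) ∈ [0, 182.5].

The Jaccard index of two labelings counts unordered point pairs
co-assigned in both, only one, or the other partition
(J = n_both/(n_a + n_b + n_both); pairs co-assigned in neither are
ignored; all-singleton partitions agree with J = 1 by convention). Its
permutation test re-clusters after permuting the point-to-curve
assignment, with a per-permutation derived k-means seed, and reports the
literal fraction of null J values ≥ the observed J — this and the
flowering autocorrelation and γ_lat Monte Carlo use the plain fraction
convention, unlike MMRR.

Benjamini–Hochberg adjustment uses `scipy.stats.false_discovery_control`.

## Regionalization ensemble and the latitudinal gradient

Hotspots are pixels at or above the 95th percentile of valid asynchrony
values (ties included). DBSCAN clusters hotspot pixel centers in degree
coordinates; the published hyperparameter magnitudes (eps 2/3.5/5) are
only consistent with degrees. Fractional `min_samples` values
(0.3/0.45/0.6) are read as an absolute count of ⌈v⌉ = 1 by default —
DBSCAN's parameter is an integer ≥ 1 and the intended semantics of the
fractional grid cannot be recovered — with a fraction-of-points mode
available. Hulls are alpha complexes: Delaunay triangles with circumradius
< 1/α, unioned; α → 0 recovers the convex hull, larger α admits concavity
and holes.

Each region draws up to 1,000 uniform points (rejection sampling over the
hull's bounding box, restricted to valid pixels), builds standardized
phenological/climatic/geodesic distance matrices, and fits
`phenology ~ β_c·climate + β_g·geography`. The ensemble reruns the whole
regionalization for all 27 grid combinations; records may share pixels.
γ_lat is the pooled OLS slope of β_c on mean |latitude| (one point per
region); because regions overlap across ensemble records, inference uses a
two-tailed permutation Monte Carlo on the latitude vector (fraction of
permuted |slopes| ≥ the observed).

## Driver model and attribution

The driver table holds the LSP asynchrony response, five climate-
seasonality asynchrony covariates, median ruggedness, vegetation
structural entropy (Shannon bits over the 5-class reclassification:
forest 1–5, shrubland 6–7, savanna 8–9, grassland 10, wetland 11, within a
100-km neighborhood including the focal pixel), 100-km neighborhood means
of land-use-change proportion and fire frequency, and Web-Mercator x/y in
metres. Covariates are screened for pairwise collinearity (R² < 0.75).

The forest uses the tuned configuration — 300 trees, 80% observation
sampling, terminal nodes of 1, 5 candidate split variables — on a
quartile-stratified 60% training split, scored on the 40% holdout (the
tuning grid is exposed as a utility but not run by default). Observation
sampling is with replacement (the implementation's only subsampling mode);
at an 0.8 fraction the practical difference from without-replacement
sampling is negligible for 300-tree forests.

Attributions are exact path-based additive decompositions of the tree
predictions: each split credits the change in node value to the split
feature, so per-sample attributions plus the base value reconstruct the
forest prediction to float precision — the property the predominance
summary relies on. Covariate importance is the mean absolute attribution.
The predominance index `(|a_ppt| − |a_tmin|)/(|a_ppt| + |a_tmin|)` is
antisymmetric under covariate swap, bounded in [−1, 1], undefined where
both attributions vanish, and mapped only within ≥85th-percentile
asynchrony hotspots.

## Flowering classification and the allochrony tests

Weekly histograms (week = ⌊(doy−1)/7⌋ capped at 51) are rotated so the
minimum of their *circularly smoothed* annual cycle leads — anchoring on
the raw first minimum is unstable under tied zero counts and can split a
wrap-around peak across the series ends — then smoothed with a 5-week-
bandwidth Gaussian kernel (Nadaraya–Watson, truncated and renormalized at
the ends rather than reflected, so the curve stays on the count scale).
Peaks are strict local maxima of the smoothed curve at least 60% of its
value range above its minimum. Seasonality is tested by comparing the
|lag-1 autocorrelation| of the rotated histogram against 100 permutations
of it: the statistic is computed on the histogram, not the smoothed curve,
because the smoother imposes autocorrelation ≈ 1 on *any* permutation and
would leave the test without power. Classes: `no_signal` when the
empirical P exceeds 0.05 (zero peaks reported), `unimodal` for exactly one
peak, `non_unimodal` otherwise; batch analyses retain every non-unimodal
class. The output is invariant to all 52 rotations of the input.

Taxa spanning beyond both 10° N and 10° S are dropped (their signal would
only reflect opposite hemispheric seasonality). Observations on masked
pixels resolve to the nearest valid pixel within a two-pixel box, else
drop; a taxon needs 4 mappable observations. Per-taxon MMRRs regress
circular flowering-date distance on phenocycle, climate and geodesic
distance; β_LSP P values are BH-FDR-adjusted across tested taxa. The
genetic analysis accepts allele frequencies (Euclidean distances) or a
precomputed matrix, drops samples on masked pixels, optionally restricts
the climate matrix to a bioclim subset, and summarizes spatial concordance
by the pairwise Jaccard index of k = 2 clusterings by phenocycle and by
genetic-distance rows. Harvest categories delegate to the Jaccard
permutation test with k = 4.

## Synthetic study conditions

The generators plant known truth: per-pixel harmonic coefficients with a
phase field that is uniform, a west–east gradient, or a two-phase
discontinuity (optionally quantized into k discrete phase regions),
baseline 0.3 and annual amplitude 0.15 in index units, 4-day sampling over
two 365-day years, i.i.d. observation noise (default experiments use
0.01–0.02, ~10% of amplitude), and optional spatially autocorrelated
coefficient perturbations built by Gaussian-smoothing white noise (any
autocorrelated field serves; σ = 3 cells by default). Each of the 19
climate layers mixes the phenology phase with weight c (the coupling) and
an independent autocorrelated field with weight √(1−c²), so c = 1 makes
climate a deterministic function of phase and c = 0 decouples them — the
two endpoints of the isoclimatic-asynchrony contrast. Flowering dates are
the local true peak day plus circular Gaussian noise (default 8 days);
genetic demes differ by 0.4·divergence per locus against 0.02 within-deme
noise; harvest categories are equal-count phase bands. All generators are
pure functions of their arguments including the seed.

What the synthetic conditions do **not** emulate: sensor physics and
BRDF/orbital effects, spatially correlated *observation* noise, realistic
land-cover textures, interannual phenological variability, or the taxon
sampling biases of community observation platforms. Passing tests
therefore demonstrate the correctness and operating characteristics of the
algorithms under the stated model, not the field performance of the
method on satellite archives.

## Problem sizes and scaled study conditions

The bundled end-to-end study runs on a 40 × 40 grid of 0.05° pixels
(~2° × 2°) with neighborhood radii 25/35/45 km, a DBSCAN eps grid of
0.2/0.35/0.5° (the published 2/3.5/5° eps values exceed the scene), 120
points per region, and 199/199/500 permutation draws; `RunConfig`'s
defaults keep the published constants (radii 50/100/150 km, eps 2/3.5/5,
1,000 draws) for full-scale data. Acceptance-level property checks use
100-series oracle panels, 600–1,000 null pixels for the significance
screen, 120–200 null MMRR datasets with 199 permutations, a 150-region
planted gradient, and a 30 + 30 (script) or 50 + 50 (test suite) taxon
panel for power and size.

## Known limitations

* Published global quantities (EOF variance fractions, the global driver
  model R², γ_lat = 0.00612) depend on multi-decade satellite archives and
  are demonstrated here only as recovered *procedure* behavior on
  synthetic conditions.
* The asynchrony slope is scale-dependent across radii by construction;
  maps are internally comparable, not across radii.
* Mini-batch k-means inertia is guaranteed monotone in k only through the
  warm-started scree scan, not for isolated calls.
* The per-pixel loops in neighborhood operations are pure Python over
  vectorized geodesic kernels; the target is the ~10³–10⁴-pixel scenes of
  the synthetic studies, not global mosaics.
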