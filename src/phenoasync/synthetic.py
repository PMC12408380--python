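"""Synthetic scenes and point sets with known ground truth.

Everything the pipeline consumes can be generated here: per-pixel harmonic
time series with planted coefficients, spatially autocorrelated noise
fields, seasonally structured missingness, categorical land-cover mosaics,
bioclimatic layers coupled to (or decoupled from) the phenology phase,
flowering observations drawn near local phenocycle peaks, and two-deme
allele-frequency divergence aligned with the phenology clusters.

All generators are pure functions of their arguments including ``seed``:
the same call yields a bit-identical result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import GridSpec, TimeSeriesCube, timeline_365
from .harmonic import DAYS_PER_YEAR, build_design_matrix

__all__ = [
    "SyntheticScene",
    "SyntheticPointSet",
    "gen_harmonic_field",
    "inject_missingness",
    "gen_flowering_taxon",
    "gen_genetic_samples",
    "gen_category_points",
]

PHASE_PATTERNS = ("uniform", "gradient", "discontinuity")


@dataclass
class SyntheticScene:
    """A generated world: cube + truth + land cover + climate."""

    grid: GridSpec
    cube: TimeSeriesCube
    true_coefficients: np.ndarray  # (n_pixels, 6): b0, bt, b1..b4
    phase: np.ndarray  # (n_pixels,) annual phase in radians
    labels: np.ndarray  # (n_pixels,) int ground-truth cluster
    landcover: np.ndarray  # (n_years, n_pixels) IGBP codes 0..16
    landcover_invalid_frac: np.ndarray  # (n_years, n_pixels) in [0, 1]
    climate: np.ndarray  # (n_pixels, 19)
    seed: int

    def peak_day(self) -> np.ndarray:
        """Day of year (1..365) when each pixel's true phenocycle peaks."""
        doy = np.arange(1, DAYS_PER_YEAR + 1)
        ann = 2 * np.pi * doy / DAYS_PER_YEAR
        sem = 4 * np.pi * doy / DAYS_PER_YEAR
        basis = np.column_stack(
            [np.ones_like(ann), np.sin(ann), np.cos(ann), np.sin(sem), np.cos(sem)]
        )
        coef = self.true_coefficients[:, [0, 2, 3, 4, 5]]  # trend excluded
        curves = coef @ basis.T
        return np.argmax(curves, axis=1) + 1

    def usable_pixels(self) -> np.ndarray:
        """Pixels with at least one available observation."""
        return np.flatnonzero(self.cube.available.any(axis=0))


@dataclass
class SyntheticPointSet:
    """Point observations tied to scene pixels, with ground-truth labels."""

    coords: np.ndarray  # (n, 2) lat, lon
    payload: np.ndarray  # doy ints | allele-frequency rows | category ints
    truth_labels: np.ndarray  # (n,)
    kind: str  # flowering | genetic | category
    pixels: np.ndarray  # (n,) pixel index into the source scene


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated field (smoothed white noise)."""
    w = rng.standard_normal(shape)
    if sigma_cells > 0:
        w = ndimage.gaussian_filter(w, sigma_cells, mode="wrap")
    sd = w.std()
    return (w - w.mean()) / (sd if sd > 0 else 1.0)


def gen_harmonic_field(
    grid: GridSpec,
    phase_pattern: str = "gradient",
    noise_sd: float = 0.0,
    trend: float = 0.0,
    seed: int = 0,
    *,
    n_years: int = 2,
    interval_days: int = 4,
    baseline: float = 0.3,
    amplitude: float = 0.15,
    semiannual_amplitude: float = 0.0,
    phase_start: float = np.pi,
    phase_span: float = np.pi,
    coef_noise_sd: float = 0.0,
    coef_noise_sigma_cells: float = 3.0,
    climate_coupling: float = 1.0,
    landcover_code: int = 8,
    n_landcover_years: int = 3,
    phase_levels: int | None = None,
) -> SyntheticScene:
    """Generate a scene whose pixels follow planted harmonic coefficients.

    The annual harmonic is parameterized by a per-pixel phase ``phi`` so
    that the annual term equals ``amplitude * cos(t_ann - phi)`` (peak near
    day ``phi * 365 / 2pi``).  ``phase_pattern`` controls the spatial phase
    field:

    ``uniform``
        every pixel at ``phase_start``;
    ``gradient``
        linear west-to-east ramp spanning ``phase_span`` radians;
    ``discontinuity``
        western half at ``phase_start``, eastern half offset by
        ``phase_span`` (two ground-truth clusters).

    ``noise_sd`` is i.i.d. observation noise on the cube; ``coef_noise_sd``
    adds spatially autocorrelated perturbations (smoothed white noise) to
    the planted coefficient fields themselves.  One bioclim layer tracks
    the phase with weight ``climate_coupling``; the remaining 18 layers are
    independent autocorrelated fields.
    """
    if phase_pattern not in PHASE_PATTERNS:
        raise ValueError(
            f"unknown phase_pattern {phase_pattern!r}; choose one of {PHASE_PATTERNS}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_pix = grid.n_pixels
    cols = np.tile(np.arange(grid.n_cols), grid.n_rows)

    if phase_pattern == "uniform":
        phase = np.full(n_pix, phase_start, dtype=float)
        labels = np.zeros(n_pix, dtype=int)
    elif phase_pattern == "gradient":
        frac = cols / max(grid.n_cols - 1, 1)
        phase = phase_start + phase_span * frac
        labels = (frac >= 0.5).astype(int)
    else:  # discontinuity
        east = cols >= grid.n_cols // 2
        phase = np.where(east, phase_start + phase_span, phase_start)
        labels = east.astype(int)
    if phase_levels is not None:
        # quantize to equal-count bands: discrete phase regions instead of
        # a smooth ramp (e.g. 4 harvest-season regions)
        if phase_levels < 2:
            raise ValueError("phase_levels must be >= 2")
        edges = np.quantile(phase, np.linspace(0, 1, phase_levels + 1)[1:-1])
        band = np.searchsorted(edges, phase, side="right")
        centers = np.array([phase[band == b].mean() for b in range(phase_levels)])
        phase = centers[band]
        labels = band

    coef = np.zeros((n_pix, 6))
    coef[:, 0] = baseline
    coef[:, 1] = trend
    coef[:, 2] = amplitude * np.sin(phase)
    coef[:, 3] = amplitude * np.cos(phase)
    coef[:, 4] = semiannual_amplitude * np.sin(2 * phase)
    coef[:, 5] = semiannual_amplitude * np.cos(2 * phase)
    if coef_noise_sd > 0:
        for j in (0, 2, 3):
            f = _smooth_field(rng, grid.shape, coef_noise_sigma_cells).ravel()
            coef[:, j] = coef[:, j] + coef_noise_sd * f

    t_days, doy = timeline_365(n_years=n_years, interval_days=interval_days)
    X = build_design_matrix(t_days, doy)
    values = X @ coef.T
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(values.shape)
    cube = TimeSeriesCube(grid=grid, t_days=t_days, doy=doy, values=values)

    landcover = np.full((n_landcover_years, n_pix), landcover_code, dtype=int)
    lc_frac = np.zeros((n_landcover_years, n_pix))

    c = float(np.clip(climate_coupling, 0.0, 1.0))
    phase_norm = (phase - phase.mean()) / (phase.std() if phase.std() > 0 else 1.0)
    climate = np.empty((n_pix, 19))
    # every bioclim layer mixes the phenology phase (weight c) with its own
    # autocorrelated field, so climatic distance tracks phase distance when
    # coupled (c = 1: a deterministic function of phase) and is independent
    # of it when decoupled (c = 0)
    for j in range(19):
        noise = _smooth_field(rng, grid.shape, coef_noise_sigma_cells).ravel()
        climate[:, j] = c * phase_norm + np.sqrt(max(0.0, 1 - c * c)) * noise

    return SyntheticScene(
        grid=grid,
        cube=cube,
        true_coefficients=coef,
        phase=phase,
        labels=labels,
        landcover=landcover,
        landcover_invalid_frac=lc_frac,
        climate=climate,
        seed=seed,
    )


def inject_missingness(
    cube: TimeSeriesCube,
    frac_random: float = 0.0,
    seasonal_gap: tuple[int, int] | None = None,
    seed: int = 0,
    *,
    pixels: np.ndarray | None = None,
) -> TimeSeriesCube:
    """Return a copy of ``cube`` with observations knocked out.

    ``frac_random`` removes that fraction of observations independently at
    random; ``seasonal_gap=(start_doy, end_doy)`` removes every observation
    whose day of year falls in the (inclusive, possibly year-wrapping)
    window.  ``pixels`` restricts the damage to a pixel subset.  Values are
    untouched where still available.
    """
    if not 0.0 <= frac_random <= 1.0:
        raise ValueError("frac_random must lie in [0, 1]")
    out = cube.copy()
    pix = np.arange(cube.n_pixels) if pixels is None else np.asarray(pixels, dtype=int)
    rng = np.random.default_rng(seed)
    if frac_random > 0:
        drop = rng.random((cube.n_times, pix.size)) < frac_random
        sub = out.available[:, pix]
        sub &= ~drop
        out.available[:, pix] = sub
    if seasonal_gap is not None:
        start, end = seasonal_gap
        if not (1 <= start <= 365 and 1 <= end <= 365):
            raise ValueError("seasonal_gap days must lie in [1, 365]")
        if start <= end:
            in_gap = (cube.doy >= start) & (cube.doy <= end)
        else:  # wraps across the year boundary
            in_gap = (cube.doy >= start) | (cube.doy <= end)
        out.available[np.ix_(in_gap, pix)] = False
    return out


def _wrap_doy(days: np.ndarray) -> np.ndarray:
    return ((np.round(days).astype(int) - 1) % DAYS_PER_YEAR) + 1


def gen_flowering_taxon(
    scene: SyntheticScene,
    n_obs: int = 50,
    date_noise_sd_days: float = 0.0,
    bimodal_split: bool = False,
    seed: int = 0,
) -> SyntheticPointSet:
    """Flowering observations with dates near the local phenocycle peak.

    Dates are the pixel's true peak day plus circular Gaussian noise.  With
    ``bimodal_split`` the points are split evenly across the scene's two
    ground-truth phase clusters, so the pooled weekly histogram is bimodal.
    """
    if n_obs < 2:
        raise ValueError("need n_obs >= 2")
    usable = scene.usable_pixels()
    if usable.size == 0:
        raise ValueError("scene is fully masked")
    rng = np.random.default_rng(seed)
    if bimodal_split:
        groups = [usable[scene.labels[usable] == g] for g in (0, 1)]
        if any(g.size == 0 for g in groups):
            raise ValueError("bimodal_split needs a scene with two phase clusters")
        half = n_obs // 2
        pix = np.concatenate(
            [
                rng.choice(groups[0], size=n_obs - half, replace=True),
                rng.choice(groups[1], size=half, replace=True),
            ]
        )
    else:
        pix = rng.choice(usable, size=n_obs, replace=True)
    peak = scene.peak_day()[pix].astype(float)
    if date_noise_sd_days > 0:
        peak = peak + date_noise_sd_days * rng.standard_normal(n_obs)
    doy = _wrap_doy(peak)
    lat, lon = scene.grid.pixel_latlon()
    coords = np.column_stack([lat[pix], lon[pix]])
    return SyntheticPointSet(
        coords=coords,
        payload=doy,
        truth_labels=scene.labels[pix].copy(),
        kind="flowering",
        pixels=pix,
    )


def gen_genetic_samples(
    scene: SyntheticScene,
    n_samples: int = 30,
    n_loci: int = 100,
    divergence: float = 0.5,
    seed: int = 0,
    *,
    freq_noise_sd: float = 0.02,
) -> SyntheticPointSet:
    """Two-deme allele frequencies aligned with the scene's phase clusters.

    Each deme has its own latent allele-frequency vector; the between-deme
    shift at each locus is proportional to ``divergence`` (at 1, demes are
    separated by 0.4 on the frequency scale at every locus, far above the
    within-deme sampling noise).
    """
    if n_loci < 1:
        raise ValueError("need n_loci >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    usable = scene.usable_pixels()
    if usable.size == 0:
        raise ValueError("scene is fully masked")
    n_clusters = np.unique(scene.labels[usable]).size
    if divergence > 0 and n_clusters < 2:
        raise ValueError("divergence > 0 requires a scene with two phase clusters")
    rng = np.random.default_rng(seed)
    if n_clusters >= 2:
        groups = [usable[scene.labels[usable] == g] for g in (0, 1)]
        half = n_samples // 2
        pix = np.concatenate(
            [
                rng.choice(groups[0], size=n_samples - half, replace=True),
                rng.choice(groups[1], size=half, replace=True),
            ]
        )
    else:
        pix = rng.choice(usable, size=n_samples, replace=True)
    demes = scene.labels[pix]
    base = rng.uniform(0.3, 0.7, size=n_loci)
    shift = 0.4 * divergence * rng.choice([-1.0, 1.0], size=n_loci)
    centers = np.vstack([base - shift / 2.0, base + shift / 2.0])
    freqs = centers[demes] + freq_noise_sd * rng.standard_normal((pix.size, n_loci))
    freqs = np.clip(freqs, 0.0, 1.0)
    lat, lon = scene.grid.pixel_latlon()
    coords = np.column_stack([lat[pix], lon[pix]])
    return SyntheticPointSet(
        coords=coords,
        payload=freqs,
        truth_labels=demes.copy(),
        kind="genetic",
        pixels=pix,
    )


def gen_category_points(
    scene: SyntheticScene,
    n_obs: int = 80,
    n_categories: int = 4,
    seed: int = 0,
) -> SyntheticPointSet:
    """Points labelled by phase quantile band (e.g. harvest-season regions).

    Pixels are binned into ``n_categories`` equal-count bands of the true
    phase field; each point carries its band as both payload and truth
    label.  On a gradient scene this emulates a mapped mosaic of
    seasonality categories.
    """
    if n_categories < 2:
        raise ValueError("need n_categories >= 2")
    usable = scene.usable_pixels()
    if usable.size == 0:
        raise ValueError("scene is fully masked")
    rng = np.random.default_rng(seed)
    phase = scene.phase[usable]
    qs = np.quantile(phase, np.linspace(0, 1, n_categories + 1)[1:-1])
    cats = np.searchsorted(qs, phase, side="right")
    pix = rng.choice(usable, size=n_obs, replace=True)
    cat_of = dict(zip(usable.tolist(), cats.tolist()))
    labels = np.array([cat_of[p] for p in pix.tolist()], dtype=int)
    lat, lon = scene.grid.pixel_latlon()
    coords = np.column_stack([lat[pix], lon[pix]])
    return SyntheticPointSet(
        coords=coords,
        payload=labels.copy(),
        truth_labels=labels.copy(),
        kind="category",
        pixels=pix,
    )
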