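"""Species-level allochrony-by-allopatry analyses.

Three tests of whether mapped land-surface phenology predicts reproductive
timing:

* **Flowering** — taxa with significantly non-unimodal range-wide flowering
  histograms are tested, one MMRR per taxon, for a correlation between
  circular flowering-date distances and phenocycle distances independent of
  climate and geography, with Benjamini-Hochberg FDR control across taxa.
* **Genetics** — genetic distances (Euclidean allele-frequency distances or
  a precomputed matrix) are regressed on phenocycle, climate and geographic
  distances; k = 2 clusterings by phenocycle and by genetic distance rows
  summarize the spatial concordance.
* **Harvest** — categorical harvest-season labels are compared with a
  k = 4 phenocycle clustering through the Jaccard permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .grid import GridSpec
from .matrix_stats import (
    DistanceMatrix,
    JaccardResult,
    MmrrResult,
    bh_fdr,
    circular_day_dm,
    euclidean_dm,
    geodesic_dm,
    jaccard_perm_test,
    mmrr,
    pairwise_jaccard,
    standardize_dm,
)

__all__ = [
    "PeakClassification",
    "weekly_histogram",
    "classify_flowering",
    "latitude_span_filter",
    "map_observations_to_pixels",
    "flowering_mmrr",
    "flowering_batch",
    "genetic_mmrr",
    "harvest_concordance",
]

N_WEEKS = 52


@dataclass
class PeakClassification:
    n_peaks: int
    autocorr_obs: float
    autocorr_p: float
    klass: str  # unimodal | non_unimodal | no_signal


def weekly_histogram(doy) -> np.ndarray:
    """52-bin weekly histogram of days of year (week = floor((doy-1)/7), capped)."""
    d = np.asarray(doy, dtype=int)
    if np.any((d < 1) | (d > 365)):
        raise ValueError("day of year must lie in [1, 365]")
    weeks = np.minimum((d - 1) // 7, N_WEEKS - 1)
    return np.bincount(weeks, minlength=N_WEEKS).astype(float)


def _gaussian_smooth(values: np.ndarray, bandwidth: float) -> np.ndarray:
    """Kernel smoothing on the (linear, truncated) week axis.

    Nadaraya-Watson with a Gaussian kernel: the smoother is renormalized at
    the series ends rather than reflected or wrapped, so it stays on the
    scale of the input counts.
    """
    idx = np.arange(values.size, dtype=float)
    w = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / bandwidth) ** 2)
    return (w @ values) / w.sum(axis=1)


def _circular_smooth(values: np.ndarray, bandwidth: float) -> np.ndarray:
    n = values.size
    idx = np.arange(n, dtype=float)
    diff = np.abs(idx[:, None] - idx[None, :])
    dist = np.minimum(diff, n - diff)
    w = np.exp(-0.5 * (dist / bandwidth) ** 2)
    return (w @ values) / w.sum(axis=1)


def _rotation_anchor(h: np.ndarray, bandwidth: float) -> int:
    """Week to rotate into first position: the circular-smoothed minimum.

    Anchoring on the smoothed minimum (rather than the first raw zero,
    whose location is arbitrary under ties) centers the rotation in the
    emptiest part of the year, so no flowering peak straddles the ends of
    the rotated series.
    """
    return int(np.argmin(_circular_smooth(h, bandwidth)))


def _lag1_autocorr(x: np.ndarray) -> float:
    a, b = x[:-1], x[1:]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def classify_flowering(
    histogram_52,
    n_perm: int = 100,
    seed: int = 0,
    *,
    bandwidth_weeks: float = 5.0,
    height_frac: float = 0.6,
    alpha: float = 0.05,
) -> PeakClassification:
    """Count significant flowering-time peaks in a weekly histogram.

    The histogram is rotated so the minimum of its circularly smoothed
    annual cycle leads — no peak then straddles the year boundary, and the
    result is invariant to the starting week of the input — then smoothed with a 5-week-bandwidth
    Gaussian kernel, and smoothed peaks reaching at least ``height_frac``
    of the smoothed curve's value range above its minimum are counted.
    Seasonality itself is tested by comparing the |lag-1 autocorrelation|
    of the rotated histogram with the same statistic under ``n_perm``
    permutations of it (the autocorrelation of the *smoothed* curve is
    dominated by the smoother and carries no information about seasonal
    concentration); when the resulting empirical P exceeds ``alpha`` the
    taxon has no significant seasonal signal and zero peaks are reported.
    """
    h = np.asarray(histogram_52, dtype=float)
    if h.shape != (N_WEEKS,):
        raise ValueError("expected a 52-week histogram")
    if np.any(h < 0) or not np.all(np.isfinite(h)):
        raise ValueError("histogram counts must be finite and non-negative")
    if h.sum() == 0:
        raise ValueError("all-zero histogram")
    rot = np.roll(h, -_rotation_anchor(h, bandwidth_weeks))
    smooth = _gaussian_smooth(rot, bandwidth_weeks)
    obs = abs(_lag1_autocorr(rot))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = abs(_lag1_autocorr(rng.permutation(rot)))
    p = float(np.mean(null >= obs))

    from scipy.signal import find_peaks

    threshold = smooth.min() + height_frac * np.ptp(smooth)
    peaks, _ = find_peaks(smooth, height=threshold)
    n_peaks = int(peaks.size)
    if p > alpha:
        return PeakClassification(0, obs, p, "no_signal")
    klass = "unimodal" if n_peaks == 1 else "non_unimodal"
    return PeakClassification(n_peaks, obs, p, klass)


def latitude_span_filter(lats) -> bool:
    """Drop taxa whose samples extend beyond both 10 N and 10 S."""
    la = np.asarray(lats, dtype=float)
    if la.size == 0:
        raise ValueError("need at least one observation")
    return not (la.max() > 10.0 and la.min() < -10.0)


def map_observations_to_pixels(
    coords: np.ndarray,
    grid: GridSpec,
    valid: np.ndarray,
    *,
    search_radius_px: int = 2,
) -> np.ndarray:
    """Pixel index per observation, or -1 when unmappable.

    Observations on masked pixels resolve to the nearest valid pixel within
    a box ``search_radius_px`` pixels wide around the containing cell
    (nearest by center-to-center degree offset), otherwise they are
    dropped.
    """
    coords = np.asarray(coords, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    out = np.full(coords.shape[0], -1, dtype=int)
    for i, (lat, lon) in enumerate(coords):
        pix = grid.pixel_of(lat, lon)
        if pix is None:
            continue
        if valid[pix]:
            out[i] = pix
            continue
        r0, c0 = grid.rowcol(pix)
        best, best_d = -1, np.inf
        for dr in range(-search_radius_px, search_radius_px + 1):
            for dc in range(-search_radius_px, search_radius_px + 1):
                r, c = r0 + dr, c0 + dc
                if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                    continue
                q = r * grid.n_cols + c
                if not valid[q]:
                    continue
                d = np.hypot(grid.lats[r] - lat, grid.lons[c] - lon)
                if d < best_d:
                    best, best_d = q, d
        out[i] = best
    return out


def _standardized_predictors(coords, pixels, curves_std, climate_std):
    phen = standardize_dm(euclidean_dm(curves_std[pixels], kind="phenological"))
    clim = standardize_dm(euclidean_dm(climate_std[pixels], kind="climatic"))
    geog = standardize_dm(geodesic_dm(coords))
    return phen, clim, geog


def flowering_mmrr(
    coords: np.ndarray,
    doy: np.ndarray,
    curves_std: np.ndarray,
    climate_std: np.ndarray,
    grid: GridSpec,
    valid: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> MmrrResult | None:
    """Per-taxon MMRR: flowering_date ~ LSP + climate + geography.

    Flowering-date distances are circular day-of-year distances; predictor
    matrices are the standardized phenocycle, climate and geodesic distance
    matrices at the mapped observation pixels.  Returns None when fewer
    than 4 observations can be mapped onto valid pixels.
    """
    coords = np.asarray(coords, dtype=float)
    doy = np.asarray(doy, dtype=int)
    pix = map_observations_to_pixels(coords, grid, valid)
    ok = pix >= 0
    if ok.sum() < 4:
        return None
    coords, doy, pix = coords[ok], doy[ok], pix[ok]
    response = standardize_dm(circular_day_dm(doy))
    phen, clim, geog = _standardized_predictors(coords, pix, curves_std, climate_std)
    return mmrr(
        response, {"lsp": phen, "climate": clim, "geography": geog},
        n_perm=n_perm, seed=seed,
    )


def flowering_batch(
    taxa: dict[str, tuple[np.ndarray, np.ndarray]],
    curves_std: np.ndarray,
    climate_std: np.ndarray,
    grid: GridSpec,
    valid: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    *,
    classify: bool = True,
) -> pd.DataFrame:
    """Classify, filter and test a panel of taxa; BH-FDR across tested taxa.

    ``taxa`` maps taxon id to ``(coords, doy)``.  Taxa classified unimodal,
    failing the latitude-span filter, or with too few mappable observations
    are recorded with the reason they dropped out.  Returns one row per
    taxon with beta_lsp, raw permutation P and FDR-adjusted q.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for (name, (coords, doy)), child in zip(taxa.items(), ss.spawn(len(taxa))):
        coords = np.asarray(coords, dtype=float)
        doy = np.asarray(doy, dtype=int)
        row = {"taxon": name, "n_obs": len(doy), "status": "tested",
               "beta_lsp": np.nan, "p_lsp": np.nan}
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        if classify:
            cls = classify_flowering(weekly_histogram(doy), seed=sub_seed)
            row["class"] = cls.klass
            if cls.klass == "unimodal":
                row["status"] = "unimodal"
                rows.append(row)
                continue
        if not latitude_span_filter(coords[:, 0]):
            row["status"] = "latitude_span"
            rows.append(row)
            continue
        res = flowering_mmrr(
            coords, doy, curves_std, climate_std, grid, valid,
            n_perm=n_perm, seed=sub_seed,
        )
        if res is None:
            row["status"] = "insufficient_data"
            rows.append(row)
            continue
        row["beta_lsp"] = res.coefficients["lsp"]
        row["p_lsp"] = res.perm_p["lsp"]
        rows.append(row)
    df = pd.DataFrame(rows)
    tested = df["status"] == "tested"
    df["q_lsp"] = np.nan
    if tested.any():
        df.loc[tested, "q_lsp"] = bh_fdr(df.loc[tested, "p_lsp"].to_numpy())
    return df


def genetic_mmrr(
    coords: np.ndarray,
    curves_std: np.ndarray,
    climate_std: np.ndarray,
    grid: GridSpec,
    valid: np.ndarray,
    *,
    allele_freqs: np.ndarray | None = None,
    genetic_dm_values: np.ndarray | None = None,
    bioclim_subset: list[int] | None = None,
    n_perm: int = 999,
    seed: int = 0,
):
    """Genetic MMRR with phenology/genetic cluster concordance.

    Genetic distances come either from allele frequencies (Euclidean) or a
    precomputed square matrix.  Samples on masked pixels are dropped.
    ``bioclim_subset`` selects climate layers (e.g. the four classic
    temperature/precipitation summaries).  Returns ``(MmrrResult,
    labels_phen, labels_gen, JaccardResult)``.
    """
    coords = np.asarray(coords, dtype=float)
    if (allele_freqs is None) == (genetic_dm_values is None):
        raise ValueError("supply exactly one of allele_freqs or genetic_dm_values")
    pix_all = map_observations_to_pixels(coords, grid, valid, search_radius_px=0)
    ok = pix_all >= 0
    if ok.sum() < 4:
        raise ValueError("fewer than 4 samples on valid pixels")
    coords = coords[ok]
    pix = pix_all[ok]
    if allele_freqs is not None:
        gen = euclidean_dm(np.asarray(allele_freqs, dtype=float)[ok], kind="genetic")
    else:
        g = np.asarray(genetic_dm_values, dtype=float)[np.ix_(ok, ok)]
        gen = DistanceMatrix(g, kind="genetic")
    clim_layers = climate_std if bioclim_subset is None else climate_std[:, bioclim_subset]
    phen = standardize_dm(euclidean_dm(curves_std[pix], kind="phenological"))
    clim = standardize_dm(euclidean_dm(clim_layers[pix], kind="climatic"))
    geog = standardize_dm(geodesic_dm(coords))
    response = standardize_dm(gen)
    res = mmrr(
        response, {"lsp": phen, "climate": clim, "geography": geog},
        n_perm=n_perm, seed=seed,
    )
    curves_at = curves_std[pix]
    if np.unique(curves_at, axis=0).shape[0] < 2:
        raise ValueError("fewer than 2 distinct phenocycles: clustering rejected")
    rs = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    labels_phen = KMeans(n_clusters=2, n_init=10, random_state=rs).fit_predict(curves_at)
    labels_gen = KMeans(n_clusters=2, n_init=10, random_state=rs).fit_predict(gen.values)
    jac = pairwise_jaccard(labels_phen, labels_gen)
    return res, labels_phen, labels_gen, jac


def harvest_concordance(
    coords: np.ndarray,
    harvest_labels: np.ndarray,
    curves_std: np.ndarray,
    grid: GridSpec,
    valid: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    k: int = 4,
) -> JaccardResult:
    """Jaccard permutation test of harvest categories vs phenocycle clusters."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(harvest_labels)
    pix = map_observations_to_pixels(coords, grid, valid, search_radius_px=0)
    ok = pix >= 0
    if not ok.any():
        raise ValueError("all points fall on masked pixels")
    return jaccard_perm_test(labels[ok], curves_std[pix[ok]], k=k, n_perm=n_perm, seed=seed)
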