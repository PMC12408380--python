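"""Harmonic regression of seasonal time series and phenocycle descriptors.

Each pixel's time series ``y`` is modelled as

    y = b0 + bt*t + b1*sin(t_ann) + b2*cos(t_ann) + b3*sin(t_sem) + b4*cos(t_sem) + e

where ``t`` is linear time in days since the series start and ``t_ann`` /
``t_sem`` are the day of year in radians at the annual and semiannual
frequencies (2*pi at day 365 for the annual term; 2*pi at mid-year and
4*pi == 2*pi at year end for the semiannual term).  The model is rich
enough to represent unimodal, evenly bimodal and unevenly bimodal annual
curves while excluding unfounded higher frequencies.

The characteristic annual curve (the *phenocycle*) is the detrended model
evaluated on days 1..365: the trend coefficient ``bt`` is dropped so the
curve represents the long-term average annual pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HarmonicFit",
    "Phenocycle",
    "nirv_from_reflectance",
    "build_design_matrix",
    "fit_harmonic",
    "fit_cube",
    "reconstruct_phenocycle",
    "standardize",
    "minmax",
    "unimodality_index",
    "rotate_days",
    "fit_agreement",
]

MIN_FIT_OBS = 12
DAYS_PER_YEAR = 365
_DOY = np.arange(1, DAYS_PER_YEAR + 1)


@dataclass(frozen=True)
class HarmonicFit:
    """Fitted harmonic-regression coefficients for one pixel."""

    b0: float
    bt: float
    b1: float
    b2: float
    b3: float
    b4: float
    r2: float
    n_obs: int
    empirical_p: float | None = None
    ok: bool = True

    @property
    def coefficients(self) -> np.ndarray:
        """(b0, bt, b1, b2, b3, b4) in design-matrix column order."""
        return np.array([self.b0, self.bt, self.b1, self.b2, self.b3, self.b4])


@dataclass(frozen=True)
class Phenocycle:
    """A 365-value characteristic annual curve, day-of-year 1..365."""

    values: np.ndarray
    flavor: str = "raw"  # raw | standardized | minmax

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (DAYS_PER_YEAR,):
            raise ValueError("phenocycle must have exactly 365 values")
        object.__setattr__(self, "values", v)


def nirv_from_reflectance(red, nir, series_min_positive: float):
    """NIR_V: the product of NDVI and total NIR reflectance.

    Values <= 0 (high-albedo scenes, assumed non-vegetated) are clamped to
    the series' minimum positive value.  Where ``red + nir == 0`` the NDVI
    is undefined and NaN is returned (the observation is unavailable).
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if np.any((red < 0) | (red > 1) | (nir < 0) | (nir > 1)):
        raise ValueError("reflectances must lie in [0, 1]")
    if series_min_positive <= 0:
        raise ValueError("series_min_positive must be positive")
    denom = red + nir
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / np.where(denom == 0, 1, denom), np.nan)
    nirv = ndvi * nir
    nirv = np.where(np.isnan(nirv), np.nan, np.where(nirv <= 0, series_min_positive, nirv))
    if np.ndim(nirv) == 0:
        return float(nirv)
    return nirv


def build_design_matrix(t_days, doy) -> np.ndarray:
    """Columns [1, t, sin t_ann, cos t_ann, sin t_sem, cos t_sem]."""
    t = np.asarray(t_days, dtype=float)
    d = np.asarray(doy, dtype=float)
    if t.size == 0:
        raise ValueError("empty timeline")
    ann = 2.0 * np.pi * d / DAYS_PER_YEAR
    sem = 4.0 * np.pi * d / DAYS_PER_YEAR
    return np.column_stack(
        [np.ones_like(t), t, np.sin(ann), np.cos(ann), np.sin(sem), np.cos(sem)]
    )


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    # relative guard: an (up to float round-off) constant response has no
    # variance to explain, and its R^2 is defined as 0
    if sst <= 1e-12 * max(float(np.sum(y**2)), 1e-300):
        return 0.0
    ssr = float(np.sum((y - fitted) ** 2))
    return max(0.0, 1.0 - ssr / sst)


def fit_harmonic(series, available, t_days, doy, *, min_obs: int = MIN_FIT_OBS) -> HarmonicFit:
    """Ordinary least squares fit of the harmonic model for one pixel.

    Requires at least ``min_obs`` available observations spanning a full
    year; otherwise (or on a rank-deficient design) the fit is flagged
    ``ok=False`` and the pixel should be masked downstream.  Collinear
    designs resolve to the minimum-norm solution via SVD-based ``lstsq``.
    """
    y = np.asarray(series, dtype=float)
    avail = np.asarray(available, dtype=bool)
    t = np.asarray(t_days, dtype=float)
    d = np.asarray(doy, dtype=int)
    ya = y[avail]
    ta = t[avail]
    da = d[avail]
    if ya.size < min_obs or (ta.size and (ta.max() - ta.min()) < DAYS_PER_YEAR - 1):
        return HarmonicFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 0.0, int(ya.size), ok=False)
    X = build_design_matrix(ta, da)
    beta, _, rank, _ = np.linalg.lstsq(X, ya, rcond=None)
    r2 = _r_squared(ya, X @ beta)
    fit = HarmonicFit(*beta, r2=r2, n_obs=int(ya.size), ok=True)
    if rank < X.shape[1]:
        # constant series etc.: keep minimum-norm coefficients but flag if
        # the deficiency comes from degenerate sampling rather than from a
        # degenerate response
        if np.ptp(ya) > 0:
            fit = replace(fit, ok=False)
    return fit


def fit_cube(cube, *, min_obs: int = MIN_FIT_OBS) -> list[HarmonicFit]:
    """Fit every pixel of a :class:`~phenoasync.grid.TimeSeriesCube`.

    Pixels sharing an availability pattern share one pseudoinverse, which
    makes fully observed cubes effectively a single matrix product.
    """
    X_full = build_design_matrix(cube.t_days, cube.doy)
    fits: list[HarmonicFit] = [None] * cube.n_pixels  # type: ignore[list-item]
    patterns: dict[bytes, list[int]] = {}
    for p in range(cube.n_pixels):
        patterns.setdefault(cube.available[:, p].tobytes(), []).append(p)
    for key, pixels in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        ta = cube.t_days[mask]
        n_av = int(mask.sum())
        if n_av < min_obs or n_av == 0 or (ta.max() - ta.min()) < DAYS_PER_YEAR - 1:
            for p in pixels:
                fits[p] = HarmonicFit(
                    np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 0.0, n_av, ok=False
                )
            continue
        Xa = X_full[mask]
        pinv = np.linalg.pinv(Xa)
        Y = cube.values[mask][:, pixels]
        B = pinv @ Y
        fitted = Xa @ B
        for j, p in enumerate(pixels):
            r2 = _r_squared(Y[:, j], fitted[:, j])
            fits[p] = HarmonicFit(*B[:, j], r2=r2, n_obs=n_av, ok=True)
    return fits


def reconstruct_phenocycle(fit: HarmonicFit) -> Phenocycle:
    """Evaluate the detrended model on days 1..365 (trend excluded)."""
    if not fit.ok:
        raise ValueError("cannot reconstruct a failed fit")
    ann = 2.0 * np.pi * _DOY / DAYS_PER_YEAR
    sem = 4.0 * np.pi * _DOY / DAYS_PER_YEAR
    v = (
        fit.b0
        + fit.b1 * np.sin(ann)
        + fit.b2 * np.cos(ann)
        + fit.b3 * np.sin(sem)
        + fit.b4 * np.cos(sem)
    )
    return Phenocycle(v, "raw")


def standardize(curve: Phenocycle) -> Phenocycle:
    """Zero-mean, unit-SD version of a curve (amplitude nullified)."""
    v = curve.values
    sd = v.std()
    if sd == 0.0:
        raise ValueError("cannot standardize a constant curve")
    return Phenocycle((v - v.mean()) / sd, "standardized")


def minmax(curve: Phenocycle) -> Phenocycle:
    """Min-max scaled version of a curve, attaining both 0 and 1."""
    v = curve.values
    rng = np.ptp(v)
    if rng == 0.0:
        raise ValueError("cannot min-max scale a constant curve")
    return Phenocycle((v - v.min()) / rng, "minmax")


def rotate_days(curve: Phenocycle, offset_days: int) -> Phenocycle:
    """Circular shift by ``offset_days``; day d moves to day d+offset mod 365."""
    offset = int(offset_days)
    if not 0 <= offset < DAYS_PER_YEAR:
        raise ValueError("offset must lie in [0, 365)")
    return Phenocycle(np.roll(curve.values, offset), curve.flavor)


def _local_maxima_circular(v: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a circular sequence.

    Plateaus collapse to their (left-biased) midpoint.
    """
    n = v.size
    idx = []
    i = 0
    while i < n:
        j = i
        while v[(j + 1) % n] == v[i] and j < i + n:
            j += 1
        if j >= i + n:  # constant sequence
            return np.array([], dtype=int)
        left = v[(i - 1) % n]
        right = v[(j + 1) % n]
        if v[i] > left and v[i] > right:
            idx.append(((i + j) // 2) % n)
        i = j + 1
    return np.array(sorted(idx), dtype=int)


def unimodality_index(curve: Phenocycle) -> float:
    """Where the curve lies between evenly bimodal (0) and unimodal (1).

    The curve is min-max scaled and rotated to start at its minimum (so no
    peak straddles the year boundary), local maxima are extracted, and the
    absolute difference of the two tallest peak heights is returned; curves
    with a single peak score exactly 1.  The construction is invariant to
    circular rotation of the input.
    """
    mm = minmax(curve).values
    start = int(np.argmin(mm))
    rot = np.roll(mm, -start)
    peaks = _local_maxima_circular(rot)
    if peaks.size <= 1:
        return 1.0
    heights = np.sort(rot[peaks])[::-1]
    return float(abs(heights[0] - heights[1]))


def fit_agreement(curve_a: Phenocycle, curve_b: Phenocycle) -> float:
    """Squared Pearson correlation between two 365-day curves."""
    a, b = curve_a.values, curve_b.values
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("fit agreement undefined for constant curves")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
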