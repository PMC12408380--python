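"""Pixel-exclusion pipeline: land cover, missingness, evenness, significance.

Pixels are excluded for the first failing reason, applied in this order:

1. ``invalid_lc``      — >10% invalid land cover (urban 13, snow/ice 15,
                         barren 16, water 0) in any year;
2. ``ag_switch``       — switched between agricultural (12, 14) and
                         non-agricultural (1..11) classes across years;
3. ``missing_50``      — more than 50% of the time series unavailable;
4. ``evenness``        — Pielou evenness of monthly availability < 0.8
                         (catches long, seasonally repeating gaps);
5. ``monthly_10``      — some calendar month has < 10% mean availability;
6. ``insignificant``   — harmonic-regression R^2 not significant under the
                         Monte-Carlo permutation test (empirical P >= 0.05);
7. ``agricultural``    — modal class 12 or 14 (asynchrony analyses only).

The evenness screen runs before the monthly screen because a pixel whose
availability is concentrated into part of the year fails the entropy
criterion as a whole even when no single month quite reaches zero; a pixel
with an isolated dead month but otherwise even coverage fails only the
monthly criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import TimeSeriesCube
from .harmonic import build_design_matrix, fit_harmonic

__all__ = [
    "PixelMask",
    "REASONS",
    "INVALID_LC",
    "AGRICULTURAL_LC",
    "landcover_filter",
    "missingness_filter",
    "pielou_evenness",
    "monthly_availability",
    "significance_filter",
    "significance_filter_cube",
    "agricultural_mask",
    "apply_filters",
]

REASONS = (
    "invalid_lc",
    "ag_switch",
    "missing_50",
    "evenness",
    "monthly_10",
    "insignificant",
    "agricultural",
)

INVALID_LC = frozenset({0, 13, 15, 16})
AGRICULTURAL_LC = frozenset({12, 14})
_NONAG_LC = frozenset(range(1, 12))

# month lengths on the 365-day calendar
_MONTH_LEN = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_OF_DOY = np.repeat(np.arange(12), _MONTH_LEN)  # index by doy-1


@dataclass
class PixelMask:
    """Keep/exclude decision per pixel with the first failing reason."""

    keep: np.ndarray
    reason: np.ndarray  # '' for kept pixels

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=object)

    @classmethod
    def all_keep(cls, n: int) -> "PixelMask":
        return cls(np.ones(n, dtype=bool), np.full(n, "", dtype=object))

    def exclude(self, idx, reason: str) -> None:
        """Record ``reason`` for pixels in ``idx`` not yet excluded."""
        idx = np.asarray(idx)
        fresh = idx[self.keep[idx]]
        self.keep[fresh] = False
        self.reason[fresh] = reason

    def counts(self) -> dict[str, int]:
        out = {r: int(np.sum(self.reason == r)) for r in REASONS}
        out["kept"] = int(self.keep.sum())
        return out


def _check_codes(landcover_by_year: np.ndarray) -> None:
    bad = np.setdiff1d(np.unique(landcover_by_year), np.arange(17))
    if bad.size:
        raise ValueError(f"unknown IGBP land-cover codes: {bad.tolist()}")


def landcover_filter(
    landcover_by_year: np.ndarray,
    invalid_frac: np.ndarray | None = None,
    *,
    frac_threshold: float = 0.10,
) -> PixelMask:
    """Exclude invalid-cover pixels and agricultural/non-agricultural switches.

    ``landcover_by_year`` is ``(n_years, n_pixels)`` integer IGBP codes.
    ``invalid_frac`` optionally gives the invalid-cover subpixel fraction
    per pixel-year (computed from finer-grained data); when omitted it is
    taken as 1 where the code itself is invalid and 0 elsewhere.  A pixel
    is dropped when any year's invalid fraction exceeds ``frac_threshold``,
    or when its agricultural status changes across years.  Pixels that are
    always agricultural are kept here (the stricter agricultural mask is a
    separate, later step).
    """
    lc = np.asarray(landcover_by_year, dtype=int)
    _check_codes(lc)
    n_years, n_pix = lc.shape
    if invalid_frac is None:
        invalid_frac = np.isin(lc, list(INVALID_LC)).astype(float)
    invalid_frac = np.asarray(invalid_frac, dtype=float)
    mask = PixelMask.all_keep(n_pix)
    mask.exclude(np.flatnonzero((invalid_frac > frac_threshold).any(axis=0)), "invalid_lc")
    is_ag = np.isin(lc, list(AGRICULTURAL_LC))
    is_nonag = np.isin(lc, list(_NONAG_LC))
    switched = is_ag.any(axis=0) & is_nonag.any(axis=0)
    mask.exclude(np.flatnonzero(switched), "ag_switch")
    return mask


def monthly_availability(available: np.ndarray, doy: np.ndarray) -> np.ndarray:
    """Mean availability per calendar month; (12,) or (12, n_pixels).

    Months with no scheduled observation at all report NaN.
    """
    av = np.asarray(available, dtype=float)
    months = _MONTH_OF_DOY[np.asarray(doy, dtype=int) - 1]
    shape = (12,) if av.ndim == 1 else (12, av.shape[1])
    out = np.full(shape, np.nan)
    for m in range(12):
        sel = months == m
        if sel.any():
            out[m] = av[sel].mean(axis=0)
    return out


def pielou_evenness(monthly_avail) -> float:
    """Pielou's J' = H'/H'_max of the 12 monthly availability proportions.

    The availabilities are normalized to sum to one; Shannon entropy runs
    over the positive proportions, and H'_max = ln 12.
    """
    v = np.asarray(monthly_avail, dtype=float)
    if v.shape != (12,):
        raise ValueError("expected 12 monthly availability values")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("availabilities must be finite and non-negative")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero availability")
    p = v / total
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(12.0)


def missingness_filter(
    cube: TimeSeriesCube,
    *,
    max_missing_frac: float = 0.5,
    min_monthly: float = 0.10,
    min_evenness: float = 0.8,
) -> PixelMask:
    """Exclude data-deficient pixels (missing_50, evenness, monthly_10)."""
    mask = PixelMask.all_keep(cube.n_pixels)
    missing = 1.0 - cube.available.mean(axis=0)
    mask.exclude(np.flatnonzero(missing > max_missing_frac), "missing_50")
    monthly = monthly_availability(cube.available, cube.doy)
    with np.errstate(invalid="ignore"):
        total = np.nansum(monthly, axis=0)
    for p in np.flatnonzero(mask.keep):
        if total[p] == 0:
            mask.exclude([p], "evenness")
            continue
        col = monthly[:, p]
        col = np.where(np.isnan(col), 0.0, col)
        if pielou_evenness(col) < min_evenness:
            mask.exclude([p], "evenness")
    low_month = np.nanmin(monthly, axis=0) < min_monthly
    mask.exclude(np.flatnonzero(low_month), "monthly_10")
    return mask


def significance_filter(
    series,
    available,
    t_days,
    doy,
    n_perm: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, bool]:
    """Monte-Carlo significance of a pixel's harmonic fit.

    The time-series values are permuted across the available time steps
    (timestamps fixed), the regression refitted, and the empirical P value
    taken as the proportion of permutations whose R^2 meets or exceeds the
    observed R^2 (ties count against the pixel).  Keep iff P < ``alpha``;
    with 20 permutations this keeps only pixels whose observed fit beats
    every permutation.
    """
    y = np.asarray(series, dtype=float)
    avail = np.asarray(available, dtype=bool)
    fit = fit_harmonic(y, avail, t_days, doy)
    if not fit.ok:
        return 1.0, False
    ya = y[avail]
    sst = float(np.sum((ya - ya.mean()) ** 2))
    if sst <= 1e-12 * max(float(np.sum(ya**2)), 1e-300):
        # constant series: every permutation ties the observed fit
        return 1.0, False
    X = build_design_matrix(np.asarray(t_days)[avail], np.asarray(doy)[avail])
    pinv = np.linalg.pinv(X)
    rng = np.random.default_rng(seed)
    n = ya.size
    # observed and permuted R^2 share one formula so ties are exact
    r2_obs = 1.0 - float(np.sum((ya - X @ (pinv @ ya)) ** 2)) / sst
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = ya[perm_idx.T]  # (n, n_perm)
    fitted = X @ (pinv @ Yp)
    ssr = np.sum((Yp - fitted) ** 2, axis=0)
    r2_perm = 1.0 - ssr / sst
    p = float(np.sum(r2_perm >= r2_obs)) / n_perm
    return p, p < alpha


def significance_filter_cube(
    cube: TimeSeriesCube,
    n_perm: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, PixelMask]:
    """Per-pixel significance filter over a cube.

    Each pixel draws its permutations from an independent stream derived
    from ``seed``, so keep/exclude events are independent across pixels.
    Returns the empirical P values and the mask (reason ``insignificant``).
    """
    ps = np.ones(cube.n_pixels)
    mask = PixelMask.all_keep(cube.n_pixels)
    for p in range(cube.n_pixels):
        pv, keep = significance_filter(
            cube.values[:, p], cube.available[:, p], cube.t_days, cube.doy,
            n_perm=n_perm, alpha=alpha, seed=np.random.SeedSequence([seed, p]),
        )
        ps[p] = pv
        if not keep:
            mask.exclude([p], "insignificant")
    return ps, mask


def agricultural_mask(landcover_by_year: np.ndarray) -> PixelMask:
    """Exclude pixels whose modal class is agricultural (12 or 14)."""
    lc = np.asarray(landcover_by_year, dtype=int)
    _check_codes(lc)
    n_pix = lc.shape[1]
    modal = np.empty(n_pix, dtype=int)
    for p in range(n_pix):
        vals, counts = np.unique(lc[:, p], return_counts=True)
        modal[p] = vals[np.argmax(counts)]
    mask = PixelMask.all_keep(n_pix)
    mask.exclude(np.flatnonzero(np.isin(modal, list(AGRICULTURAL_LC))), "agricultural")
    return mask


def apply_filters(
    cube: TimeSeriesCube,
    landcover_by_year: np.ndarray,
    *,
    invalid_frac: np.ndarray | None = None,
    include_agricultural_mask: bool = True,
    n_perm: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> PixelMask:
    """Run the full exclusion pipeline in order; first failure wins.

    The significance filter is only evaluated for pixels that survive the
    earlier screens (it needs a successful fit on adequately sampled data).
    """
    mask = landcover_filter(landcover_by_year, invalid_frac)
    m2 = missingness_filter(cube)
    for reason in ("missing_50", "evenness", "monthly_10"):
        mask.exclude(np.flatnonzero(m2.reason == reason), reason)
    for p in np.flatnonzero(mask.keep):
        _, keep = significance_filter(
            cube.values[:, p], cube.available[:, p], cube.t_days, cube.doy,
            n_perm=n_perm, alpha=alpha, seed=np.random.SeedSequence([seed, p]),
        )
        if not keep:
            mask.exclude([p], "insignificant")
    if include_agricultural_mask:
        m4 = agricultural_mask(landcover_by_year)
        mask.exclude(np.flatnonzero(~m4.keep), "agricultural")
    return mask
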