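"""Spatial phenological asynchrony: the neighborhood slope metric.

For a focal pixel, asynchrony is the slope of the OLS regression of
365-dimensional Euclidean distances between *standardized* phenocycles on
the geodesic distances to all neighbors within a radius (50/100/150 km in
the global analysis), set to zero where the slope is not significant
(two-tailed P > 0.01) and left unset where fewer than 30 neighbors are
available.  Standardizing the curves first nullifies amplitude differences
so the metric responds to timing, not productivity.  The same machinery
applies unchanged to harmonic fits of climate seasonality, which is how
climate-asynchrony covariate maps are produced.

Units: distance per metre of separation (Delta standardized units / m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import GridSpec
from .geodesy import geodesic_m, neighborhood

__all__ = [
    "AsynchronyMap",
    "phen_distance",
    "asynchrony_at",
    "asynchrony_map",
    "asynchrony_map_tiled",
    "map_agreement",
]

_STD_TOL = 1e-6


def _check_standardized(curves: np.ndarray) -> None:
    mu = curves.mean(axis=-1)
    sd = curves.std(axis=-1)
    if np.any(np.abs(mu) > _STD_TOL) or np.any(np.abs(sd - 1.0) > _STD_TOL):
        raise ValueError("curves must be standardized (mean 0, SD 1)")


@dataclass
class AsynchronyMap:
    """Per-pixel asynchrony values; NaN where unset (< 30 neighbors or invalid)."""

    value: np.ndarray
    n_neighbors: np.ndarray
    radius_km: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.value)


def phen_distance(curve_a, curve_b) -> float:
    """365-dimensional Euclidean distance between standardized curves."""
    a = np.asarray(getattr(curve_a, "values", curve_a), dtype=float)
    b = np.asarray(getattr(curve_b, "values", curve_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must have equal length")
    _check_standardized(np.vstack([a, b]))
    return float(np.linalg.norm(a - b))


def asynchrony_at(
    focal_curve,
    neighbor_curves,
    geo_dist_m,
    *,
    p_threshold: float = 0.01,
    clamp_negative: bool = False,
    check: bool = True,
) -> float:
    """Slope of phenological distance on geographical distance.

    Returns NaN when the regression is degenerate (all neighbors at one
    distance, or a perfectly constant response making the slope test
    undefined).  A slope whose two-tailed P exceeds ``p_threshold`` is
    reported as zero.  Negative significant slopes are kept by default;
    ``clamp_negative`` zeroes them.
    """
    focal = np.asarray(getattr(focal_curve, "values", focal_curve), dtype=float)
    nb = np.asarray(neighbor_curves, dtype=float)
    d = np.asarray(geo_dist_m, dtype=float)
    if check:
        _check_standardized(np.vstack([focal[None, :], nb]))
    phen_d = np.linalg.norm(nb - focal[None, :], axis=1)
    if np.ptp(d) == 0.0:
        return np.nan
    if np.ptp(phen_d) == 0.0:
        # spatially uniform curve field: zero distances everywhere, slope 0
        return 0.0
    res = stats.linregress(d, phen_d)
    if not np.isfinite(res.slope):
        return np.nan
    if np.isfinite(res.pvalue) and res.pvalue > p_threshold:
        return 0.0
    slope = float(res.slope)
    if clamp_negative and slope < 0:
        return 0.0
    return slope


def asynchrony_map(
    curves: np.ndarray,
    grid: GridSpec,
    radius_km: float,
    *,
    valid: np.ndarray | None = None,
    min_neighbors: int = 30,
    p_threshold: float = 0.01,
    clamp_negative: bool = False,
    row_lats: np.ndarray | None = None,
    col_lons: np.ndarray | None = None,
) -> AsynchronyMap:
    """Pixel-wise asynchrony of a standardized curve stack.

    ``curves`` is ``(n_pixels, n_days)``; ``valid`` marks pixels that
    survived filtering (invalid pixels neither receive values nor serve as
    neighbors).  ``row_lats``/``col_lons`` override the grid coordinates
    (tiled computation passes exact slices of the parent grid's).
    """
    curves = np.asarray(curves, dtype=float)
    if curves.shape[0] != grid.n_pixels:
        raise ValueError("curve stack does not match grid")
    if valid is None:
        valid = np.ones(grid.n_pixels, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if valid.any():
        _check_standardized(curves[valid])
    rl = grid.lats if row_lats is None else np.asarray(row_lats, dtype=float)
    cl = grid.lons if col_lons is None else np.asarray(col_lons, dtype=float)
    lat = np.repeat(rl, grid.n_cols)
    lon = np.tile(cl, grid.n_rows)
    value = np.full(grid.n_pixels, np.nan)
    n_nb = np.zeros(grid.n_pixels, dtype=int)
    for p in np.flatnonzero(valid):
        nb = neighborhood(grid, p, radius_km, row_lats=rl, col_lons=cl)
        nb = nb[valid[nb]]
        n_nb[p] = nb.size
        if nb.size < min_neighbors:
            continue
        d = geodesic_m(lat[p], lon[p], lat[nb], lon[nb])
        value[p] = asynchrony_at(
            curves[p], curves[nb], d,
            p_threshold=p_threshold, clamp_negative=clamp_negative, check=False,
        )
    return AsynchronyMap(value=value, n_neighbors=n_nb, radius_km=float(radius_km))


def asynchrony_map_tiled(
    curves: np.ndarray,
    grid: GridSpec,
    radius_km: float,
    *,
    tile_rows: int,
    halo_rows: int | None = None,
    valid: np.ndarray | None = None,
    min_neighbors: int = 30,
    p_threshold: float = 0.01,
    clamp_negative: bool = False,
) -> AsynchronyMap:
    """Row-tiled computation; bit-identical to the untiled map.

    Each tile of ``tile_rows`` focal rows is processed together with a halo
    of neighbor rows on each side.  The halo must cover the neighborhood
    radius; by default it is derived from ``radius_km`` (with margin), and
    an explicitly passed ``halo_rows`` that falls short is rejected.
    """
    curves = np.asarray(curves, dtype=float)
    if valid is None:
        valid = np.ones(grid.n_pixels, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    # shortest meridian degree is ~110.57 km; one extra row of margin
    need = int(np.ceil(radius_km / (110.0 * grid.cell_size))) + 1
    if halo_rows is None:
        halo_rows = need
    elif halo_rows < need:
        raise ValueError(
            f"halo_rows={halo_rows} cannot cover radius {radius_km} km (need >= {need})"
        )
    value = np.full(grid.n_pixels, np.nan)
    n_nb = np.zeros(grid.n_pixels, dtype=int)
    curves2 = curves.reshape(grid.n_rows, grid.n_cols, -1)
    valid2 = valid.reshape(grid.n_rows, grid.n_cols)
    for r0 in range(0, grid.n_rows, tile_rows):
        r1 = min(r0 + tile_rows, grid.n_rows)
        a = max(0, r0 - halo_rows)
        b = min(grid.n_rows, r1 + halo_rows)
        sub = GridSpec(
            n_rows=b - a,
            n_cols=grid.n_cols,
            cell_size=grid.cell_size,
            origin=(grid.origin[0] - a * grid.cell_size, grid.origin[1]),
        )
        sub_map = asynchrony_map(
            curves2[a:b].reshape(-1, curves.shape[1]),
            sub,
            radius_km,
            valid=valid2[a:b].ravel(),
            min_neighbors=min_neighbors,
            p_threshold=p_threshold,
            clamp_negative=clamp_negative,
            row_lats=grid.lats[a:b],
            col_lons=grid.lons,
        )
        core = slice((r0 - a) * grid.n_cols, (r1 - a) * grid.n_cols)
        dest = slice(r0 * grid.n_cols, r1 * grid.n_cols)
        value[dest] = sub_map.value[core]
        n_nb[dest] = sub_map.n_neighbors[core]
    return AsynchronyMap(value=value, n_neighbors=n_nb, radius_km=float(radius_km))


def map_agreement(map_a, map_b) -> float:
    """R^2 (squared Pearson correlation) over jointly valid pixels."""
    a = np.asarray(getattr(map_a, "value", map_a), dtype=float)
    b = np.asarray(getattr(map_b, "value", map_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    joint = np.isfinite(a) & np.isfinite(b)
    if joint.sum() < 3:
        raise ValueError("fewer than 3 jointly valid pixels")
    av, bv = a[joint], b[joint]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("map agreement undefined for a constant map")
    r = np.corrcoef(av, bv)[0, 1]
    return float(r * r)
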