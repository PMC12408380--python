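"""High-asynchrony regionalization and the isoclimatic-asynchrony ensemble.

Hotspot pixels (>= a percentile of the asynchrony map) are clustered with
DBSCAN, each cluster is bounded by an alpha-complex hull, points are drawn
inside each hull, and an MMRR of phenological distance on climatic and
geographic distance yields per-region beta_c and beta_g.  Rerunning over a
3 x 3 x 3 grid of (eps, min_samples, alpha) gives the ensemble; a pooled
OLS of beta_c on mean absolute latitude, with a permutation Monte Carlo on
the latitude vector, quantifies the latitudinal gradient gamma_lat in
isoclimatic asynchrony.

DBSCAN's ``eps`` is in degrees of lat/lon over pixel center coordinates.
Fractional ``min_samples`` values (the published grid is 0.3/0.45/0.6) are
interpreted as an absolute count of ceil(value); pass
``min_samples_mode='fraction'`` to read them as a fraction of the point
set instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from sklearn.cluster import DBSCAN

from .grid import GridSpec
from .matrix_stats import (
    DistanceMatrix,
    euclidean_dm,
    geodesic_dm,
    mmrr,
    standardize_dm,
)

__all__ = [
    "RegionHull",
    "EnsembleRecord",
    "GradientResult",
    "hotspot_mask",
    "density_cluster",
    "alpha_hull",
    "region_mmrr",
    "run_ensemble",
    "latitudinal_gradient",
    "DEFAULT_EPS_GRID",
    "DEFAULT_MIN_SAMPLES_GRID",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_EPS_GRID = (2.0, 3.5, 5.0)
DEFAULT_MIN_SAMPLES_GRID = (0.3, 0.45, 0.6)
DEFAULT_ALPHA_GRID = (0.25, 0.75, 1.25)


@dataclass
class RegionHull:
    """A delineated high-asynchrony region with its MMRR coefficients."""

    polygon: object  # shapely Polygon / MultiPolygon, lon/lat coordinates
    member_pixels: np.ndarray
    mean_abs_lat: float
    beta_c: float = np.nan
    beta_g: float = np.nan
    perm_p_c: float = np.nan
    perm_p_g: float = np.nan
    n_points: int = 0


@dataclass
class EnsembleRecord:
    eps: float
    min_samples: float
    alpha: float
    regions: list[RegionHull] = field(default_factory=list)


@dataclass
class GradientResult:
    gamma_lat: float
    intercept: float
    ols_p: float
    mc_p: float | None
    n_regions: int


def hotspot_mask(values: np.ndarray, percentile: float, valid: np.ndarray | None = None) -> np.ndarray:
    """Binary mask of pixels at or above the given percentile of valid values."""
    v = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(v)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(v)
    if not valid.any():
        raise ValueError("no valid pixels")
    thr = np.percentile(v[valid], percentile)
    return valid & (v >= thr)


def _resolve_min_samples(min_samples: float, n_points: int, mode: str) -> int:
    if min_samples >= 1:
        return int(min_samples)
    if mode == "fraction":
        return max(1, int(np.ceil(min_samples * n_points)))
    return int(np.ceil(min_samples))  # absolute: ceil(0.3) = 1


def density_cluster(
    points: np.ndarray,
    eps: float,
    min_samples: float,
    *,
    min_samples_mode: str = "absolute",
) -> np.ndarray:
    """DBSCAN labels over point coordinates (-1 = noise)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty(0, dtype=int)
    ms = _resolve_min_samples(min_samples, pts.shape[0], min_samples_mode)
    return DBSCAN(eps=eps, min_samples=ms).fit_predict(pts)


def _circumradius(p: np.ndarray) -> float:
    a = np.linalg.norm(p[1] - p[0])
    b = np.linalg.norm(p[2] - p[1])
    c = np.linalg.norm(p[0] - p[2])
    area2 = abs(
        (p[1][0] - p[0][0]) * (p[2][1] - p[0][1]) - (p[2][0] - p[0][0]) * (p[1][1] - p[0][1])
    )
    if area2 == 0:
        return np.inf
    return a * b * c / (2.0 * area2)


def alpha_hull(points: np.ndarray, alpha: float):
    """Alpha-complex hull: union of Delaunay triangles with circumradius < 1/alpha.

    ``alpha -> 0`` recovers the convex hull; larger alpha admits concavity
    and holes.  Needs at least 3 non-collinear points.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 distinct points")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # qhull degeneracy (collinear etc.)
        raise ValueError(f"degenerate point set: {exc}") from exc
    limit = np.inf if alpha <= 0 else 1.0 / alpha
    keep = [
        Polygon(pts[s])
        for s in tri.simplices
        if _circumradius(pts[s]) < limit
    ]
    if not keep:
        raise ValueError("alpha too large: no triangle passes the circumradius filter")
    return unary_union(keep)


def sample_points_in_region(
    polygon,
    grid: GridSpec,
    valid: np.ndarray,
    n_points: int,
    rng: np.random.Generator,
    *,
    max_tries: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points inside the polygon that land on valid pixels.

    Rejection sampling over the polygon's bounding box; returns (coords
    lat/lon, pixel indices), possibly fewer than ``n_points`` when the
    region is small.
    """
    minx, miny, maxx, maxy = polygon.bounds
    if max_tries is None:
        max_tries = 200 * n_points
    coords, pixels = [], []
    tries = 0
    while len(coords) < n_points and tries < max_tries:
        tries += 1
        lon = rng.uniform(minx, maxx)
        lat = rng.uniform(miny, maxy)
        if not polygon.intersects(Point(lon, lat)):
            continue
        pix = grid.pixel_of(lat, lon)
        if pix is None or not valid[pix]:
            continue
        coords.append((lat, lon))
        pixels.append(pix)
    return np.asarray(coords, dtype=float).reshape(-1, 2), np.asarray(pixels, dtype=int)


def region_mmrr(
    polygon,
    curves_std: np.ndarray,
    climate_std: np.ndarray,
    grid: GridSpec,
    valid: np.ndarray,
    n_points: int = 1000,
    seed: int = 0,
    n_perm: int = 99,
):
    """Per-region MMRR: phenology ~ beta_c * climate + beta_g * geography.

    Draws up to ``n_points`` random points on valid pixels inside the
    region, builds standardized phenological, climatic, and geodesic
    distance matrices, and returns the fitted MmrrResult together with the
    sampled coordinates and pixels.  Returns None when fewer than 4 usable
    points exist.
    """
    rng = np.random.default_rng(seed)
    coords, pixels = sample_points_in_region(polygon, grid, valid, n_points, rng)
    if pixels.size < 4:
        return None
    phen = standardize_dm(euclidean_dm(curves_std[pixels], kind="phenological"))
    clim = standardize_dm(euclidean_dm(climate_std[pixels], kind="climatic"))
    geog = standardize_dm(geodesic_dm(coords))
    try:
        res = mmrr(phen, {"climate": clim, "geography": geog}, n_perm=n_perm, seed=seed)
    except ValueError:
        return None
    return res, coords, pixels


def run_ensemble(
    asynchrony_values: np.ndarray,
    curves_std: np.ndarray,
    climate_std: np.ndarray,
    grid: GridSpec,
    *,
    valid: np.ndarray | None = None,
    hotspot_percentile: float = 95.0,
    eps_grid=DEFAULT_EPS_GRID,
    min_samples_grid=DEFAULT_MIN_SAMPLES_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
    min_samples_mode: str = "absolute",
    n_points: int = 1000,
    n_perm: int = 99,
    seed: int = 0,
) -> list[EnsembleRecord]:
    """The full regionalization + climate-phenology correlation ensemble.

    One record per hyperparameter combination (27 for the default grids);
    regions may overlap between records.  Fully deterministic under a
    fixed master seed.
    """
    if valid is None:
        valid = np.isfinite(np.asarray(asynchrony_values, dtype=float))
    valid = np.asarray(valid, dtype=bool)
    hot = hotspot_mask(asynchrony_values, hotspot_percentile, valid)
    lat, lon = grid.pixel_latlon()
    hot_idx = np.flatnonzero(hot)
    pts = np.column_stack([lon[hot_idx], lat[hot_idx]])  # x=lon, y=lat
    records: list[EnsembleRecord] = []
    ss = np.random.SeedSequence(seed)
    for eps, ms, alpha in itertools.product(eps_grid, min_samples_grid, alpha_grid):
        rec = EnsembleRecord(eps=eps, min_samples=ms, alpha=alpha)
        labels = density_cluster(pts, eps, ms, min_samples_mode=min_samples_mode)
        for c in np.unique(labels[labels >= 0]):
            members = hot_idx[labels == c]
            if members.size < 3:
                continue
            try:
                hull = alpha_hull(pts[labels == c], alpha)
            except ValueError:
                continue
            if hull.is_empty or hull.area == 0:
                continue
            child = ss.spawn(1)[0]
            out = region_mmrr(
                hull, curves_std, climate_std, grid, valid,
                n_points=n_points, seed=int(child.generate_state(1)[0] % (2**31 - 1)),
                n_perm=n_perm,
            )
            region = RegionHull(
                polygon=hull,
                member_pixels=members,
                mean_abs_lat=float(np.mean(np.abs(lat[members]))),
            )
            if out is not None:
                res, coords, pixels = out
                region.beta_c = res.coefficients["climate"]
                region.beta_g = res.coefficients["geography"]
                region.perm_p_c = res.perm_p["climate"]
                region.perm_p_g = res.perm_p["geography"]
                region.n_points = int(pixels.size)
            rec.regions.append(region)
        records.append(rec)
    return records


def latitudinal_gradient(
    records: list[EnsembleRecord] | list[RegionHull],
    n_mc: int = 1000,
    seed: int = 0,
) -> GradientResult:
    """Pooled OLS of beta_c on mean |lat| with a permutation Monte Carlo.

    One point per region across all ensemble records.  The Monte-Carlo P
    is two-tailed: the fraction of latitude-permuted slopes at least as
    extreme in magnitude as the observed gamma_lat (regions overlap across
    records, so the OLS P alone would overstate certainty).
    """
    regions: list[RegionHull] = []
    for item in records:
        regions.extend(item.regions if isinstance(item, EnsembleRecord) else [item])
    regions = [r for r in regions if np.isfinite(r.beta_c)]
    if len(regions) < 3:
        raise ValueError("need at least 3 regions with fitted beta_c")
    x = np.array([r.mean_abs_lat for r in regions])
    y = np.array([r.beta_c for r in regions])
    if np.ptp(x) == 0:
        raise ValueError("no variance in |lat| across regions")
    res = stats.linregress(x, y)
    mc_p = None
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        xc = x - x.mean()
        yc = y - y.mean()
        denom = float(xc @ xc)
        perms = np.stack([rng.permutation(xc) for _ in range(n_mc)])
        slopes = perms @ yc / denom
        mc_p = float(np.mean(np.abs(slopes) >= abs(res.slope)))
    return GradientResult(
        gamma_lat=float(res.slope),
        intercept=float(res.intercept),
        ols_p=float(res.pvalue),
        mc_p=mc_p,
        n_regions=len(regions),
    )
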