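"""Geodesic distances on the WGS84 ellipsoid and grid neighborhood search.

Distances use Vincenty's inverse formula, vectorized over numpy arrays,
with a haversine fallback (authalic sphere) for the rare near-antipodal
pairs where Vincenty's iteration fails to converge.  Accuracy for the
sub-1000-km separations used in neighborhood analyses is well below a
millimetre, which is far beyond what the 0.05-degree pixel geometry needs.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec

__all__ = ["geodesic_m", "neighborhood", "pairwise_geodesic_m"]

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)
# mean Earth radius for the haversine fallback
_R_MEAN = 6371008.8


def _haversine_m(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * _R_MEAN * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geodesic_m(lat1, lon1, lat2, lon2, *, tol: float = 1e-12, max_iter: int = 200):
    """Geodesic distance in metres between points on WGS84.

    All four arguments broadcast against each other.  Returns an array (or
    scalar) of distances in metres.
    """
    lat1, lon1, lat2, lon2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    )
    shape = lat1.shape
    lat1, lon1, lat2, lon2 = (a.ravel() for a in (lat1, lon1, lat2, lon2))

    f = _WGS84_F
    U1 = np.arctan((1.0 - f) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1.0 - f) * np.tan(np.radians(lat2)))
    L = np.radians(lon2 - lon1)
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    sigma = np.zeros_like(lam)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.ones_like(lam)
    active = np.ones(lam.shape, dtype=bool)
    converged = np.zeros(lam.shape, dtype=bool)

    for _ in range(max_iter):
        if not np.any(active):
            break
        sl, cl = np.sin(lam[active]), np.cos(lam[active])
        cu1, su1 = cosU1[active], sinU1[active]
        cu2, su2 = cosU2[active], sinU2[active]
        ss = np.sqrt((cu2 * sl) ** 2 + (cu1 * su2 - su1 * cu2 * cl) ** 2)
        cs = su1 * su2 + cu1 * cu2 * cl
        sig = np.arctan2(ss, cs)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(ss != 0.0, cu1 * cu2 * sl / np.where(ss == 0, 1, ss), 0.0)
        c2a = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            c2sm = np.where(c2a != 0.0, cs - 2.0 * su1 * su2 / np.where(c2a == 0, 1, c2a), 0.0)
        C = f / 16.0 * c2a * (4.0 + f * (4.0 - 3.0 * c2a))
        lam_new = L[active] + (1.0 - C) * f * sin_alpha * (
            sig + C * ss * (c2sm + C * cs * (-1.0 + 2.0 * c2sm**2))
        )
        delta = np.abs(lam_new - lam[active])
        sigma[active] = sig
        sin_sigma[active] = ss
        cos_sigma[active] = cs
        cos_sq_alpha[active] = c2a
        cos2sm[active] = c2sm
        lam[active] = lam_new
        done = delta < tol
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False

    u2 = cos_sq_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    Bc = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    dsig = Bc * sin_sigma * (
        cos2sm
        + Bc
        / 4.0
        * (
            cos_sigma * (-1.0 + 2.0 * cos2sm**2)
            - Bc / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos2sm**2)
        )
    )
    dist = _WGS84_B * A * (sigma - dsig)

    coincident = (lat1 == lat2) & (((lon1 - lon2) % 360.0) == 0.0)
    dist[coincident] = 0.0
    bad = ~converged & ~coincident
    if np.any(bad):
        dist[bad] = _haversine_m(lat1[bad], lon1[bad], lat2[bad], lon2[bad])
    return dist.reshape(shape) if shape else float(dist[0])


def pairwise_geodesic_m(lats, lons) -> np.ndarray:
    """Symmetric matrix of geodesic distances (metres) between points."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    n = lats.shape[0]
    out = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    d = geodesic_m(lats[iu], lons[iu], lats[ju], lons[ju])
    out[iu, ju] = d
    out[ju, iu] = d
    return out


def neighborhood(
    grid: GridSpec,
    focal_pixel: int,
    radius_km: float,
    *,
    row_lats: np.ndarray | None = None,
    col_lons: np.ndarray | None = None,
) -> np.ndarray:
    """Pixels whose centers lie within ``radius_km`` of the focal center.

    The focal pixel itself is excluded.  Candidates are pre-filtered with a
    generous lat/lon bounding window, then confirmed with exact geodesic
    distances.  ``row_lats``/``col_lons`` override the grid's computed
    coordinates (used by tiled computations to keep results bit-identical
    across tile boundaries).
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    grid_lats = grid.lats if row_lats is None else np.asarray(row_lats, dtype=float)
    grid_lons = grid.lons if col_lons is None else np.asarray(col_lons, dtype=float)
    r, c = grid.rowcol(focal_pixel)
    lat0 = grid_lats[r]
    lon0 = grid_lons[c]
    # conservative degree window: shortest meridian degree is ~110.57 km,
    # shortest parallel degree shrinks with cos(lat)
    dlat = radius_km / 110.0
    max_abs_lat = min(89.999, abs(lat0) + dlat)
    dlon = radius_km / max(110.0 * np.cos(np.radians(max_abs_lat)), 1e-6)

    rows = np.flatnonzero(np.abs(grid_lats - lat0) <= dlat + grid.cell_size)
    cols = np.flatnonzero(np.abs(grid_lons - lon0) <= dlon + grid.cell_size)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    cand = (rr * grid.n_cols + cc).ravel()
    cand = cand[cand != focal_pixel]
    if cand.size == 0:
        return cand
    lat_c = grid_lats[cand // grid.n_cols]
    lon_c = grid_lons[cand % grid.n_cols]
    d = geodesic_m(lat0, lon0, lat_c, lon_c)
    return cand[d <= radius_km * 1000.0]
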