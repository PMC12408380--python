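"""Weighted EOF decomposition, ITCZ transform, RGB composition, clustering.

The global set of standardized phenocycles is decomposed into empirical
orthogonal functions (EOFs) of the pixel-weighted covariance, with weights
equal to the square root of the cosine of latitude (the usual equal-area
correction on a lat/lon grid).  Mode score maps can then be min-max scaled,
transformed across the intertropical convergence zone (ITCZ) so that
similar phenologies in either hemisphere render in similar colours, and
composed into an RGB image.  Mini-batch k-means over the standardized
curves yields the characteristic-phenocycle clusters that annotate the
composite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import MiniBatchKMeans

from .harmonic import DAYS_PER_YEAR

__all__ = [
    "EofResult",
    "ItczCurve",
    "weighted_eof",
    "itcz_weight",
    "transform_eof",
    "rgb_composite",
    "cluster_phenocycles",
    "inertia_scan",
]

_STD_TOL = 1e-6


@dataclass
class EofResult:
    """Modes of a weighted EOF decomposition.

    ``modes`` are per-pixel score maps (one row per mode), ``mode_curves``
    the corresponding orthonormal 365-day patterns, ``variance_fraction``
    the non-increasing share of weighted variance per mode.  The centered
    data are recovered exactly as ``modes.T @ mode_curves`` over the full
    rank.
    """

    modes: np.ndarray  # (n_modes, n_pixels)
    mode_curves: np.ndarray  # (n_modes, n_days)
    variance_fraction: np.ndarray  # (n_modes,)
    weights: np.ndarray  # (n_pixels,)
    mean_curve: np.ndarray  # (n_days,)

    def reconstruct(self) -> np.ndarray:
        """Curves rebuilt from all retained modes (plus the mean curve)."""
        return self.modes.T @ self.mode_curves + self.mean_curve


def weighted_eof(curves: np.ndarray, lats: np.ndarray, n_modes: int | None = None) -> EofResult:
    """EOF decomposition of standardized curves with sqrt-cos(lat) weights.

    ``curves`` is ``(n_pixels, n_days)`` with each row standardized.  The
    weighted mean curve is removed, rows are scaled by w = sqrt(cos lat),
    and the SVD taken; requesting more modes than the rank yields a
    rank-limited result.  A field of identical curves has rank 0 after
    centering and is rejected.
    """
    X = np.asarray(curves, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if X.ndim != 2 or lats.shape != (X.shape[0],):
        raise ValueError("curves must be (n_pixels, n_days) with one latitude per pixel")
    mu = X.mean(axis=1)
    sd = X.std(axis=1)
    if np.any(np.abs(mu) > _STD_TOL) or np.any(np.abs(sd - 1.0) > _STD_TOL):
        raise ValueError("curves must be standardized (mean 0, SD 1) per pixel")
    w = np.sqrt(np.cos(np.radians(lats)))
    if np.any(w <= 0):
        raise ValueError("latitudes must lie strictly between the poles")
    wsum = (w**2).sum()
    mean_curve = (w[:, None] ** 2 * X).sum(axis=0) / wsum
    A = X - mean_curve
    B = w[:, None] * A
    U, S, Vt = np.linalg.svd(B, full_matrices=False)
    # absolute floor: standardized curves have O(1) singular values, so
    # anything below 1e-9 is centering round-off, not structure
    tol = max(S.max(initial=0.0) * max(B.shape) * np.finfo(float).eps, 1e-9)
    rank = int(np.sum(S > tol))
    if rank == 0:
        raise ValueError("all curves identical: nothing to decompose")
    k = rank if n_modes is None else min(n_modes, rank)
    V = Vt[:k]
    scores = A @ V.T  # (n_pixels, k)
    # EOF signs are arbitrary; fix each mode so the largest-magnitude entry
    # of its curve is positive (reproducible colours)
    for i in range(k):
        j = int(np.argmax(np.abs(V[i])))
        if V[i, j] < 0:
            V[i] = -V[i]
            scores[:, i] = -scores[:, i]
    var_frac = (S[:k] ** 2) / (S**2).sum()
    return EofResult(
        modes=scores.T,
        mode_curves=V,
        variance_fraction=var_frac,
        weights=w,
        mean_curve=mean_curve,
    )


@dataclass
class ItczCurve:
    """Mean ITCZ latitude sampled along longitude."""

    lons: np.ndarray
    lats: np.ndarray

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if self.lons.shape != self.lats.shape or self.lons.ndim != 1:
            raise ValueError("lons and lats must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.lats)):
            raise ValueError("ITCZ latitudes must be finite")

    @classmethod
    def constant(cls, lat: float = 0.0) -> "ItczCurve":
        return cls(np.array([-180.0, 180.0]), np.array([lat, lat]))

    def lat_at(self, lon) -> np.ndarray:
        order = np.argsort(self.lons)
        return np.interp(np.asarray(lon, dtype=float), self.lons[order], self.lats[order])


def itcz_weight(lat, itcz, band_deg: float = 10.0, lon=None):
    """Interhemispheric weight w: 1 north of the ITCZ band, 0 south of it.

    Transitions linearly across a ``band_deg``-wide latitudinal band
    centered on the (longitude-dependent) annual-mean ITCZ; w = 0.5 on the
    ITCZ itself.
    """
    if band_deg <= 0:
        raise ValueError("band must be positive")
    lat = np.asarray(lat, dtype=float)
    if isinstance(itcz, ItczCurve):
        if lon is None:
            raise ValueError("an ItczCurve needs the longitudes too")
        center = itcz.lat_at(lon)
    else:
        center = np.asarray(itcz, dtype=float)
    w = (lat - (center - band_deg / 2.0)) / band_deg
    return np.clip(w, 0.0, 1.0)


def transform_eof(mode_map, w_map):
    """Blend a min-max-scaled mode map with its complement: w*x + (1-w)*(1-x)."""
    x = np.asarray(mode_map, dtype=float)
    w = np.asarray(w_map, dtype=float)
    finite = np.isfinite(x)
    if np.any((x[finite] < 0) | (x[finite] > 1)):
        raise ValueError("mode map must be min-max scaled to [0, 1] first")
    return w * x + (1.0 - w) * (1.0 - x)


def _minmax_valid(x: np.ndarray) -> np.ndarray:
    finite = np.isfinite(x)
    lo, hi = x[finite].min(), x[finite].max()
    if hi == lo:
        raise ValueError("constant band cannot be min-max scaled")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - lo) / (hi - lo)
    return out


def rgb_composite(map_r, map_g, map_b) -> np.ndarray:
    """Stack three maps as RGB after per-band min-max scaling.

    Input maps share a grid; NaN pixels stay NaN (transparent).  Output is
    ``(n_pixels, 3)`` in [0, 1].
    """
    bands = [np.asarray(m, dtype=float) for m in (map_r, map_g, map_b)]
    if len({b.shape for b in bands}) != 1:
        raise ValueError("all three maps must share a grid")
    return np.stack([_minmax_valid(b) for b in bands], axis=-1)


def _full_inertia(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, float]:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return labels, float(d2[np.arange(X.shape[0]), labels].sum())


def cluster_phenocycles(
    curves: np.ndarray,
    k: int,
    batch_size: int = 1024,
    seed: int = 0,
    *,
    n_restarts: int = 10,
    rgb: np.ndarray | None = None,
    extra_inits: list[np.ndarray] | None = None,
):
    """Mini-batch k-means over standardized curves; best of ``n_restarts``.

    Returns ``(labels, inertia, centers, median_rgb)`` where inertia is
    evaluated on the full dataset with the final centers (so runs are
    comparable across k) and ``median_rgb`` is the per-cluster median of
    the supplied RGB composite (or None).
    """
    X = np.asarray(curves, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        km = MiniBatchKMeans(
            n_clusters=k, batch_size=min(batch_size, n), random_state=rs, n_init=1
        ).fit(X)
        labels, inertia = _full_inertia(X, km.cluster_centers_)
        if best is None or inertia < best[1]:
            best = (labels, inertia, km.cluster_centers_)
    extras = list(extra_inits or [])
    if k == 1:
        extras.append(X.mean(axis=0, keepdims=True))  # exact optimum
    for init in extras:
        labels, inertia = _full_inertia(X, init)
        if inertia < best[1]:
            best = (labels, inertia, init.copy())
    labels, inertia, centers = best
    median_rgb = None
    if rgb is not None:
        rgb = np.asarray(rgb, dtype=float)
        median_rgb = np.vstack(
            [
                np.nanmedian(rgb[labels == c], axis=0) if np.any(labels == c) else np.full(3, np.nan)
                for c in range(k)
            ]
        )
    return labels, inertia, centers, median_rgb


def inertia_scan(curves: np.ndarray, ks, batch_size: int = 1024, seed: int = 0, n_restarts: int = 10):
    """Best inertia per k for scree inspection; non-increasing in k.

    Each k's candidate set includes the previous best centers augmented
    with the worst-served point, which guarantees the scan never goes up.
    """
    X = np.asarray(curves, dtype=float)
    out = {}
    prev_centers = None
    for k in sorted(ks):
        extra = []
        if prev_centers is not None and prev_centers.shape[0] < k:
            labels, _ = _full_inertia(X, prev_centers)
            resid = ((X - prev_centers[labels]) ** 2).sum(axis=1)
            grown = prev_centers
            while grown.shape[0] < k:
                far = int(np.argmax(resid))
                grown = np.vstack([grown, X[far]])
                labels, _ = _full_inertia(X, grown)
                resid = ((X - grown[labels]) ** 2).sum(axis=1)
            extra.append(grown)
        _, inertia, centers, _ = cluster_phenocycles(
            X, k, batch_size=batch_size, seed=seed, n_restarts=n_restarts, extra_inits=extra
        )
        out[k] = inertia
        prev_centers = centers
    return out
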