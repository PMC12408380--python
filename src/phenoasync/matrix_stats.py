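"""Distance matrices and permutation statistics (MMRR, FDR, Jaccard).

MMRR (multiple matrix regression with randomization) regresses a response
distance matrix on predictor distance matrices over their vectorized upper
triangles, with significance assessed by simultaneously permuting the rows
and columns of the response matrix and recomputing the |t| statistics.
Distance matrices are z-scored over their off-diagonal entries before
regression so fitted coefficients are comparable beta weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .geodesy import pairwise_geodesic_m
from .harmonic import DAYS_PER_YEAR

__all__ = [
    "DistanceMatrix",
    "MmrrResult",
    "JaccardResult",
    "euclidean_dm",
    "geodesic_dm",
    "circular_day_distance",
    "circular_day_dm",
    "standardize_dm",
    "mmrr",
    "bh_fdr",
    "pairwise_jaccard",
    "jaccard_perm_test",
]

KINDS = ("phenological", "climatic", "geographic", "genetic", "flowering_date")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal.

    ``standardized`` marks matrices that were z-scored over the off-diagonal
    (and may therefore hold negative entries).
    """

    values: np.ndarray
    kind: str = "phenological"
    standardized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if not self.standardized and np.any(v < 0):
            raise ValueError("raw distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def euclidean_dm(vectors, kind: str = "phenological") -> DistanceMatrix:
    """Pairwise Euclidean distances between row vectors."""
    X = np.asarray(vectors, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input vectors contain NaN/inf")
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(X)), kind=kind)


def geodesic_dm(coords) -> DistanceMatrix:
    """Pairwise geodesic distances (metres) between (lat, lon) points."""
    c = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("coordinates contain NaN/inf")
    if np.any(np.abs(c[:, 0]) > 90) or np.any(np.abs(c[:, 1]) > 360):
        raise ValueError("coordinates out of range")
    return DistanceMatrix(pairwise_geodesic_m(c[:, 0], c[:, 1]), kind="geographic")


def circular_day_distance(d1, d2):
    """Shorter of the forward- and backward-time distances between days of year."""
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if np.any((a < 1) | (a > DAYS_PER_YEAR)) or np.any((b < 1) | (b > DAYS_PER_YEAR)):
        raise ValueError("day of year must lie in [1, 365]")
    diff = np.abs(a - b)
    out = np.minimum(diff, DAYS_PER_YEAR - diff)
    return float(out) if np.ndim(out) == 0 else out


def circular_day_dm(days) -> DistanceMatrix:
    d = np.asarray(days, dtype=float)
    diff = np.abs(d[:, None] - d[None, :])
    return DistanceMatrix(np.minimum(diff, DAYS_PER_YEAR - diff), kind="flowering_date")


def standardize_dm(dm: DistanceMatrix) -> DistanceMatrix:
    """Z-score the off-diagonal entries; diagonal stays zero."""
    v = dm.values.copy()
    n = dm.n
    off = ~np.eye(n, dtype=bool)
    mu = v[off].mean()
    sd = v[off].std()
    if sd == 0:
        raise ValueError("constant distances cannot be standardized")
    v[off] = (v[off] - mu) / sd
    return DistanceMatrix(v, kind=dm.kind, standardized=True)


@dataclass
class MmrrResult:
    coefficients: dict[str, float]
    t_stats: dict[str, float]
    perm_p: dict[str, float]
    r2: float
    n_perm: int


def mmrr(
    response_dm: DistanceMatrix,
    predictor_dms: dict[str, DistanceMatrix],
    n_perm: int = 999,
    seed: int = 0,
) -> MmrrResult:
    """Multiple matrix regression with randomization.

    OLS of the response's vectorized upper triangle on the predictors'
    (with intercept).  Permutation P values use the +1 convention,
    (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1), from simultaneous row/
    column permutations of the response matrix.  Collinear predictors fall
    back to the minimum-norm fit (pseudoinverse) with a warning flag in the
    t statistics (NaN where the standard error is undefined).
    """
    n = response_dm.n
    if n < 4:
        raise ValueError("need at least 4 points")
    names = list(predictor_dms)
    for nm in names:
        if predictor_dms[nm].n != n:
            raise ValueError(f"predictor {nm!r} has mismatched size")
    iu = np.triu_indices(n, k=1)
    y = response_dm.values[iu]
    X = np.column_stack([np.ones(y.size)] + [predictor_dms[nm].values[iu] for nm in names])
    m, k = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    resid = y - X @ beta
    dof = m - k
    sigma2 = float(resid @ resid) / dof
    xtx_inv = pinv @ pinv.T
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(se > 0, beta / se, np.nan)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0

    count = np.zeros(k)
    rng = np.random.default_rng(seed)
    R = response_dm.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = R[np.ix_(perm, perm)][iu]
        bp = pinv @ yp
        rp = yp - X @ bp
        s2 = float(rp @ rp) / dof
        sep = np.sqrt(np.clip(s2 * np.diag(xtx_inv), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tp = np.where(sep > 0, bp / sep, np.nan)
        count += np.abs(tp) >= np.abs(t_obs)
    perm_p = (1.0 + count) / (n_perm + 1.0)

    labels = ["intercept"] + names
    return MmrrResult(
        coefficients=dict(zip(labels, beta.tolist())),
        t_stats=dict(zip(labels, t_obs.tolist())),
        perm_p=dict(zip(labels, perm_p.tolist())),
        r2=r2,
        n_perm=n_perm,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


@dataclass
class JaccardResult:
    J: float
    n_both: int
    n_a_only: int
    n_b_only: int
    perm_p: float | None = None


def pairwise_jaccard(labels_a, labels_b) -> JaccardResult:
    """Jaccard index of two partitions over unordered point pairs.

    J = n_both / (n_a_only + n_b_only + n_both) where pairs co-assigned in
    neither partition are ignored; label names are irrelevant.  If every
    point is a singleton in both partitions the partitions agree exactly
    and J = 1 by convention.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be equal-length 1-D")
    if a.size < 2:
        raise ValueError("need at least 2 points")
    iu = np.triu_indices(a.size, k=1)
    same_a = (a[:, None] == a[None, :])[iu]
    same_b = (b[:, None] == b[None, :])[iu]
    n_both = int(np.sum(same_a & same_b))
    n_a = int(np.sum(same_a & ~same_b))
    n_b = int(np.sum(~same_a & same_b))
    denom = n_both + n_a + n_b
    J = 1.0 if denom == 0 else n_both / denom
    return JaccardResult(J=J, n_both=n_both, n_a_only=n_a, n_b_only=n_b)


def _kmeans_labels(curves: np.ndarray, k: int, seed: int, n_init: int = 10) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(curves)


def jaccard_perm_test(
    labels_fixed,
    curves,
    k: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> JaccardResult:
    """Concordance of a fixed labelling with k-means clusters of the curves.

    The observed J compares k-means(k) labels of the curves with the fixed
    labels.  The null re-clusters after permuting the point-to-curve
    assignment; the one-sided empirical P is the fraction of null J values
    at least as large as the observed J.
    """
    labels_fixed = np.asarray(labels_fixed)
    X = np.asarray(curves, dtype=float)
    if X.shape[0] != labels_fixed.size:
        raise ValueError("labels and curves must align")
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of points")
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")
    ss = np.random.SeedSequence(seed)
    base = int(ss.generate_state(1)[0] % (2**31 - 1))
    obs_labels = _kmeans_labels(X, k, base)
    obs = pairwise_jaccard(labels_fixed, obs_labels)
    rng = np.random.default_rng(ss.spawn(1)[0])
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(X.shape[0])
        lab = _kmeans_labels(X[perm], k, (base + 1 + i) % (2**31 - 1), n_init=1)
        null[i] = pairwise_jaccard(labels_fixed, lab).J
    p = float(np.mean(null >= obs.J))
    return JaccardResult(
        J=obs.J, n_both=obs.n_both, n_a_only=obs.n_a_only, n_b_only=obs.n_b_only, perm_p=p
    )
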