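"""Asynchrony driver modelling: covariates, random forest, attribution.

The response is the land-surface-phenology asynchrony map; candidate
drivers are climate-seasonality asynchrony maps (precipitation, min/max
temperature, water deficit, cloud), topographic ruggedness, vegetation
structural entropy, land-use-change proportion, fire frequency and
optionally the pixel coordinates.  A random forest regressor captures the
nonlinear, regionally varying relationships; per-pixel attributions use an
exact path-based additive decomposition of the tree predictions, and the
predominance of the two leading drivers is summarized as the normalized
difference of their absolute attributions within asynchrony hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .grid import GridSpec
from .geodesy import neighborhood

__all__ = [
    "DRIVER_COLUMNS",
    "Attribution",
    "RfModel",
    "vegetation_entropy",
    "neighborhood_mean",
    "reclass_vegetation",
    "rf_fit",
    "rf_tuning_grid",
    "attribution",
    "predominance",
    "predominance_map",
]

DRIVER_COLUMNS = [
    "ppt_asy",
    "tmp_min_asy",
    "tmp_max_asy",
    "def_asy",
    "cld_asy",
    "vrm_med",
    "veg_ent",
    "luc_prp_mea",
    "brn_frq_mea",
]

# IGBP -> structural class: forest, shrubland, savanna, grassland, wetland
_VEG_CLASS = {**{c: 0 for c in range(1, 6)}, 6: 1, 7: 1, 8: 2, 9: 2, 10: 3, 11: 4}


def reclass_vegetation(modal_landcover: np.ndarray) -> np.ndarray:
    """Map modal IGBP codes onto the 5 structural classes (-1 = outside)."""
    lc = np.asarray(modal_landcover, dtype=int)
    out = np.full(lc.shape, -1, dtype=int)
    for code, cls in _VEG_CLASS.items():
        out[lc == code] = cls
    return out


def vegetation_entropy(
    modal_landcover: np.ndarray,
    grid: GridSpec,
    radius_km: float = 100.0,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Shannon entropy (bits) of structural classes in each pixel's neighborhood.

    The focal pixel is included in its own neighborhood.  Pixels whose
    neighborhood holds no classifiable vegetation are unset (NaN).
    """
    cls = reclass_vegetation(modal_landcover)
    if valid is not None:
        cls = np.where(np.asarray(valid, dtype=bool), cls, -1)
    out = np.full(grid.n_pixels, np.nan)
    for p in range(grid.n_pixels):
        nb = neighborhood(grid, p, radius_km)
        pool = cls[np.append(nb, p)]
        pool = pool[pool >= 0]
        if pool.size == 0:
            continue
        _, counts = np.unique(pool, return_counts=True)
        prob = counts / counts.sum()
        out[p] = float(-(prob * np.log2(prob)).sum())
    return out


def neighborhood_mean(
    raster: np.ndarray,
    grid: GridSpec,
    radius_km: float = 100.0,
    *,
    include_focal: bool = True,
) -> np.ndarray:
    """Mean of a raster over each pixel's radial neighborhood (NaN-aware)."""
    v = np.asarray(raster, dtype=float)
    out = np.full(grid.n_pixels, np.nan)
    for p in range(grid.n_pixels):
        nb = neighborhood(grid, p, radius_km)
        pool = v[np.append(nb, p)] if include_focal else v[nb]
        pool = pool[np.isfinite(pool)]
        if pool.size:
            out[p] = pool.mean()
    return out


@dataclass
class RfModel:
    model: RandomForestRegressor
    features: list[str]
    r2: float
    rmse: float
    train_index: np.ndarray
    test_index: np.ndarray


def rf_tuning_grid() -> dict[str, list]:
    """The hyperparameter tuning grid explored for the driver model."""
    return {
        "n_estimators": [150, 200, 250, 300],
        "sample_fraction": [0.3, 0.55, 0.8],
        "min_node_size": [1, 3, 5, 10],
        "mtry": [1, 3, 5],
    }


def _check_collinearity(X: pd.DataFrame, limit: float = 0.75) -> None:
    corr = X.corr().to_numpy() ** 2
    np.fill_diagonal(corr, 0.0)
    if np.nanmax(corr) >= limit:
        i, j = np.unravel_index(np.nanargmax(corr), corr.shape)
        raise ValueError(
            f"covariates {X.columns[i]!r} and {X.columns[j]!r} are collinear "
            f"(R^2 = {corr[i, j]:.3f} >= {limit})"
        )


def rf_fit(
    table: pd.DataFrame,
    include_xy: bool = True,
    hyperparams: dict | None = None,
    split: float = 0.6,
    seed: int = 0,
    *,
    response: str = "lsp_asy",
    subset_frac: float | None = None,
) -> RfModel:
    """Fit the asynchrony driver forest and score it on a held-out split.

    The training rows come from a quartile-stratified (by the response)
    ``split`` fraction of the table (optionally of a stratified
    ``subset_frac`` subsample).  Defaults mirror the tuned configuration:
    300 trees, 80% observation sampling, terminal nodes of 1, and 5
    candidate split variables.
    """
    hp = {"n_estimators": 300, "sample_fraction": 0.8, "min_node_size": 1, "mtry": 5}
    hp.update(hyperparams or {})
    cols = [c for c in table.columns if c != response]
    if not include_xy:
        cols = [c for c in cols if c not in ("x", "y")]
    df = table[[response] + cols].dropna()
    if df[response].nunique() < 2:
        raise ValueError("response is constant")
    _check_collinearity(df[cols])
    quart = pd.qcut(df[response], 4, labels=False, duplicates="drop")
    if subset_frac is not None:
        df, _ = train_test_split(
            df, train_size=subset_frac, stratify=quart, random_state=seed
        )
        quart = pd.qcut(df[response], 4, labels=False, duplicates="drop")
    idx_train, idx_test = train_test_split(
        np.arange(len(df)), train_size=split, stratify=quart, random_state=seed
    )
    X = df[cols].to_numpy()
    y = df[response].to_numpy()
    model = RandomForestRegressor(
        n_estimators=hp["n_estimators"],
        min_samples_leaf=hp["min_node_size"],
        max_features=min(hp["mtry"], len(cols)),
        bootstrap=True,
        max_samples=hp["sample_fraction"],
        random_state=seed,
        n_jobs=1,
    ).fit(X[idx_train], y[idx_train])
    pred = model.predict(X[idx_test])
    resid = y[idx_test] - pred
    sst = np.sum((y[idx_test] - y[idx_test].mean()) ** 2)
    r2 = float(1.0 - np.sum(resid**2) / sst) if sst > 0 else 0.0
    rmse = float(np.sqrt(np.mean(resid**2)))
    return RfModel(
        model=model,
        features=cols,
        r2=r2,
        rmse=rmse,
        train_index=df.index.to_numpy()[idx_train],
        test_index=df.index.to_numpy()[idx_test],
    )


@dataclass
class Attribution:
    """Exactly additive per-sample, per-feature attributions."""

    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    features: list[str]

    def importance(self) -> pd.Series:
        """Mean absolute attribution per covariate, descending."""
        return pd.Series(
            np.abs(self.values).mean(axis=0), index=self.features
        ).sort_values(ascending=False)

    def prediction(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1)


def _tree_contributions(estimator, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Path attribution for one tree: value changes at splits, credited to
    the split feature.  Additivity is exact: base + contributions = leaf value."""
    t = estimator.tree_
    n_nodes = t.node_count
    value = t.value.reshape(n_nodes)
    contrib_per_node = np.zeros((n_nodes, X.shape[1]))
    for parent in range(n_nodes):
        left, right = t.children_left[parent], t.children_right[parent]
        if left == -1:
            continue
        f = t.feature[parent]
        contrib_per_node[left, f] += value[left] - value[parent]
        contrib_per_node[right, f] += value[right] - value[parent]
    path = estimator.decision_path(X)  # sparse (n_samples, n_nodes)
    return path @ contrib_per_node, float(value[0])


def attribution(fitted: RfModel, table: pd.DataFrame) -> Attribution:
    """Additive attribution of forest predictions to the covariates.

    Averages the per-tree path attributions; the result reconstructs each
    prediction exactly (base value + row sum).
    """
    X = table[fitted.features].to_numpy(dtype=np.float32)
    total = np.zeros((X.shape[0], X.shape[1]))
    base = 0.0
    for est in fitted.model.estimators_:
        c, b = _tree_contributions(est, X)
        total += c
        base += b
    n = len(fitted.model.estimators_)
    return Attribution(values=total / n, base_value=base / n, features=fitted.features)


def predominance(attr: Attribution, feature_a: str = "ppt_asy", feature_b: str = "tmp_min_asy") -> np.ndarray:
    """Normalized difference of absolute attributions of two covariates.

    (+1: ``feature_a`` fully predominates; -1: ``feature_b``; NaN where
    both attributions vanish.)
    """
    ia = attr.features.index(feature_a)
    ib = attr.features.index(feature_b)
    a = np.abs(attr.values[:, ia])
    b = np.abs(attr.values[:, ib])
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (a - b) / np.where(denom == 0, 1, denom), np.nan)
    return out


def predominance_map(predom_values: np.ndarray, hotspot: np.ndarray) -> np.ndarray:
    """Predominance restricted to hotspot pixels (NaN elsewhere)."""
    out = np.where(np.asarray(hotspot, dtype=bool), np.asarray(predom_values, dtype=float), np.nan)
    return out
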