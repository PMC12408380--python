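"""Readers and writers for the pipeline's artifact formats.

Cubes and raster layers travel as NetCDF (via xarray, scipy backend);
point sets as CSV; region hulls as GeoJSON; statistical results as JSON
records.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping

from .grid import GridSpec, TimeSeriesCube
from .synthetic import SyntheticPointSet

__all__ = [
    "write_cube",
    "read_cube",
    "write_layers",
    "read_layers",
    "write_point_set",
    "read_point_set",
    "write_hulls_geojson",
    "write_json",
]


def _grid_coords(grid: GridSpec) -> dict:
    return {"lat": ("lat", grid.lats), "lon": ("lon", grid.lons)}


def write_cube(cube: TimeSeriesCube, path) -> None:
    ds = xr.Dataset(
        {
            "values": (("time", "lat", "lon"),
                       cube.values.reshape(cube.n_times, *cube.grid.shape)),
            "available": (("time", "lat", "lon"),
                          cube.available.reshape(cube.n_times, *cube.grid.shape).astype("i1")),
            "doy": (("time",), cube.doy),
        },
        coords={"time": ("time", cube.t_days), **_grid_coords(cube.grid)},
        attrs={"cell_size": cube.grid.cell_size},
    )
    ds.to_netcdf(path, engine="scipy")


def read_cube(path) -> TimeSeriesCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        lats, lons = ds["lat"].values, ds["lon"].values
        grid = GridSpec(
            n_rows=lats.size,
            n_cols=lons.size,
            cell_size=float(ds.attrs["cell_size"]),
            origin=(float(lats[0]), float(lons[0])),
        )
        n_t = ds.sizes["time"]
        return TimeSeriesCube(
            grid=grid,
            t_days=ds["time"].values,
            doy=ds["doy"].values,
            values=ds["values"].values.reshape(n_t, -1),
            available=ds["available"].values.reshape(n_t, -1).astype(bool),
        )


def write_layers(layers: dict[str, np.ndarray], grid: GridSpec, path) -> None:
    """Per-pixel layers (flattened row-major) to a NetCDF of 2-D variables."""
    ds = xr.Dataset(
        {
            name: (("lat", "lon"), np.asarray(v, dtype=float).reshape(grid.shape))
            for name, v in layers.items()
        },
        coords=_grid_coords(grid),
        attrs={"cell_size": grid.cell_size},
    )
    ds.to_netcdf(path, engine="scipy")


def read_layers(path) -> dict[str, np.ndarray]:
    with xr.open_dataset(path, engine="scipy") as ds:
        return {name: ds[name].values.ravel() for name in ds.data_vars}


def write_point_set(ps: SyntheticPointSet, path) -> None:
    payload = np.asarray(ps.payload)
    cols = {"id": np.arange(len(ps.coords)), "lat": ps.coords[:, 0], "lon": ps.coords[:, 1]}
    if payload.ndim == 1:
        cols["payload"] = payload
    else:
        for j in range(payload.shape[1]):
            cols[f"payload_{j}"] = payload[:, j]
    cols["truth_label"] = ps.truth_labels
    pd.DataFrame(cols).to_csv(path, index=False)


def read_point_set(path, kind: str = "category") -> SyntheticPointSet:
    df = pd.read_csv(path)
    pay_cols = [c for c in df.columns if c.startswith("payload")]
    payload = df[pay_cols].to_numpy()
    if payload.shape[1] == 1:
        payload = payload[:, 0]
    return SyntheticPointSet(
        coords=df[["lat", "lon"]].to_numpy(),
        payload=payload,
        truth_labels=df["truth_label"].to_numpy(),
        kind=kind,
        pixels=np.full(len(df), -1, dtype=int),
    )


def write_hulls_geojson(regions, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(r.polygon),
            "properties": {
                "mean_abs_lat": r.mean_abs_lat,
                "beta_c": None if not np.isfinite(r.beta_c) else r.beta_c,
                "beta_g": None if not np.isfinite(r.beta_g) else r.beta_g,
                "n_points": int(r.n_points),
            },
        }
        for r in regions
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(record: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(record), indent=1, sort_keys=True))
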