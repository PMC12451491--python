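"""Raster containers and plain-text raster I/O.

Rasters are numpy arrays tied to the run's :class:`~montrange.grid.GridSpec`.
On disk they are ESRI ASCII grids (``.asc``) — a text format readable by
every GIS — with one file per layer; multi-layer stacks are a directory
of ``.asc`` files plus a ``layers.json`` manifest preserving order.
Polygons travel as GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec, build_grid

NODATA = -9999.0

__all__ = [
    "check_aligned",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_stack",
    "read_stack",
    "write_geojson",
    "read_geojson",
    "rasterize_polygons",
]


def check_aligned(grid: GridSpec, *arrays: np.ndarray) -> None:
    """Raise ValueError unless every array has the grid's shape."""
    for a in arrays:
        if a.shape != grid.shape:
            raise ValueError(f"raster shape {a.shape} does not match grid {grid.shape}")


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    check_aligned(grid, values)
    vals = np.asarray(values, dtype=float)
    vals = np.where(np.isfinite(vals), vals, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min!r}\n"
        f"yllcorner {grid.lat_min!r}\n"
        f"cellsize {grid.resolution!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    n_cols, n_rows = int(hdr["ncols"]), int(hdr["nrows"])
    res = hdr["cellsize"]
    grid = build_grid(
        lon_min=hdr["xllcorner"],
        lon_max=hdr["xllcorner"] + n_cols * res,
        lat_min=hdr["yllcorner"],
        lat_max=hdr["yllcorner"] + n_rows * res,
        resolution=res,
    )
    values = np.where(values == hdr["nodata_value"], np.nan, values)
    check_aligned(grid, values)
    return grid, values


def write_stack(directory: str | Path, grid: GridSpec, layers: dict[str, np.ndarray]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, values in layers.items():
        write_ascii_grid(directory / f"{name}.asc", grid, values)
    (directory / "layers.json").write_text(json.dumps(list(layers), indent=1))


def read_stack(directory: str | Path) -> tuple[GridSpec, dict[str, np.ndarray]]:
    directory = Path(directory)
    names = json.loads((directory / "layers.json").read_text())
    grid = None
    layers: dict[str, np.ndarray] = {}
    for name in names:
        g, values = read_ascii_grid(directory / f"{name}.asc")
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"layer {name} not aligned with the rest of the stack")
        layers[name] = values
    if grid is None:
        raise ValueError(f"empty stack in {directory}")
    return grid, layers


def write_geojson(path: str | Path, geometries: list[BaseGeometry], properties: list[dict] | None = None) -> None:
    props = properties or [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, props, strict=True)
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_geojson(path: str | Path) -> list[BaseGeometry]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in doc["features"]]
    if doc.get("type") == "Feature":
        return [shape(doc["geometry"])]
    return [shape(doc)]


def rasterize_polygons(grid: GridSpec, geometries, all_touched: bool = False) -> np.ndarray:
    """Boolean mask of cells whose centers fall inside any geometry.

    `all_touched` additionally includes cells whose center lies within
    half a cell diagonal of the geometry boundary (cheap approximation,
    used nowhere critical).
    """
    geoms = list(geometries)
    if not geoms:
        return np.zeros(grid.shape, dtype=bool)
    union = shapely.unary_union(geoms)
    lon, lat = grid.center_mesh()
    mask = shapely.contains_xy(union, lon.ravel(), lat.ravel()).reshape(grid.shape)
    if all_touched:
        near = shapely.dwithin(
            union, shapely.points(lon.ravel(), lat.ravel()), grid.resolution * 0.7071
        ).reshape(grid.shape)
        mask |= near
    return mask
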