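"""Shared raster-grid convention.

Every raster, mask and stack in a run is aligned to a single
:class:`GridSpec`: a regular geographic (lon/lat) grid. Cells are
half-open intervals ``[west, east) x (south, north]`` so that every
point inside the extent belongs to exactly one cell; row 0 is the
northernmost row, column 0 the westernmost column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "build_grid", "cell_area_km2"]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridSpec:
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float
    n_rows: int
    n_cols: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        """West-to-east cell-center longitudes (length n_cols)."""
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        """North-to-south cell-center latitudes (length n_rows)."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of cell centers, shape (n_rows, n_cols)."""
        return np.meshgrid(self.lon_centers(), self.lat_centers())

    def point_to_cell(self, lon: float, lat: float) -> tuple[int, int] | None:
        r, c = self.points_to_cells(np.asarray([lon]), np.asarray([lat]))
        if r[0] < 0:
            return None
        return int(r[0]), int(c[0])

    def points_to_cells(
        self, lon: np.ndarray, lat: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized point->cell lookup; (-1, -1) marks points off-grid.

        Longitude intervals are [west, east): a point on a cell's west
        edge belongs to it, the grid's east edge is outside. Latitude
        intervals are (south, north]: the grid's north edge is row 0,
        the south edge is outside.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        res = self.resolution
        with np.errstate(invalid="ignore"):
            col = np.floor((lon - self.lon_min) / res)
            # (south, north]: a boundary latitude is the north edge of the
            # row below it, so plain floor gives the owning row, with the
            # grid's own north edge folded into row 0
            d = (self.lat_max - lat) / res
            row = np.where(d <= 0.0, 0.0, np.floor(d))
        ok = (
            np.isfinite(lon)
            & np.isfinite(lat)
            & (lon >= self.lon_min)
            & (col < self.n_cols)
            & (lat <= self.lat_max)
            & (lat > self.lat_min)
            & (row < self.n_rows)
        )
        row = np.where(ok, row, -1).astype(int)
        col = np.where(ok, col, -1).astype(int)
        return row, col


def build_grid(
    lon_min: float,
    lon_max: float,
    lat_min: float,
    lat_max: float,
    resolution: float = 0.05,
) -> GridSpec:
    """Construct the run's shared grid.

    Raises
    ------
    ValueError
        If the extent is degenerate or the resolution non-positive.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0, got {resolution}")
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError(
            f"degenerate extent: lon [{lon_min}, {lon_max}], lat [{lat_min}, {lat_max}]"
        )
    n_cols = int(round((lon_max - lon_min) / resolution))
    n_rows = int(round((lat_max - lat_min) / resolution))
    if n_cols < 1 or n_rows < 1:
        raise ValueError("extent smaller than one cell")
    return GridSpec(
        lon_min=float(lon_min),
        lon_max=float(lon_max),
        lat_min=float(lat_min),
        lat_max=float(lat_max),
        resolution=float(resolution),
        n_rows=n_rows,
        n_cols=n_cols,
    )


def cell_area_km2(grid: GridSpec) -> np.ndarray:
    """Exact spherical cell area per row (km^2), north to south.

    area(row) = R^2 * dlam * (sin(phi_north) - sin(phi_south)) for a
    sphere of authalic radius R = 6371.0088 km; constant along a row.
    """
    lat_north = grid.lat_max - np.arange(grid.n_rows) * grid.resolution
    lat_south = lat_north - grid.resolution
    dlam = np.deg2rad(grid.resolution)
    return (
        EARTH_RADIUS_KM**2
        * dlam
        * (np.sin(np.deg2rad(lat_north)) - np.sin(np.deg2rad(lat_south)))
    )
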