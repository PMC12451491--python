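"""Occurrence-record curation: cleaning filters and grid thinning.

Records pass a fixed sequence of filters — coordinate validity, the
zero/equal coordinate artefacts typical of poorly georeferenced
herbarium data, a temporal cutoff matching the climatology baseline
(year >= 1981, inclusive), and region / native-range membership — and
each rejected row is labelled with the first failing reason. Cleaned
records are then thinned to one per species per grid cell with a
deterministic representative (smallest (year, lon, lat, source)), so
results do not depend on input order or a thinning seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

from .grid import GridSpec

__all__ = ["REJECTION_REASONS", "clean_records", "thin_to_grid", "eligible_species", "cell_counts"]

#: fixed filter order; a row is labelled with its first failing reason
REJECTION_REASONS = [
    "invalid_coords",
    "zero_coords",
    "equal_lat_lon",
    "pre_year_min",
    "outside_region",
    "outside_native",
]

_COLUMNS = ["species", "decimalLongitude", "decimalLatitude", "year", "source"]


def _as_table(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if "source" not in df.columns:
        df["source"] = ""
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns {missing}")
    return df


def _inside(geoms, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    if geoms is None:
        return np.ones(lon.shape, dtype=bool)
    union = shapely.unary_union(list(geoms))
    ok = np.zeros(lon.shape, dtype=bool)
    finite = np.isfinite(lon) & np.isfinite(lat)
    ok[finite] = shapely.intersects_xy(union, lon[finite], lat[finite])
    return ok


def clean_records(
    records: pd.DataFrame,
    region_mask_polygons=None,
    native_mask_polygons=None,
    year_min: int = 1981,
) -> pd.DataFrame:
    """Apply the cleaning filters; returns the full table with a
    ``rejection_reason`` column (empty string = retained).

    Rows with a missing year are rejected (``pre_year_min``): the
    temporal filter cannot be evaluated for them. When a native mask is
    given per species, pass a dict ``{species_id: [polygons]}``;
    otherwise one polygon list applies to all species.
    """
    if len(records) == 0:
        raise ValueError("records table is empty")
    df = _as_table(records)
    lon = pd.to_numeric(df["decimalLongitude"], errors="coerce").to_numpy(dtype=float)
    lat = pd.to_numeric(df["decimalLatitude"], errors="coerce").to_numpy(dtype=float)
    year = pd.to_numeric(df["year"], errors="coerce").to_numpy(dtype=float)

    reason = np.full(len(df), "", dtype=object)

    def flag(mask: np.ndarray, label: str) -> None:
        mask = mask & (reason == "")
        reason[mask] = label

    flag(~np.isfinite(lon) | ~np.isfinite(lat) | (np.abs(lat) > 90) | (np.abs(lon) > 180), "invalid_coords")
    flag((lon == 0.0) & (lat == 0.0), "zero_coords")
    flag(lon == lat, "equal_lat_lon")
    flag(~np.isfinite(year) | (year < year_min), "pre_year_min")
    flag(~_inside(region_mask_polygons, lon, lat), "outside_region")

    if isinstance(native_mask_polygons, dict):
        for sp, geoms in native_mask_polygons.items():
            sel = (df["species"] == sp).to_numpy()
            flag(sel & ~_inside(geoms, lon, lat), "outside_native")
        known = df["species"].isin(native_mask_polygons).to_numpy()
        flag(~known, "outside_native")
    elif native_mask_polygons is not None:
        flag(~_inside(native_mask_polygons, lon, lat), "outside_native")

    out = df.copy()
    out["rejection_reason"] = reason
    return out


def retained(cleaned: pd.DataFrame) -> pd.DataFrame:
    return cleaned[cleaned["rejection_reason"] == ""].drop(columns=["rejection_reason"])


def thin_to_grid(records: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """One record per (species, grid cell); the representative is the
    lexicographically smallest (year, lon, lat, source) in the cell.
    Records falling off-grid are dropped. Adds ``row``/``col`` columns."""
    df = _as_table(records)
    if "rejection_reason" in df.columns:
        df = retained(df)
    row, col = grid.points_to_cells(
        df["decimalLongitude"].to_numpy(dtype=float),
        df["decimalLatitude"].to_numpy(dtype=float),
    )
    df = df.assign(row=row, col=col)
    df = df[df["row"] >= 0]
    df = df.sort_values(
        ["species", "row", "col", "year", "decimalLongitude", "decimalLatitude", "source"],
        kind="mergesort",
    )
    thinned = df.drop_duplicates(subset=["species", "row", "col"], keep="first")
    return thinned.reset_index(drop=True)


def cell_counts(thinned: pd.DataFrame) -> pd.Series:
    """Occupied-cell count per species (index: species id, sorted)."""
    return thinned.groupby("species").size().sort_index()


def eligible_species(counts: pd.Series, min_cells: int = 14) -> list[str]:
    """Species with at least ``min_cells`` occupied grid cells, sorted by id."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    return sorted(counts[counts >= min_cells].index.tolist())
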