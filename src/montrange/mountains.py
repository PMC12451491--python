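"""Mountain-association scoring and modelling-cohort selection.

Each species' occupied area is approximated by dissolving 1-km disks
around its records; the share of that area inside the mountain polygons
is its mountain-association fraction. The modelling cohort is every
species whose fraction strictly exceeds the chosen percentile (default
75th) of the fractions of the whole flora and that occupies at least
``min_cells`` grid cells. Buffers and areas are computed in a local
Lambert azimuthal equal-area frame per species so km-unit buffers and
km^2 areas are exact on the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .geo import LocalEqualArea

__all__ = [
    "MountainAssociation",
    "CohortSelection",
    "buffered_range_polygon",
    "mountain_fraction",
    "score_species",
    "select_cohort",
]


@dataclass(frozen=True)
class MountainAssociation:
    species_id: str
    range_area_km2: float
    mountain_overlap_km2: float
    fraction: float
    cell_count: int


@dataclass(frozen=True)
class CohortSelection:
    percentile: float
    threshold: float
    quantile_rule: str
    selected: list[str]


def _local_frame(lon: np.ndarray, lat: np.ndarray) -> LocalEqualArea:
    return LocalEqualArea(float(np.mean(lon)), float(np.mean(lat)))


def buffered_range_polygon(
    lon: np.ndarray,
    lat: np.ndarray,
    buffer_km: float = 1.0,
    frame: LocalEqualArea | None = None,
    quad_segs: int = 64,
) -> tuple[BaseGeometry, LocalEqualArea]:
    """Dissolved union of per-record disks of radius ``buffer_km``.

    Returns the multipolygon in the local equal-area frame (km units)
    together with the frame, so the caller can project other geometries
    into the same frame for overlap areas.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size == 0:
        raise ValueError("need at least one record")
    if buffer_km <= 0:
        raise ValueError("buffer_km must be > 0")
    frame = frame or _local_frame(lon, lat)
    x, y = frame.forward(lon, lat)
    disks = shapely.buffer(shapely.points(x, y), buffer_km, quad_segs=quad_segs)
    return shapely.unary_union(disks), frame


def mountain_fraction(
    range_polygon: BaseGeometry,
    mountain_polygons_lonlat,
    frame: LocalEqualArea,
) -> float:
    """area(range ∩ mountains) / area(range), both in the equal-area frame."""
    total = range_polygon.area
    if total <= 0:
        raise ValueError("zero-area range polygon")
    mountains = [frame.project_geometry(g) for g in mountain_polygons_lonlat]
    if not mountains:
        return 0.0
    overlap = range_polygon.intersection(shapely.unary_union(mountains)).area
    return float(overlap / total)


def score_species(
    thinned: pd.DataFrame,
    mountain_polygons,
    buffer_km: float = 1.0,
) -> pd.DataFrame:
    """Mountain association per species from thinned records.

    Returns a frame with species, range_area_km2, mountain_overlap_km2,
    fraction and cell_count, sorted by species id.
    """
    out = []
    for sp, sub in thinned.groupby("species"):
        lon = sub["decimalLongitude"].to_numpy(dtype=float)
        lat = sub["decimalLatitude"].to_numpy(dtype=float)
        poly, frame = buffered_range_polygon(lon, lat, buffer_km)
        frac = mountain_fraction(poly, mountain_polygons, frame)
        out.append(
            {
                "species": sp,
                "range_area_km2": poly.area,
                "mountain_overlap_km2": frac * poly.area,
                "fraction": frac,
                "cell_count": len(sub),
            }
        )
    return pd.DataFrame(out).sort_values("species").reset_index(drop=True)


def select_cohort(
    associations: pd.DataFrame,
    percentile: float = 75.0,
    min_cells: int = 14,
) -> CohortSelection:
    """Cohort = species with fraction strictly above the percentile
    threshold and enough occupied cells.

    The threshold is the linear-interpolation quantile of the fractions
    of *all* scored species (the whole flora, not only candidates);
    species sitting exactly at the threshold are excluded ("more than").
    """
    if len(associations) < 2:
        raise ValueError("need at least 2 scored species to set a percentile threshold")
    fractions = associations["fraction"].to_numpy(dtype=float)
    threshold = float(np.percentile(fractions, percentile, method="linear"))
    sel = associations[
        (associations["fraction"] > threshold) & (associations["cell_count"] >= min_cells)
    ]
    return CohortSelection(
        percentile=float(percentile),
        threshold=threshold,
        quantile_rule="linear",
        selected=sorted(sel["species"].tolist()),
    )
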