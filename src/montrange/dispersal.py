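"""Trait-based maximum dispersal distances and reachable-area masks.

A species' maximum per-generation dispersal distance is predicted from
its growth form and dispersal syndrome on a log10-km scale, multiplied
by the number of generations fitting into the projection horizon
(horizon / juvenile period, floored, at least one), and turned into a
great-circle buffer around the modelled current range. Reach is
additionally restricted to landmasses the species already occupies, so
trans-oceanic colonisation is excluded.

The shipped coefficient table is synthetic: the published trait
regression's coefficients are not reproduced here, only the documented
ordering of syndromes (unassisted wind < ballistic < ant < adapted wind
< animal) and field-plausible magnitudes. Runs record the table used so
outputs are never mistaken for the original model's.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geo import EARTH_RADIUS_KM, sphere_xyz
from .grid import GridSpec

__all__ = [
    "GROWTH_FORMS",
    "SYNDROMES",
    "SpeciesTraits",
    "DispersalSpec",
    "default_coefficient_table",
    "per_generation_distance",
    "n_generations",
    "dispersal_mask",
]

GROWTH_FORMS = ["tree", "shrub", "herb", "fern", "shrub_or_tree", "herb_or_shrub"]
#: ascending order of maximum dispersal distance
SYNDROMES = ["wind_nonadapted", "ballistic", "ant", "wind_adapted", "animal"]

#: log10-km syndrome terms, strictly ascending in the documented order
_SYNDROME_TERMS = {
    "wind_nonadapted": -1.7,
    "ballistic": -1.3,
    "ant": -1.0,
    "wind_adapted": -0.2,
    "animal": 0.1,
}
_FORM_TERMS = {
    "herb": 0.0,
    "shrub": 0.15,
    "tree": 0.35,
    "shrub_or_tree": 0.35,
    "herb_or_shrub": 0.15,
}
_BASE_TERM = -0.3

#: fallback juvenile periods (years) per growth form when a species has none
DEFAULT_LIFE_FORM_JUVENILE_MEANS = {
    "herb": 3.0,
    "fern": 3.0,
    "herb_or_shrub": 4.0,
    "shrub": 5.0,
    "shrub_or_tree": 8.0,
    "tree": 10.0,
}


@dataclass
class SpeciesTraits:
    growth_form: str
    dispersal_syndromes: frozenset[str]
    juvenile_period_years: float | None = None
    native_landmasses: frozenset[int] = dc_field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(
                f"unknown growth form {self.growth_form!r}; accepted: {GROWTH_FORMS}"
            )
        self.dispersal_syndromes = frozenset(self.dispersal_syndromes)
        unknown = self.dispersal_syndromes - set(SYNDROMES)
        if unknown:
            raise ValueError(f"unknown syndromes {sorted(unknown)}; accepted: {SYNDROMES}")
        if not self.dispersal_syndromes:
            raise ValueError("at least one dispersal syndrome is required")
        if self.juvenile_period_years is not None and self.juvenile_period_years <= 0:
            raise ValueError("juvenile_period_years must be > 0 when present")


@dataclass(frozen=True)
class DispersalSpec:
    distance_per_generation_km: float
    n_generations: int
    total_distance_km: float


def default_coefficient_table() -> pd.DataFrame:
    """The shipped (synthetic) log10-km coefficient table.

    One row per (growth_form, syndrome) with the additive term
    ``base + form + syndrome``; ferns are mapped to herb/wind_adapted
    before lookup and therefore carry no rows of their own.
    """
    rows = [
        {
            "growth_form": gf,
            "syndrome": sy,
            "log10_km": _BASE_TERM + _FORM_TERMS[gf] + _SYNDROME_TERMS[sy],
        }
        for gf in _FORM_TERMS
        for sy in SYNDROMES
    ]
    return pd.DataFrame(rows)


def per_generation_distance(
    traits: SpeciesTraits, coefficient_table: pd.DataFrame | None = None
) -> float:
    """Maximum per-generation dispersal distance in km.

    With several syndromes the one yielding the largest distance is
    used; ferns are evaluated as herbs with adapted wind dispersal.
    """
    table = coefficient_table if coefficient_table is not None else default_coefficient_table()
    form = traits.growth_form
    syndromes = set(traits.dispersal_syndromes)
    if form == "fern":
        form = "herb"
        syndromes = {"wind_adapted"}
    sub = table[table["growth_form"] == form]
    if sub.empty:
        raise ValueError(f"coefficient table has no rows for growth form {form!r}")
    best = -np.inf
    for sy in syndromes:
        match = sub[sub["syndrome"] == sy]
        if match.empty:
            raise ValueError(f"coefficient table has no ({form!r}, {sy!r}) row")
        best = max(best, float(match["log10_km"].iloc[0]))
    return float(10.0**best)


def n_generations(
    juvenile_period_years: float | None,
    growth_form: str,
    horizon_years: float = 70.0,
    life_form_means: dict[str, float] | None = None,
) -> int:
    """Number of colonisation generations until the horizon (default 70 y,
    i.e. to 2100): floor(horizon / juvenile period), clamped to >= 1.
    A missing juvenile period falls back to the growth-form mean."""
    means = life_form_means or DEFAULT_LIFE_FORM_JUVENILE_MEANS
    jp = juvenile_period_years
    if jp is None:
        try:
            jp = means[growth_form]
        except KeyError:
            raise ValueError(f"no juvenile-period mean for growth form {growth_form!r}") from None
    if jp <= 0:
        raise ValueError("juvenile period must be > 0")
    return max(1, int(np.floor(horizon_years / jp)))


def build_dispersal_spec(
    traits: SpeciesTraits,
    horizon_years: float = 70.0,
    coefficient_table: pd.DataFrame | None = None,
    life_form_means: dict[str, float] | None = None,
) -> DispersalSpec:
    d = per_generation_distance(traits, coefficient_table)
    n = n_generations(traits.juvenile_period_years, traits.growth_form, horizon_years, life_form_means)
    return DispersalSpec(distance_per_generation_km=d, n_generations=n, total_distance_km=d * n)


def dispersal_mask(
    current_range: np.ndarray,
    total_distance_km: float,
    grid: GridSpec,
    landmass_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean raster of cells reachable from the current range.

    A cell is reachable iff the great-circle distance from its centre to
    the nearest current-presence cell centre is at most the total
    dispersal distance, and (when a landmass raster is given) the cell
    lies on a landmass that already holds a presence — which forbids
    trans-oceanic colonisation of unoccupied islands. Current presences
    are always reachable.

    landmass_ids: integer raster (-1 = sea / no landmass).
    """
    current = np.asarray(current_range, dtype=bool)
    if current.shape != grid.shape:
        raise ValueError("current_range not aligned to grid")
    if not current.any():
        return current.copy()

    lon, lat = grid.center_mesh()
    pr, pc = np.nonzero(current)
    tree = cKDTree(sphere_xyz(lon[pr, pc], lat[pr, pc]))
    chord, _ = tree.query(sphere_xyz(lon.ravel(), lat.ravel()).reshape(-1, 3), k=1)
    gc_km = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    reachable = (gc_km.reshape(grid.shape) <= total_distance_km) | current

    if landmass_ids is not None:
        landmass_ids = np.asarray(landmass_ids)
        occupied = np.unique(landmass_ids[current])
        occupied = occupied[occupied >= 0]
        on_occupied = np.isin(landmass_ids, occupied)
        reachable &= on_occupied | current
    return reachable
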