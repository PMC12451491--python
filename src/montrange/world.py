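"""Seeded synthetic landscapes, climates, scenarios and virtual species.

The generators here emulate the statistical structure the analysis
assumes: a mountainous DEM with polygon-delimited mountain regions, a
13-variable bioclim-like climate stack in which temperature declines
with elevation at a fixed lapse rate, nine smooth soil fields, per-SSP
ensembles of perturbed future members, per-cell land-use class
fractions, and virtual plant species with Gaussian climatic niches and
clustered presence samples. Every generator is a pure function of its
configuration and seed, so downstream parameter recovery can be scored
against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry.base import BaseGeometry

from .dispersal import SpeciesTraits
from .grid import GridSpec, build_grid
from .rasters import check_aligned

__all__ = [
    "CLIMATE_LAYERS",
    "SOIL_LAYERS",
    "EXCLUDED_LANDUSE_CLASSES",
    "DEFAULT_LANDUSE_CLASSES",
    "TerrainModel",
    "EnvStack",
    "ScenarioEnsemble",
    "LandUseStack",
    "VirtualSpecies",
    "InfeasibleSampleError",
    "build_grid",
    "smooth_noise",
    "generate_terrain",
    "generate_climate",
    "generate_future_ensemble",
    "generate_landuse",
    "gaussian_suitability",
    "simulate_species",
]

#: nine temperature-like and four precipitation-like layers (bioclim naming)
CLIMATE_LAYERS = [
    "bio1", "bio2", "bio3", "bio4", "bio5", "bio6", "bio7", "bio10", "bio11",
    "bio12", "bio13", "bio14", "bio15",
]
PRECIP_LAYERS = ["bio12", "bio13", "bio14", "bio15"]
SOIL_LAYERS = ["ocd", "soc", "bdod", "cec", "clay", "nitrogen", "phh2o", "sand", "silt"]

#: land-cover classes treated as unavailable habitat when dominant
EXCLUDED_LANDUSE_CLASSES = [
    "corn", "wheat", "soybean", "cotton", "rice", "sugar_crop",
    "other_crops", "bioenergy_crop", "urban",
]
NATURAL_LANDUSE_CLASSES = ["forest", "grassland", "shrubland", "pasture", "barren"]
DEFAULT_LANDUSE_CLASSES = NATURAL_LANDUSE_CLASSES + EXCLUDED_LANDUSE_CLASSES


class InfeasibleSampleError(ValueError):
    """Requested more presence samples than the truth range has cells."""


@dataclass
class TerrainModel:
    grid: GridSpec
    dem: np.ndarray
    mountain_polygons: list[BaseGeometry]
    mountain_elev_cut_m: float


@dataclass
class EnvStack:
    """Named, grid-aligned environmental rasters."""

    grid: GridSpec
    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.layers) != len(set(self.layers)):
            raise ValueError("layer names must be unique")
        check_aligned(self.grid, *self.layers.values())
        for name, vals in self.layers.items():
            if not np.isfinite(vals).any():
                raise ValueError(f"layer {name} is all-missing")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def copy(self) -> "EnvStack":
        return EnvStack(self.grid, {k: v.copy() for k, v in self.layers.items()})


@dataclass
class LandUseStack:
    grid: GridSpec
    class_names: list[str]
    fractions: np.ndarray  # (n_classes, n_rows, n_cols), each cell sums to 1

    def __post_init__(self) -> None:
        if self.fractions.shape != (len(self.class_names), *self.grid.shape):
            raise ValueError("fractions shape does not match class list and grid")
        total = self.fractions.sum(axis=0)
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ValueError("per-cell class fractions must sum to 1")


@dataclass
class ScenarioEnsemble:
    scenario_id: str
    members: list[EnvStack]
    landuse: LandUseStack | None = None


@dataclass
class VirtualSpecies:
    species_id: str
    niche_center: tuple[float, float]  # (muT degC on bio1, muP mm on bio12)
    niche_width: tuple[float, float]  # (sigmaT, sigmaP); inf disables an axis
    tau: float
    traits: SpeciesTraits
    truth_range: np.ndarray = field(repr=False)  # boolean, grid-aligned


def smooth_noise(
    shape: tuple[int, int], sd: float, kernel_cells: float, rng: np.random.Generator
) -> np.ndarray:
    """Spatially correlated ('red') noise: white noise of the given sd
    convolved with a Gaussian kernel. Smoothing shrinks the pointwise
    variance, so `sd` is an upper bound on the field's sd."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.normal(0.0, sd, size=shape)
    if kernel_cells <= 0:
        return white
    return gaussian_filter(white, sigma=kernel_cells, mode="nearest")


def _polygonize_mask(grid: GridSpec, mask: np.ndarray) -> list[BaseGeometry]:
    """Dissolve the cells of a boolean mask into polygons (cell rectangles
    unioned; slow but exact, fine at desk scale)."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return []
    res = grid.resolution
    west = grid.lon_min + cols * res
    north = grid.lat_max - rows * res
    boxes = shapely.box(west, north - res, west + res, north)
    merged = shapely.unary_union(boxes)
    return list(shapely.get_parts(merged)) if merged.geom_type == "MultiPolygon" else [merged]


def generate_terrain(
    grid: GridSpec,
    n_ridges: int = 3,
    amplitude_m: float = 2000.0,
    base_m: float = 200.0,
    noise_sd: float = 50.0,
    mountain_elev_cut_m: float = 1000.0,
    seed: int = 0,
    noise_kernel_cells: float = 3.0,
) -> TerrainModel:
    """A DEM of anisotropic Gaussian ridges over a base elevation plus
    smooth noise, clipped at sea level, with mountain polygons taken as
    the dissolved regions above an elevation cutoff."""
    rng = np.random.default_rng(seed)
    lon, lat = grid.center_mesh()
    dem = np.full(grid.shape, float(base_m))
    span_lon = grid.lon_max - grid.lon_min
    span_lat = grid.lat_max - grid.lat_min
    for _ in range(n_ridges):
        c_lon = rng.uniform(grid.lon_min + 0.15 * span_lon, grid.lon_max - 0.15 * span_lon)
        c_lat = rng.uniform(grid.lat_min + 0.15 * span_lat, grid.lat_max - 0.15 * span_lat)
        theta = rng.uniform(0.0, np.pi)
        s_major = rng.uniform(0.10, 0.30) * max(span_lon, span_lat)
        s_minor = s_major * rng.uniform(0.25, 0.6)
        amp = amplitude_m * rng.uniform(0.6, 1.0)
        u = (lon - c_lon) * np.cos(theta) + (lat - c_lat) * np.sin(theta)
        v = -(lon - c_lon) * np.sin(theta) + (lat - c_lat) * np.cos(theta)
        dem += amp * np.exp(-0.5 * ((u / s_major) ** 2 + (v / s_minor) ** 2))
    dem += smooth_noise(grid.shape, noise_sd, noise_kernel_cells, rng)
    dem = np.clip(dem, 0.0, None)
    polys = _polygonize_mask(grid, dem >= mountain_elev_cut_m)
    return TerrainModel(grid, dem, polys, mountain_elev_cut_m)


def generate_climate(
    terrain: TerrainModel,
    sea_level_temp_C: float = 26.0,
    lapse_C_per_km: float = 6.5,
    lat_gradient_C_per_deg: float = 0.3,
    precip_base_mm: float = 900.0,
    orographic_mm_per_km: float = 400.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    noise_kernel_cells: float = 3.0,
    precip_noise_scale: float = 100.0,
) -> EnvStack:
    """Current-climate stack: 13 bioclim-like + 9 soil-like layers + dem.

    bio1 (mean annual temperature) declines with elevation at the lapse
    rate and with poleward latitude; bio12 (annual precipitation) rises
    orographically. The other eleven climate layers are seeded linear
    mixtures of bio1, bio12, dem and independent smooth fields, so the
    collinearity of real bioclim stacks is present. Soil layers are
    independent smooth random fields. With ``noise_sd = 0`` the world is
    fully deterministic given the terrain, which is what the closed-form
    elevation-band oracles rely on.
    """
    if lapse_C_per_km <= 0:
        raise ValueError("lapse_C_per_km must be > 0")
    grid = terrain.grid
    rng = np.random.default_rng(seed)
    lon, lat = grid.center_mesh()
    lat_ref = 0.5 * (grid.lat_min + grid.lat_max)
    z_km = terrain.dem / 1000.0

    bio1 = (
        sea_level_temp_C
        - lapse_C_per_km * z_km
        - lat_gradient_C_per_deg * np.abs(lat - lat_ref)
        + smooth_noise(grid.shape, noise_sd, noise_kernel_cells, rng)
    )
    bio12 = np.clip(
        precip_base_mm
        + orographic_mm_per_km * z_km
        + smooth_noise(grid.shape, noise_sd * precip_noise_scale, noise_kernel_cells, rng),
        0.0,
        None,
    )

    layers: dict[str, np.ndarray] = {"bio1": bio1, "bio12": bio12}
    # standardized ingredients for the declared mixtures
    ingredients = [
        (bio1 - bio1.mean()) / max(bio1.std(), 1e-9),
        (bio12 - bio12.mean()) / max(bio12.std(), 1e-9),
        (terrain.dem - terrain.dem.mean()) / max(terrain.dem.std(), 1e-9),
    ]
    for name in CLIMATE_LAYERS:
        if name in layers:
            continue
        w = rng.normal(0.0, 1.0, size=3)
        # independent component vanishes with noise_sd=0 so the whole
        # stack is deterministic in the noise-free oracle worlds
        own = smooth_noise(grid.shape, 1.0 if noise_sd > 0 else 0.0, noise_kernel_cells, rng)
        mix = w[0] * ingredients[0] + w[1] * ingredients[1] + w[2] * ingredients[2]
        scale = rng.uniform(1.0, 5.0)
        offset = rng.uniform(-5.0, 30.0)
        layers[name] = offset + scale * (mix + 0.5 * own)

    for name in SOIL_LAYERS:
        mean = rng.uniform(5.0, 50.0)
        sd = rng.uniform(1.0, 10.0)
        field_ = smooth_noise(grid.shape, 1.0, noise_kernel_cells, rng)
        layers[name] = mean + sd * field_

    layers["dem"] = terrain.dem.copy()
    return EnvStack(grid, layers)


def generate_future_ensemble(
    current: EnvStack,
    scenario_id: str,
    delta_T_C: float,
    precip_scale: float,
    n_gcm: int = 5,
    gcm_spread_sd: float = 0.3,
    precip_member_sd: float = 0.02,
    seed: int = 0,
    landuse: LandUseStack | None = None,
) -> ScenarioEnsemble:
    """Per-scenario ensemble of perturbed future climate members.

    Member g warms bio1 by ``delta_T_C + eta_g`` with one draw of eta per
    member (sd ``gcm_spread_sd``, the between-model spread), and scales
    the four precipitation layers by ``precip_scale`` with a member-level
    multiplicative jitter. Soil layers and the DEM are unchanged.
    """
    if n_gcm < 1:
        raise ValueError("n_gcm must be >= 1")
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_gcm):
        eta = rng.normal(0.0, gcm_spread_sd) if gcm_spread_sd > 0 else 0.0
        nu = rng.normal(0.0, precip_member_sd) if precip_member_sd > 0 else 0.0
        member = current.copy()
        member.layers["bio1"] = member.layers["bio1"] + delta_T_C + eta
        for p in PRECIP_LAYERS:
            member.layers[p] = np.clip(member.layers[p] * precip_scale * (1.0 + nu), 0.0, None)
        members.append(member)
    return ScenarioEnsemble(scenario_id=scenario_id, members=members, landuse=landuse)


def generate_landuse(
    terrain: TerrainModel,
    scenario_id: str,
    crop_pressure: float = 0.0,
    seed: int = 0,
    class_names: list[str] | None = None,
    noise_kernel_cells: float = 4.0,
    lowland_scale_m: float = 500.0,
) -> LandUseStack:
    """Per-cell land-use class fractions (logistic-normal random field).

    Each class gets a baseline log-preference plus a smooth spatial
    field; the softmax across classes yields fractions that sum to one.
    ``crop_pressure`` adds log-mass to the crop/urban classes with a
    weight decaying exponentially in elevation, so conversion pressure
    concentrates in lowlands. The scenario id is a tag only: with
    ``crop_pressure = 0`` and the same seed the stack equals the
    baseline stack.
    """
    names = list(class_names) if class_names is not None else list(DEFAULT_LANDUSE_CLASSES)
    missing = [c for c in EXCLUDED_LANDUSE_CLASSES if c not in names]
    if missing:
        raise ValueError(f"class list must include the excluded classes; missing {missing}")
    if len([c for c in names if c not in EXCLUDED_LANDUSE_CLASSES]) < 2:
        raise ValueError("class list needs at least two natural classes")
    rng = np.random.default_rng(seed)
    grid = terrain.grid
    base_pref = {c: (1.0 if c not in EXCLUDED_LANDUSE_CLASSES else -1.5) for c in names}
    base_pref["urban"] = -2.5
    lowland = np.exp(-terrain.dem / lowland_scale_m)
    logits = np.empty((len(names), *grid.shape))
    for i, c in enumerate(names):
        logits[i] = base_pref[c] + smooth_noise(grid.shape, 1.5, noise_kernel_cells, rng)
        if c in EXCLUDED_LANDUSE_CLASSES:
            logits[i] += crop_pressure * lowland
    logits -= logits.max(axis=0, keepdims=True)
    fr = np.exp(logits)
    fr /= fr.sum(axis=0, keepdims=True)
    return LandUseStack(grid=grid, class_names=names, fractions=fr)


def gaussian_suitability(
    bio1: np.ndarray,
    bio12: np.ndarray,
    niche_center: tuple[float, float],
    niche_width: tuple[float, float],
) -> np.ndarray:
    """Bivariate Gaussian niche on (bio1, bio12); an infinite width
    disables that axis. Peaks at exactly 1 at the niche centre."""
    muT, muP = niche_center
    sT, sP = niche_width
    if sT <= 0 or sP <= 0:
        raise ValueError("niche widths must be > 0")
    expo = np.zeros_like(np.asarray(bio1, dtype=float))
    if np.isfinite(sT):
        expo = expo + (bio1 - muT) ** 2 / (2.0 * sT**2)
    if np.isfinite(sP):
        expo = expo + (bio12 - muP) ** 2 / (2.0 * sP**2)
    return np.exp(-expo)


def simulate_species(
    env: EnvStack,
    species_id: str,
    niche_center: tuple[float, float],
    niche_width: tuple[float, float],
    tau: float,
    traits: SpeciesTraits,
    n_presence: int,
    sampling_bias_exp: float = 1.0,
    seed: int = 0,
    year_range: tuple[int, int] = (1981, 2020),
) -> tuple[VirtualSpecies, pd.DataFrame]:
    """Sample clustered presence records from a virtual species' truth range.

    The truth range is the set of cells with suitability >= tau; records
    are sampled without replacement with probability proportional to
    suitability**sampling_bias_exp, then jittered uniformly within the
    cell and assigned a uniform collection year, emulating the
    spatially-biased, post-1981 records the curation stage expects.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    grid = env.grid
    suit = gaussian_suitability(env.layers["bio1"], env.layers["bio12"], niche_center, niche_width)
    truth = suit >= tau
    n_truth = int(truth.sum())
    if n_truth < n_presence:
        raise InfeasibleSampleError(
            f"{species_id}: truth range has {n_truth} cells, fewer than n_presence={n_presence}"
        )
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(truth)
    w = suit[rows, cols] ** sampling_bias_exp
    p = w / w.sum()
    idx = rng.choice(rows.size, size=n_presence, replace=False, p=p)
    res = grid.resolution
    west = grid.lon_min + cols[idx] * res
    north = grid.lat_max - rows[idx] * res
    lon = west + rng.uniform(0.0, 1.0, size=n_presence) * res
    lat = north - rng.uniform(0.0, 1.0, size=n_presence) * res
    years = rng.integers(year_range[0], year_range[1] + 1, size=n_presence)
    occ = pd.DataFrame(
        {
            "species": species_id,
            "decimalLongitude": lon,
            "decimalLatitude": lat,
            "year": years,
            "source": "synthetic",
        }
    )
    vs = VirtualSpecies(
        species_id=species_id,
        niche_center=niche_center,
        niche_width=niche_width,
        tau=tau,
        traits=traits,
        truth_range=truth,
    )
    return vs, occ
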