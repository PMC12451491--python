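"""Run configuration: defaults, YAML round-trip and validation.

Analysis parameters default to the protocol values the pipeline is
built around (year cutoff 1981, 1-km record buffers, >= 14 occupied
cells, 75th-percentile mountain association, 10,000 background points,
250-km blocks in 5 folds, AUC gate 0.70, 70-year horizon, 5-member
ensembles with 3-of-5 consensus, the nine excluded land-cover classes).
``validate_config`` reports any deviation from these defaults as well
as outright inconsistencies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .world import DEFAULT_LANDUSE_CLASSES, EXCLUDED_LANDUSE_CLASSES

__all__ = ["WorldConfig", "ScenarioConfig", "PipelineConfig", "validate_config", "load_config", "save_config"]


@dataclass
class ScenarioConfig:
    """Climate/land-use forcing of one shared socioeconomic pathway."""

    scenario_id: str
    delta_T_C: float
    precip_scale: float
    crop_pressure: float


#: end-of-century forcing used for the three pathways in the synthetic study
DEFAULT_SCENARIOS = [
    ScenarioConfig("SSP1.26", delta_T_C=1.8, precip_scale=1.02, crop_pressure=0.5),
    ScenarioConfig("SSP3.70", delta_T_C=3.7, precip_scale=0.95, crop_pressure=2.0),
    ScenarioConfig("SSP5.85", delta_T_C=4.4, precip_scale=0.90, crop_pressure=3.0),
]


@dataclass
class WorldConfig:
    """Synthetic-world geometry, climate and virtual-flora parameters."""

    lon_min: float = 20.0
    lon_max: float = 30.0
    lat_min: float = -35.0
    lat_max: float = -25.0
    resolution: float = 0.05
    # terrain
    n_ridges: int = 3
    amplitude_m: float = 2500.0
    base_m: float = 200.0
    terrain_noise_sd: float = 50.0
    mountain_elev_cut_m: float = 1000.0
    # climate
    sea_level_temp_C: float = 26.0
    lapse_C_per_km: float = 6.5
    lat_gradient_C_per_deg: float = 0.3
    precip_base_mm: float = 900.0
    orographic_mm_per_km: float = 400.0
    climate_noise_sd: float = 0.3
    noise_kernel_cells: float = 3.0
    # ensemble spread
    gcm_spread_sd: float = 0.3
    precip_member_sd: float = 0.02
    # virtual flora
    n_species: int = 24
    n_presence: int = 120
    sampling_bias_exp: float = 1.0
    tau: float = 0.5
    sigma_T_range: tuple[float, float] = (0.8, 2.0)
    sigma_P_range: tuple[float, float] = (150.0, 400.0)
    #: disable the precipitation niche axis (oracle worlds where the
    #: truth range is a pure elevation band)
    temperature_only_niche: bool = False
    #: elevation window (m) the niche optima are drawn from; None = the
    #: full terrain range
    niche_elevation_range: tuple[float, float] | None = None
    landuse_classes: list[str] = field(default_factory=lambda: list(DEFAULT_LANDUSE_CLASSES))


@dataclass
class PipelineConfig:
    seed: int = 0
    world: WorldConfig = field(default_factory=WorldConfig)
    scenarios: list[ScenarioConfig] = field(default_factory=lambda: [dataclasses.replace(s) for s in DEFAULT_SCENARIOS])
    year_min: int = 1981
    buffer_km: float = 1.0
    min_cells: int = 14
    mountain_percentile: float = 75.0
    n_background: int = 10_000
    block_km: float = 250.0
    k_folds: int = 5
    auc_min: float = 0.70
    lam: float = 1.0
    horizon_years: float = 70.0
    n_gcm: int = 5
    min_agree: int = 3
    excluded_landuse: list[str] = field(default_factory=lambda: list(EXCLUDED_LANDUSE_CLASSES))
    clip_fraction: float = 0.05
    predictors: list[str] | None = None  # None = all climate + soil layers
    n_perm: int = 10
    mask_current: bool = False  # apply the land-use mask to the baseline too
    unlimited_dispersal: bool = False  # skip the dispersal constraint entirely


_PROTOCOL_DEFAULTS = {
    "year_min": 1981,
    "buffer_km": 1.0,
    "min_cells": 14,
    "mountain_percentile": 75.0,
    "n_background": 10_000,
    "block_km": 250.0,
    "k_folds": 5,
    "auc_min": 0.70,
    "horizon_years": 70.0,
    "n_gcm": 5,
    "min_agree": 3,
}


def validate_config(config: PipelineConfig) -> list[dict[str, str]]:
    """Consistency checks plus a deviation report against the protocol
    defaults. Returns a list of {level, field, message} entries;
    level 'error' marks configurations that cannot run."""
    report: list[dict[str, str]] = []

    def err(field_: str, msg: str) -> None:
        report.append({"level": "error", "field": field_, "message": msg})

    def dev(field_: str, msg: str) -> None:
        report.append({"level": "deviation", "field": field_, "message": msg})

    if config.min_agree > config.n_gcm or config.min_agree < 1:
        err("min_agree", f"min_agree={config.min_agree} incompatible with n_gcm={config.n_gcm}")
    if config.world.resolution <= 0:
        err("world.resolution", "resolution must be > 0")
    if not (0 <= config.clip_fraction < 1):
        err("clip_fraction", "clip_fraction must lie in [0, 1)")
    missing = [c for c in config.excluded_landuse if c not in config.world.landuse_classes]
    if missing:
        err("excluded_landuse", f"classes {missing} absent from world.landuse_classes")
    if config.k_folds < 2:
        err("k_folds", "k_folds must be >= 2")
    if config.lam < 0:
        err("lam", "lam must be >= 0")

    for fld, default in _PROTOCOL_DEFAULTS.items():
        val = getattr(config, fld)
        if val != default:
            dev(fld, f"{fld}={val} deviates from the protocol default {default}")
    if sorted(config.excluded_landuse) != sorted(EXCLUDED_LANDUSE_CLASSES):
        dev("excluded_landuse", "excluded land-cover classes differ from the protocol's nine")
    return report


def _to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["world"]["sigma_T_range"] = list(d["world"]["sigma_T_range"])
    d["world"]["sigma_P_range"] = list(d["world"]["sigma_P_range"])
    if d["world"]["niche_elevation_range"] is not None:
        d["world"]["niche_elevation_range"] = list(d["world"]["niche_elevation_range"])
    return d


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    world_doc = doc.pop("world", {})
    for key in ("sigma_T_range", "sigma_P_range", "niche_elevation_range"):
        if world_doc.get(key) is not None:
            world_doc[key] = tuple(world_doc[key])
    scen_doc = doc.pop("scenarios", None)
    cfg = PipelineConfig(
        world=WorldConfig(**world_doc),
        scenarios=[ScenarioConfig(**s) for s in scen_doc] if scen_doc is not None else None,
        **doc,
    )
    if cfg.scenarios is None:
        cfg.scenarios = [dataclasses.replace(s) for s in DEFAULT_SCENARIOS]
    return cfg
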