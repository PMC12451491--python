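"""End-to-end orchestration of the synthetic range-shift study.

Stages: synthetic world -> occurrence curation -> mountain-cohort
selection -> per-species suitability models (block-CV gated) ->
dispersal reach -> scenario projection (ensemble consensus + land-use
mask) -> range/richness accounting. Per-species failures (infeasible
sampling, rejected models, empty ranges) are logged and skipped, never
fatal. Every stage draws its randomness from a child seed derived by
hashing the master seed with the stage label, so a run is reproducible
end to end and stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import __version__
from .config import PipelineConfig, save_config, validate_config
from .dispersal import SpeciesTraits, build_dispersal_spec, default_coefficient_table, dispersal_mask
from .grid import GridSpec, build_grid
from .metrics import (
    cohort_summary,
    proportional_loss_map,
    range_change,
    range_position_stats,
    richness_change,
    richness_clip,
    stack_richness,
)
from .mountains import score_species, select_cohort
from .occurrences import cell_counts, clean_records, eligible_species, thin_to_grid
from .projection import binarize, consensus, dominant_class, future_range, habitat_mask
from .rasters import write_ascii_grid, write_geojson
from .sdm import (
    assign_blocks,
    cross_validate,
    fit_model,
    permutation_importance,
    predict,
    sample_background,
    select_threshold,
)
from .world import (
    CLIMATE_LAYERS,
    SOIL_LAYERS,
    EnvStack,
    InfeasibleSampleError,
    ScenarioEnsemble,
    TerrainModel,
    VirtualSpecies,
    generate_climate,
    generate_future_ensemble,
    generate_landuse,
    generate_terrain,
    simulate_species,
)

__all__ = ["RunResult", "child_seed", "run_pipeline"]

STAGES = ["world", "occurrences", "cohort", "models", "projection", "metrics"]

# growth-form and syndrome frequencies the virtual flora is drawn from,
# mirroring a herb-dominated flora where animal dispersal is the most
# and ant dispersal the least frequent syndrome
_FORM_WEIGHTS = {
    "herb": 0.42, "shrub": 0.21, "tree": 0.10, "shrub_or_tree": 0.14,
    "herb_or_shrub": 0.08, "fern": 0.05,
}
_SYNDROME_WEIGHTS = {
    "animal": 0.40, "wind_adapted": 0.25, "wind_nonadapted": 0.20,
    "ballistic": 0.10, "ant": 0.05,
}


def child_seed(master_seed: int, stage: str) -> int:
    """Stage-scoped seed: hash of 'master:stage', below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SpeciesModelRecord:
    species_id: str
    cv_auc: list[float]
    mean_cv_auc: float
    accepted: bool
    threshold: float = float("nan")
    importances: dict[str, float] = field(default_factory=dict)
    total_dispersal_km: float = float("nan")


@dataclass
class RunResult:
    config: PipelineConfig
    grid: GridSpec
    terrain: TerrainModel | None = None
    env: EnvStack | None = None
    ensembles: dict[str, ScenarioEnsemble] = field(default_factory=dict)
    flora: dict[str, VirtualSpecies] = field(default_factory=dict)
    occurrences: pd.DataFrame | None = None
    cleaned: pd.DataFrame | None = None
    thinned: pd.DataFrame | None = None
    associations: pd.DataFrame | None = None
    cohort: list[str] = field(default_factory=list)
    cohort_threshold: float = float("nan")
    models: dict = field(default_factory=dict)
    model_records: dict[str, SpeciesModelRecord] = field(default_factory=dict)
    current_ranges: dict[str, np.ndarray] = field(default_factory=dict)
    dispersal_masks: dict[str, np.ndarray] = field(default_factory=dict)
    future_ranges: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    per_species: pd.DataFrame | None = None
    cohort_summaries: dict[str, dict] = field(default_factory=dict)
    richness_current: np.ndarray | None = None
    richness_future: dict[str, np.ndarray] = field(default_factory=dict)
    skipped: list[dict] = field(default_factory=list)


def _draw_traits(rng: np.random.Generator) -> SpeciesTraits:
    forms = list(_FORM_WEIGHTS)
    form = rng.choice(forms, p=np.array(list(_FORM_WEIGHTS.values())) / sum(_FORM_WEIGHTS.values()))
    syn_names = list(_SYNDROME_WEIGHTS)
    p = np.array(list(_SYNDROME_WEIGHTS.values())) / sum(_SYNDROME_WEIGHTS.values())
    n_syn = 2 if rng.random() < 0.15 else 1
    syndromes = rng.choice(syn_names, size=n_syn, replace=False, p=p)
    # juvenile period known for roughly 40% of the flora
    juvenile = None
    if rng.random() < 0.4:
        base = {"herb": 3.0, "fern": 3.0, "herb_or_shrub": 4.0, "shrub": 5.0,
                "shrub_or_tree": 8.0, "tree": 10.0}[str(form)]
        juvenile = float(np.round(base * rng.uniform(0.6, 1.6), 1))
    return SpeciesTraits(
        growth_form=str(form),
        dispersal_syndromes=frozenset(str(s) for s in syndromes),
        juvenile_period_years=juvenile,
    )


def _build_world(cfg: PipelineConfig, result: RunResult) -> None:
    w = cfg.world
    grid = result.grid
    terrain = generate_terrain(
        grid,
        n_ridges=w.n_ridges,
        amplitude_m=w.amplitude_m,
        base_m=w.base_m,
        noise_sd=w.terrain_noise_sd,
        mountain_elev_cut_m=w.mountain_elev_cut_m,
        seed=child_seed(cfg.seed, "terrain"),
        noise_kernel_cells=w.noise_kernel_cells,
    )
    env = generate_climate(
        terrain,
        sea_level_temp_C=w.sea_level_temp_C,
        lapse_C_per_km=w.lapse_C_per_km,
        lat_gradient_C_per_deg=w.lat_gradient_C_per_deg,
        precip_base_mm=w.precip_base_mm,
        orographic_mm_per_km=w.orographic_mm_per_km,
        noise_sd=w.climate_noise_sd,
        seed=child_seed(cfg.seed, "climate"),
        noise_kernel_cells=w.noise_kernel_cells,
    )
    result.terrain, result.env = terrain, env
    for sc in cfg.scenarios:
        landuse = generate_landuse(
            terrain,
            sc.scenario_id,
            crop_pressure=sc.crop_pressure,
            seed=child_seed(cfg.seed, "landuse"),
            class_names=w.landuse_classes,
        )
        result.ensembles[sc.scenario_id] = generate_future_ensemble(
            env,
            sc.scenario_id,
            delta_T_C=sc.delta_T_C,
            precip_scale=sc.precip_scale,
            n_gcm=cfg.n_gcm,
            gcm_spread_sd=w.gcm_spread_sd,
            precip_member_sd=w.precip_member_sd,
            seed=child_seed(cfg.seed, f"ensemble:{sc.scenario_id}"),
            landuse=landuse,
        )

    # virtual flora: niche optima placed along the elevation gradient so
    # that mountain association varies across species
    rng = np.random.default_rng(child_seed(cfg.seed, "flora"))
    if w.niche_elevation_range is not None:
        z_lo, z_hi = w.niche_elevation_range
    else:
        z_lo, z_hi = 0.0, 0.9 * float(np.quantile(terrain.dem, 0.99))
    occ_tables = []
    for i in range(w.n_species):
        sp_id = f"sp{i:03d}"
        z_opt = rng.uniform(z_lo, z_hi)
        muT = w.sea_level_temp_C - w.lapse_C_per_km * z_opt / 1000.0
        muP = w.precip_base_mm + w.orographic_mm_per_km * z_opt / 1000.0
        sT = rng.uniform(*w.sigma_T_range)
        sP = np.inf if w.temperature_only_niche else rng.uniform(*w.sigma_P_range)
        traits = _draw_traits(rng)
        try:
            vs, occ = simulate_species(
                env,
                sp_id,
                niche_center=(muT, muP),
                niche_width=(sT, sP),
                tau=w.tau,
                traits=traits,
                n_presence=w.n_presence,
                sampling_bias_exp=w.sampling_bias_exp,
                seed=child_seed(cfg.seed, f"species:{sp_id}"),
            )
        except InfeasibleSampleError as exc:
            result.skipped.append({"species": sp_id, "stage": "world", "reason": str(exc)})
            continue
        result.flora[sp_id] = vs
        occ_tables.append(occ)
    if not occ_tables:
        raise RuntimeError("no virtual species could be sampled; world misconfigured")
    result.occurrences = pd.concat(occ_tables, ignore_index=True)


def _curate(cfg: PipelineConfig, result: RunResult) -> None:
    grid = result.grid
    region = [shapely.box(grid.lon_min, grid.lat_min, grid.lon_max, grid.lat_max)]
    result.cleaned = clean_records(result.occurrences, region_mask_polygons=region, year_min=cfg.year_min)
    result.thinned = thin_to_grid(result.cleaned, grid)


def _select_cohort(cfg: PipelineConfig, result: RunResult) -> None:
    counts = cell_counts(result.thinned)
    eligible = set(eligible_species(counts, cfg.min_cells))
    assoc = score_species(result.thinned, result.terrain.mountain_polygons, buffer_km=cfg.buffer_km)
    result.associations = assoc
    selection = select_cohort(assoc, percentile=cfg.mountain_percentile, min_cells=cfg.min_cells)
    result.cohort = [s for s in selection.selected if s in eligible]
    result.cohort_threshold = selection.threshold
    for sp in sorted(set(assoc["species"]) - set(result.cohort)):
        result.skipped.append({"species": sp, "stage": "cohort", "reason": "below mountain-association threshold or too few cells"})


def _env_at_cells(env: EnvStack, rows: np.ndarray, cols: np.ndarray, predictors: list[str]) -> pd.DataFrame:
    return pd.DataFrame({p: env.layers[p][rows, cols] for p in predictors})


def _fit_models(cfg: PipelineConfig, result: RunResult) -> None:
    env = result.env
    grid = result.grid
    predictors = cfg.predictors or (CLIMATE_LAYERS + SOIL_LAYERS)
    land_mask = np.ones(grid.shape, dtype=bool)
    background = sample_background(land_mask, grid, n=cfg.n_background,
                                  seed=child_seed(cfg.seed, "background"))
    bg_vals = _env_at_cells(env, background["row"].to_numpy(), background["col"].to_numpy(), predictors)

    for sp in list(result.cohort):
        sub = result.thinned[result.thinned["species"] == sp]
        rows = sub["row"].to_numpy()
        cols = sub["col"].to_numpy()
        pres_vals = _env_at_cells(env, rows, cols, predictors)
        lon = np.concatenate([sub["decimalLongitude"].to_numpy(), background["lon"].to_numpy()])
        lat = np.concatenate([sub["decimalLatitude"].to_numpy(), background["lat"].to_numpy()])
        is_pres = np.concatenate([np.ones(len(sub), bool), np.zeros(len(background), bool)])
        try:
            blocks = assign_blocks(lon, lat, is_pres, grid, block_size_km=cfg.block_km,
                                   k=cfg.k_folds, seed=child_seed(cfg.seed, f"blocks:{sp}"))
            fold_p = blocks.fold_id[: len(sub)]
            fold_b = blocks.fold_id[len(sub):]
            aucs, mean_auc, accepted = cross_validate(
                pres_vals, bg_vals, predictors, fold_p, fold_b, lam=cfg.lam, auc_min=cfg.auc_min
            )
        except ValueError as exc:
            result.skipped.append({"species": sp, "stage": "models", "reason": str(exc)})
            result.cohort.remove(sp)
            continue
        rec = SpeciesModelRecord(sp, [float(a) for a in aucs], mean_auc, accepted)
        result.model_records[sp] = rec
        if not accepted:
            result.skipped.append({"species": sp, "stage": "models",
                                   "reason": f"mean CV AUC {mean_auc:.3f} below gate {cfg.auc_min}"})
            result.cohort.remove(sp)
            continue
        model = fit_model(pres_vals, bg_vals, predictors, lam=cfg.lam)
        model.cv_auc, model.mean_cv_auc, model.accepted = rec.cv_auc, mean_auc, True
        model.threshold = select_threshold(model.score_raw(pres_vals), model.score_raw(bg_vals))
        model.importances = permutation_importance(
            model, pres_vals, bg_vals, n_perm=cfg.n_perm,
            seed=child_seed(cfg.seed, f"importance:{sp}"),
        )
        rec.threshold = model.threshold
        rec.importances = model.importances
        current = binarize(predict(model, env), model.threshold)
        if not current.any():
            result.skipped.append({"species": sp, "stage": "models", "reason": "empty current range"})
            result.cohort.remove(sp)
            continue
        if cfg.mask_current:
            baseline_lu = result.ensembles[cfg.scenarios[0].scenario_id].landuse
            current = current & habitat_mask(dominant_class(baseline_lu), baseline_lu.class_names, cfg.excluded_landuse)
        result.models[sp] = model
        result.current_ranges[sp] = current

        traits = result.flora[sp].traits if sp in result.flora else None
        if cfg.unlimited_dispersal:
            result.dispersal_masks[sp] = np.ones(grid.shape, dtype=bool)
        elif traits is not None:
            spec = build_dispersal_spec(traits, horizon_years=cfg.horizon_years)
            rec.total_dispersal_km = spec.total_distance_km
            result.dispersal_masks[sp] = dispersal_mask(current, spec.total_distance_km, grid)
        else:
            result.dispersal_masks[sp] = np.ones(grid.shape, dtype=bool)


def _project(cfg: PipelineConfig, result: RunResult) -> None:
    for sc in cfg.scenarios:
        ensemble = result.ensembles[sc.scenario_id]
        habitat = habitat_mask(dominant_class(ensemble.landuse), ensemble.landuse.class_names, cfg.excluded_landuse)
        per_species: dict[str, np.ndarray] = {}
        for sp, model in result.models.items():
            members = [binarize(predict(model, m), model.threshold) for m in ensemble.members]
            cons = consensus(members, min_agree=cfg.min_agree)
            per_species[sp] = future_range(cons, result.dispersal_masks[sp], habitat)
        result.future_ranges[sc.scenario_id] = per_species


def _summarize(cfg: PipelineConfig, result: RunResult) -> None:
    grid = result.grid
    dem = result.terrain.dem
    rows = []
    for sc in cfg.scenarios:
        for sp, current in result.current_ranges.items():
            fut = result.future_ranges[sc.scenario_id][sp]
            rc = range_change(current, fut, grid, species_id=sp, scenario=sc.scenario_id)
            cur_stats = range_position_stats(current, dem, grid)
            row = {
                "species": sp,
                "scenario": sc.scenario_id,
                "current_area_km2": rc.current_area_km2,
                "future_area_km2": rc.future_area_km2,
                "loss_pct": rc.loss_pct,
                "gain_pct": rc.gain_pct,
                "net_pct": rc.net_pct,
                "current_mean_elev_m": cur_stats["mean_elev_m"],
                "current_min_lat": cur_stats["min_lat"],
                "current_max_lat": cur_stats["max_lat"],
            }
            if fut.any():
                fut_stats = range_position_stats(fut, dem, grid)
                row.update(
                    future_mean_elev_m=fut_stats["mean_elev_m"],
                    mean_elev_shift_m=fut_stats["mean_elev_m"] - cur_stats["mean_elev_m"],
                    southern_limit_increase=fut_stats["min_lat"] < cur_stats["min_lat"],
                    northern_limit_increase=fut_stats["max_lat"] > cur_stats["max_lat"],
                )
            else:
                row.update(future_mean_elev_m=np.nan, mean_elev_shift_m=np.nan,
                           southern_limit_increase=False, northern_limit_increase=False)
            rows.append(row)
    result.per_species = pd.DataFrame(rows)
    if result.per_species.empty:
        return

    ranges_now = [result.current_ranges[sp] for sp in sorted(result.current_ranges)]
    if ranges_now:
        result.richness_current = stack_richness(ranges_now)
    for sc in cfg.scenarios:
        sub = result.per_species[result.per_species["scenario"] == sc.scenario_id]
        if len(sub):
            result.cohort_summaries[sc.scenario_id] = cohort_summary(sub)
        futs = [result.future_ranges[sc.scenario_id][sp] for sp in sorted(result.current_ranges)]
        if futs:
            result.richness_future[sc.scenario_id] = stack_richness(futs)


def _write_outputs(cfg: PipelineConfig, result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out_dir / "config.yaml")
    if result.terrain is not None:
        write_ascii_grid(out_dir / "dem.asc", result.grid, result.terrain.dem)
        write_geojson(out_dir / "mountains.geojson", result.terrain.mountain_polygons)
    if result.cleaned is not None:
        result.cleaned.to_csv(out_dir / "occurrences_cleaned.csv", index=False)
    if result.thinned is not None:
        result.thinned.to_csv(out_dir / "occurrences_thinned.csv", index=False)
    if result.associations is not None:
        assoc = result.associations.copy()
        assoc["selected"] = assoc["species"].isin(result.cohort)
        assoc.to_csv(out_dir / "mountain_associations.csv", index=False)
    if result.model_records:
        pd.DataFrame(
            [
                {
                    "species": r.species_id,
                    "mean_cv_auc": r.mean_cv_auc,
                    "accepted": r.accepted,
                    "threshold": r.threshold,
                    "total_dispersal_km": r.total_dispersal_km,
                }
                for r in result.model_records.values()
            ]
        ).to_csv(out_dir / "model_evaluation.csv", index=False)
    if result.per_species is not None:
        result.per_species.to_csv(out_dir / "per_species_changes.csv", index=False)
    if result.cohort_summaries:
        pd.DataFrame(result.cohort_summaries).to_csv(out_dir / "cohort_summary.csv")
    if result.richness_current is not None:
        write_ascii_grid(out_dir / "richness_current.asc", result.grid, result.richness_current)
        n_cohort = len(result.current_ranges)
        for sc_id, rich in result.richness_future.items():
            change = richness_change(result.richness_current, rich)
            clipped = richness_clip(change, result.richness_current, cfg.clip_fraction, n_cohort)
            write_ascii_grid(out_dir / f"richness_change__{sc_id}.asc", result.grid, clipped)
            loss = proportional_loss_map(
                [result.current_ranges[sp] for sp in sorted(result.current_ranges)],
                [result.future_ranges[sc_id][sp] for sp in sorted(result.current_ranges)],
            )
            write_ascii_grid(out_dir / f"proportional_loss__{sc_id}.asc", result.grid, loss)

    manifest = {
        "montrange_version": __version__,
        "master_seed": cfg.seed,
        "stage_seeds": {s: child_seed(cfg.seed, s) for s in ("terrain", "climate", "flora", "background")},
        "config_deviations": validate_config(cfg),
        "dispersal_table": "synthetic default (ordering-calibrated); see docs/methods.md",
        "dispersal_coefficients": default_coefficient_table().to_dict(orient="records"),
        "n_species_simulated": len(result.flora),
        "n_species_modelled": len(result.models),
        "cohort_threshold": result.cohort_threshold,
        "skipped": result.skipped,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    stop_after: str | None = None,
) -> RunResult:
    """Execute the study; returns the in-memory result and (optionally)
    writes rasters, CSV summaries and a machine-readable manifest.

    ``stop_after`` halts after the named stage (one of %s).
    """ % (STAGES,)
    errors = [e for e in validate_config(config) if e["level"] == "error"]
    if errors:
        raise ValueError("invalid config: " + "; ".join(e["message"] for e in errors))
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; expected one of {STAGES}")
    w = config.world
    grid = build_grid(w.lon_min, w.lon_max, w.lat_min, w.lat_max, w.resolution)
    result = RunResult(config=dataclasses.replace(config), grid=grid)

    stages = [
        ("world", _build_world),
        ("occurrences", _curate),
        ("cohort", _select_cohort),
        ("models", _fit_models),
        ("projection", _project),
        ("metrics", _summarize),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        for name, fn in stages:
            fn(config, result)
            if stop_after == name:
                break
    if out_dir is not None:
        _write_outputs(config, result, Path(out_dir))
    return result
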