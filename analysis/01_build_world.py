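#!/usr/bin/env python
"""Build the synthetic study world and report what it contains.

Generates the seeded virtual landscape (DEM + mountain polygons), the
current climate/soil stack, the three scenario ensembles with their
land-use stacks, and the virtual flora with its occurrence records.
Writes the world rasters and occurrence CSV under results/world/.
"""

import numpy as np

from montrange.experiments import demo_study_config
from montrange.pipeline import run_pipeline

SEED = 1

cfg = demo_study_config(SEED)
res = run_pipeline(cfg, out_dir="results/world", stop_after="world")

dem = res.terrain.dem
print(f"grid: {res.grid.n_rows} x {res.grid.n_cols} cells at {res.grid.resolution} deg")
print(f"elevation: {dem.min():.0f}-{dem.max():.0f} m "
      f"({(dem >= cfg.world.mountain_elev_cut_m).mean() * 100:.1f}% above the "
      f"{cfg.world.mountain_elev_cut_m:.0f} m mountain cutoff, "
      f"{len(res.terrain.mountain_polygons)} mountain polygons)")
bio1 = res.env.layers["bio1"]
print(f"bio1: {bio1.min():.1f} to {bio1.max():.1f} degC "
      f"(lapse {cfg.world.lapse_C_per_km} degC/km)")
print(f"scenarios: {[s.scenario_id for s in cfg.scenarios]}, "
      f"{cfg.n_gcm} ensemble members each")
print(f"virtual flora: {len(res.flora)} species, "
      f"{len(res.occurrences)} presence records")
mean_elev = {sp: dem[vs.truth_range].mean() for sp, vs in res.flora.items()}
print(f"species mean truth-range elevation: {min(mean_elev.values()):.0f}-"
      f"{max(mean_elev.values()):.0f} m")
print("world rasters and occurrence records written to results/world/")
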