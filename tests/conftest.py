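import numpy as np
import pytest

from montrange.config import PipelineConfig, WorldConfig
from montrange.grid import build_grid
from montrange.world import generate_climate, generate_terrain


@pytest.fixture(scope="session")
def small_grid():
    """200x200 cells at 0.05 degrees over a Southern-Hemisphere extent."""
    return build_grid(20.0, 30.0, -35.0, -25.0, 0.05)


@pytest.fixture(scope="session")
def tiny_grid():
    return build_grid(20.0, 22.0, -32.0, -30.0, 0.1)


@pytest.fixture(scope="session")
def noise_free_world():
    """Deterministic world: no terrain/climate noise, no latitude
    gradient, so bio1 is an exact linear function of elevation."""
    grid = build_grid(20.0, 25.0, -32.0, -27.0, 0.05)
    terrain = generate_terrain(
        grid, n_ridges=4, amplitude_m=2500.0, base_m=100.0, noise_sd=0.0,
        mountain_elev_cut_m=1000.0, seed=7,
    )
    env = generate_climate(
        terrain, sea_level_temp_C=26.0, lapse_C_per_km=6.5,
        lat_gradient_C_per_deg=0.0, precip_base_mm=900.0,
        orographic_mm_per_km=400.0, noise_sd=0.0, seed=7,
    )
    return terrain, env


@pytest.fixture(scope="session")
def noisy_world():
    grid = build_grid(20.0, 25.0, -32.0, -27.0, 0.05)
    terrain = generate_terrain(grid, seed=3)
    env = generate_climate(terrain, noise_sd=0.3, seed=3)
    return terrain, env


def demo_config(seed: int = 1) -> PipelineConfig:
    """Small but complete study configuration used by smoke and
    determinism tests."""
    return PipelineConfig(
        seed=seed,
        world=WorldConfig(resolution=0.1, n_species=6, n_presence=60),
        n_background=500,
        n_gcm=2,
        min_agree=2,
        n_perm=2,
    )


@pytest.fixture()
def demo_cfg():
    return demo_config()
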