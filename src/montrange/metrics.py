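"""Range-change accounting, richness stacking and summary statistics.

Areas are exact spherical cell areas (authalic radius 6371.0088 km), so
loss/gain/net percentages are free of projection or resampling error.
Loss and gain are both expressed relative to the current range area and
net = gain - loss by construction. Cohort summaries follow the
convention that a species with net change exactly zero counts as a
gainer, so losers + gainers = cohort size; percentages are rounded
half-up to integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, cell_area_km2

__all__ = [
    "RangeChangeSummary",
    "range_change",
    "range_position_stats",
    "stack_richness",
    "richness_change",
    "richness_clip",
    "proportional_loss_map",
    "cohort_summary",
    "regional_composition",
    "bootstrap_mean_ci",
    "group_ttest",
    "round_half_up",
]


@dataclass(frozen=True)
class RangeChangeSummary:
    species_id: str
    scenario: str
    current_area_km2: float
    future_area_km2: float
    loss_pct: float
    gain_pct: float
    net_pct: float


def _area_of(mask: np.ndarray, row_areas: np.ndarray) -> float:
    return float((mask.sum(axis=1) * row_areas).sum())


def range_change(
    current: np.ndarray,
    future: np.ndarray,
    grid: GridSpec,
    species_id: str = "",
    scenario: str = "",
) -> RangeChangeSummary:
    """Loss/gain/net percentages of the future vs current binary range.

    loss = area(current & ~future) / area(current) * 100
    gain = area(future & ~current) / area(current) * 100
    net  = gain - loss
    """
    cur = np.asarray(current, dtype=bool)
    fut = np.asarray(future, dtype=bool)
    if cur.shape != grid.shape or fut.shape != grid.shape:
        raise ValueError("ranges not aligned to grid")
    row_areas = cell_area_km2(grid)
    a_cur = _area_of(cur, row_areas)
    if a_cur <= 0:
        raise ValueError(f"empty current range for species {species_id!r}")
    a_fut = _area_of(fut, row_areas)
    loss = _area_of(cur & ~fut, row_areas) / a_cur * 100.0
    gain = _area_of(fut & ~cur, row_areas) / a_cur * 100.0
    return RangeChangeSummary(
        species_id=species_id,
        scenario=scenario,
        current_area_km2=a_cur,
        future_area_km2=a_fut,
        loss_pct=loss,
        gain_pct=gain,
        net_pct=gain - loss,
    )


def range_position_stats(range_mask: np.ndarray, dem: np.ndarray, grid: GridSpec) -> dict[str, float]:
    """Unweighted elevation mean/min/max and latitude min/max over
    presence cells (cell centers)."""
    mask = np.asarray(range_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty range")
    elev = dem[mask]
    lat = grid.center_mesh()[1][mask]
    return {
        "mean_elev_m": float(elev.mean()),
        "min_elev_m": float(elev.min()),
        "max_elev_m": float(elev.max()),
        "min_lat": float(lat.min()),
        "max_lat": float(lat.max()),
    }


def stack_richness(ranges: list[np.ndarray]) -> np.ndarray:
    """Per-cell count of species present (stacked binary ranges)."""
    if not ranges:
        raise ValueError("no ranges to stack")
    return np.sum([np.asarray(r, dtype=bool) for r in ranges], axis=0).astype(int)


def richness_change(current_map: np.ndarray, future_map: np.ndarray) -> np.ndarray:
    return np.asarray(future_map, dtype=int) - np.asarray(current_map, dtype=int)


def richness_clip(values: np.ndarray, current_richness: np.ndarray, fraction: float, cohort_size: int) -> np.ndarray:
    """Hide (NaN) cells whose current richness is at most
    fraction * cohort size; shows only areas dense enough that single
    species' responses do not dominate."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    out = np.asarray(values, dtype=float).copy()
    out[np.asarray(current_richness) <= fraction * cohort_size] = np.nan
    return out


def proportional_loss_map(
    current_ranges: list[np.ndarray], future_ranges: list[np.ndarray]
) -> np.ndarray:
    """Per cell: species present now but absent in the future, divided by
    species present now; expansions are ignored; cells with no current
    species are NaN."""
    if len(current_ranges) != len(future_ranges):
        raise ValueError("need matching current/future range lists")
    cur = np.array([np.asarray(r, dtype=bool) for r in current_ranges])
    fut = np.array([np.asarray(r, dtype=bool) for r in future_ranges])
    n_now = cur.sum(axis=0).astype(float)
    n_lost = (cur & ~fut).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n_now > 0, n_lost / n_now, np.nan)
    return out


def round_half_up(x: float) -> int:
    """Ordinary half-up rounding (0.5 -> 1), as printed summary tables use."""
    return int(np.floor(x + 0.5))


def cohort_summary(per_species: pd.DataFrame) -> dict[str, float]:
    """Cohort-level accounting for one scenario.

    Input columns: net_pct, loss_pct, gain_pct, and optionally the
    elevation/latitude shift columns (mean_elev_shift_m,
    southern_limit_increase, northern_limit_increase as booleans).
    net_pct == 0 counts as a gain so losers + gainers = cohort size.
    """
    n = len(per_species)
    if n < 1:
        raise ValueError("empty cohort")
    net = per_species["net_pct"].to_numpy(dtype=float)
    losers = net < 0
    gainers = ~losers
    out = {
        "n_species": n,
        "n_net_loss": int(losers.sum()),
        "n_net_gain": int(gainers.sum()),
        "pct_net_loss": round_half_up(100.0 * losers.sum() / n),
        "pct_net_gain": round_half_up(100.0 * gainers.sum() / n),
        "mean_net_change_pct": float(net.mean()),
        "mean_loss_all_pct": float(per_species["loss_pct"].mean()) if "loss_pct" in per_species else float("nan"),
        "mean_net_among_losers_pct": float(net[losers].mean()) if losers.any() else float("nan"),
        "mean_net_among_gainers_pct": float(net[gainers].mean()) if gainers.any() else float("nan"),
    }
    if "mean_elev_shift_m" in per_species:
        shift = per_species["mean_elev_shift_m"].to_numpy(dtype=float)
        up = shift > 0
        out.update(
            n_upward=int(up.sum()),
            n_downward=int((~up).sum()),
            pct_upward=round_half_up(100.0 * up.sum() / n),
            pct_downward=round_half_up(100.0 * (~up).sum() / n),
            mean_elev_shift_m=float(shift.mean()),
            mean_elev_shift_up_m=float(shift[up].mean()) if up.any() else float("nan"),
        )
    for side in ("southern", "northern"):
        col = f"{side}_limit_increase"
        if col in per_species:
            inc = per_species[col].to_numpy(dtype=bool)
            out[f"n_{side}_increase"] = int(inc.sum())
            out[f"pct_{side}_increase"] = round_half_up(100.0 * inc.sum() / n)
    return out


def regional_composition(counts: pd.Series) -> pd.Series:
    """Percent share per region of the column total (species may occur in
    several regions, so the total is the sum of the per-region counts,
    not the cohort size). Rounded to one decimal, printed-table style."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("no regional counts")
    return (100.0 * counts / total).round(1)


def bootstrap_mean_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def group_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Two-sample pooled-variance t statistic and df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    return float(t), int(df)
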