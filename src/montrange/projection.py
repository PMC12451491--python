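"""From per-GCM suitability to a single constrained future range.

Per scenario, each ensemble member's suitability raster is binarized at
the species' threshold; a cell enters the consensus range when at least
``min_agree`` members (default 3 of 5) call it a presence; and the final
future range is the conjunction of consensus, dispersal reach and
land-use habitat availability (cells whose dominant land-cover class is
cropland/urban are removed).
"""

from __future__ import annotations

import numpy as np

from .world import EXCLUDED_LANDUSE_CLASSES, LandUseStack

__all__ = [
    "binarize",
    "consensus",
    "dominant_class",
    "habitat_mask",
    "future_range",
]


def binarize(suitability: np.ndarray, threshold: float) -> np.ndarray:
    """presence <=> score >= threshold; missing cells are absence."""
    s = np.asarray(suitability, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(s), s >= threshold, False)


def consensus(member_ranges: list[np.ndarray], min_agree: int = 3) -> np.ndarray:
    """presence <=> at least ``min_agree`` members agree on presence."""
    if not member_ranges:
        raise ValueError("need at least one member range")
    if not (1 <= min_agree <= len(member_ranges)):
        raise ValueError(f"min_agree={min_agree} out of range for {len(member_ranges)} members")
    shape = member_ranges[0].shape
    for m in member_ranges:
        if m.shape != shape:
            raise ValueError("member ranges are not aligned")
    count = np.sum([np.asarray(m, dtype=bool) for m in member_ranges], axis=0)
    return count >= min_agree


def dominant_class(landuse: LandUseStack) -> np.ndarray:
    """Per-cell index (into class_names) of the largest class fraction;
    ties go to the earliest class in the list (argmax convention)."""
    return np.argmax(landuse.fractions, axis=0)


def habitat_mask(
    dominant: np.ndarray,
    class_names: list[str],
    excluded_classes: list[str] | None = None,
) -> np.ndarray:
    """available <=> dominant class not in the excluded set."""
    excluded = EXCLUDED_LANDUSE_CLASSES if excluded_classes is None else list(excluded_classes)
    unknown = [c for c in excluded if c not in class_names]
    if unknown:
        raise ValueError(f"excluded classes not in the stack: {unknown}")
    excluded_idx = np.array([class_names.index(c) for c in excluded], dtype=int)
    return ~np.isin(np.asarray(dominant), excluded_idx)


def future_range(
    consensus_range: np.ndarray,
    dispersal_mask: np.ndarray | None = None,
    habitat: np.ndarray | None = None,
) -> np.ndarray:
    """presence <=> consensus AND reachable AND available."""
    out = np.asarray(consensus_range, dtype=bool)
    for m in (dispersal_mask, habitat):
        if m is not None:
            if m.shape != out.shape:
                raise ValueError("masks not aligned with the consensus range")
            out = out & np.asarray(m, dtype=bool)
    return out
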