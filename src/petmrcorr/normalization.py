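"""PET activity normalizations: SUV and tumor-to-background ratio (TBR).

Both are strictly monotone per-voxel rescalings, so every downstream rank
statistic (Spearman) is exactly invariant to them; they only make values
comparable across patients on scatter plots and summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids_io import ParametricMap, ROIMask

__all__ = ["InjectionRecord", "UnitError", "to_suv", "to_tbr"]


class UnitError(ValueError):
    """Input map carries the wrong physical unit for this normalization."""


@dataclass(frozen=True)
class InjectionRecord:
    """Injected activity (MBq, decay-corrected to scan start) and body weight (kg)."""

    injected_activity_mbq: float
    body_weight_kg: float

    def __post_init__(self):
        if self.injected_activity_mbq <= 0 or self.body_weight_kg <= 0:
            raise ValueError("injected activity and body weight must be positive")


def to_suv(activity: ParametricMap, injection: InjectionRecord) -> ParametricMap:
    """Standardized uptake value: activity / (injected activity / body weight).

    SUV = A[kBq/mL] / (injected[kBq] / weight[g]), assuming 1 g/mL tissue
    density; decay correction to scan start is the caller's responsibility.
    """
    if activity.unit != "kBq/mL":
        raise UnitError(f"to_suv expects kBq/mL, got {activity.unit!r}")
    dose_per_gram = injection.injected_activity_mbq * 1e3 / (
        injection.body_weight_kg * 1e3)  # kBq / g
    return activity.with_values(activity.values / dose_per_gram, unit="SUV",
                                name=f"{activity.name}_SUV")


def to_tbr(activity: ParametricMap, background: ROIMask,
           statistic: str = "mean") -> ParametricMap:
    """Tumor-to-background ratio: divide by the background-muscle ROI level.

    The background statistic is the arithmetic mean of the muscle ROI by
    default (median available); a non-positive background level is an error.
    """
    if background.grid != activity.grid:
        raise ValueError("background mask must live on the activity grid")
    vals = activity.values[background.membership]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("background ROI has no valid voxels")
    if statistic == "mean":
        level = float(vals.mean())
    elif statistic == "median":
        level = float(np.median(vals))
    else:
        raise ValueError(f"unknown background statistic {statistic!r}")
    if level <= 0:
        raise ValueError(f"background level must be positive, got {level}")
    return activity.with_values(activity.values / level, unit="TBR",
                                name=f"{activity.name}_TBR")
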