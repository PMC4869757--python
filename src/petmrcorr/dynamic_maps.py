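"""Wash-in summary maps from dynamic series, and two-point ADC.

The dynamic FMISO wash-in and the DCE enhancement series are both collapsed
to mean-value maps over an integration window (default 0-4 min post
injection) by rectangle integration: each frame contributes its value times
the length of its overlap with the window, and the sum is divided by the
window length.  Frames partially overlapping the window edges are pro-rated
by overlap length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids_io import DynamicSeries, ParametricMap

__all__ = [
    "IntegrationWindow",
    "CoverageError",
    "mean_activity_map",
    "signal_enhancement_series",
    "adc_from_two_b",
]


class CoverageError(ValueError):
    """The frames do not cover the integration window."""


@dataclass(frozen=True)
class IntegrationWindow:
    """Time window (seconds) for wash-in integration; default 0-240 s."""

    start: float = 0.0
    end: float = 240.0

    def __post_init__(self):
        if not (0.0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got ({self.start}, {self.end})")

    @property
    def length(self) -> float:
        return self.end - self.start


def mean_activity_map(series: DynamicSeries,
                      window: IntegrationWindow = IntegrationWindow()
                      ) -> ParametricMap:
    """Rectangle-integrated mean over the window; A-bar_FMISO for wash-in PET.

    Per voxel: sum over frames of value * (overlap of frame with window),
    divided by the window length.  The frames must cover the window up to a
    total gap smaller than one (the longest overlapping) frame duration.
    """
    starts, ends = series.frame_starts, series.frame_ends
    overlap = np.clip(np.minimum(ends, window.end)
                      - np.maximum(starts, window.start), 0.0, None)
    touching = overlap > 0
    if not touching.any():
        raise CoverageError(
            f"no frames overlap window ({window.start}, {window.end}) s"
        )
    covered = float(overlap.sum())  # frames are non-overlapping
    gap = window.length - covered
    tol = float(series.frame_durations[touching].max())
    if gap > tol + 1e-9:
        lo = max(window.start, float(ends[touching].max()))
        raise CoverageError(
            f"frames cover only {covered:.1f} s of the {window.length:.1f} s "
            f"window; missing about ({lo:.1f}, {window.end:.1f}) s"
        )
    values = np.tensordot(overlap, series.frames, axes=(0, 0)) / window.length
    return ParametricMap(series.grid, values, unit=series.unit,
                         name=f"mean[{window.start:g}-{window.end:g}s]")


def signal_enhancement_series(series: DynamicSeries,
                              n_baseline_frames: int) -> DynamicSeries:
    """Subtract the per-voxel mean of the first frames (pre-injection baseline)."""
    if not (1 <= n_baseline_frames < series.n_frames):
        raise ValueError(
            f"n_baseline_frames must be in [1, {series.n_frames - 1}], "
            f"got {n_baseline_frames}"
        )
    baseline = series.frames[:n_baseline_frames].mean(axis=0)
    return DynamicSeries(series.grid, series.frames - baseline,
                         series.frame_starts, series.frame_durations,
                         unit="signal-difference")


def adc_from_two_b(s_low: ParametricMap, s_high: ParametricMap,
                   b_values: tuple[float, float]) -> ParametricMap:
    """Monoexponential ADC from two diffusion weightings: ln(S1/S2)/(b2-b1).

    Voxels with non-positive signal or S(b_high) > S(b_low) (negative ADC)
    are flagged invalid rather than raising; equal signals give ADC 0.
    """
    b1, b2 = (float(b) for b in b_values)
    if not b2 > b1 >= 0:
        raise ValueError(f"need b2 > b1 >= 0, got ({b1}, {b2})")
    if s_low.grid != s_high.grid:
        raise ValueError("signal maps must share one grid")
    lo, hi = s_low.values, s_high.values
    ok = np.isfinite(lo) & np.isfinite(hi) & (lo > 0) & (hi > 0) & (hi <= lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.where(ok, np.log(np.where(ok, lo, 1.0) / np.where(ok, hi, 1.0))
                       / (b2 - b1), np.nan)
    return ParametricMap(s_low.grid, adc, unit="mm^2/s", name="ADC")
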