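"""Grid-aware image containers, NIfTI I/O, and grid-to-grid resampling.

All images live on axis-aligned regular 3D lattices.  Voxel indices are
0-based and world coordinates refer to voxel centers, so the world position
of voxel ``(i, j, k)`` is ``origin + index * spacing``.  Maps and masks are
only ever compared on identical grids; resampling is the explicit bridge
between grids.  Invalid voxels are carried as NaN in the value array.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "ParametricMap",
    "DynamicSeries",
    "ROIMask",
    "GridError",
    "FormatError",
    "MissingTimingError",
    "read_volume",
    "write_map",
    "write_series",
    "resample_to_grid",
]

_GRID_ATOL = 1e-6  # mm tolerance for grid equality


class GridError(ValueError):
    """Inconsistent grid geometry or grid mismatch between objects."""


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


class MissingTimingError(FormatError):
    """A 4D volume was read without frame-timing metadata."""


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3D lattice: voxels per axis, mm per voxel, world origin (mm).

    The origin is the world position of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise GridError("shape, spacing and origin must be length-3")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(s < 1 for s in self.shape):
            raise GridError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GridError(f"all spacings must be > 0 mm, got {self.spacing}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ImageGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=_GRID_ATOL, rtol=0.0)
            and np.allclose(self.origin, other.origin, atol=_GRID_ATOL, rtol=0.0)
        )

    def __hash__(self):
        return hash(self.shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine, axis-aligned by construction."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )


def _check_on_grid(values: np.ndarray, grid: ImageGrid, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise GridError(
            f"{what} shape {values.shape} does not match grid shape {grid.shape}"
        )
    return values


@dataclass
class ParametricMap:
    """One scalar per grid voxel with a physical-unit label.

    Non-finite values mark invalid voxels (e.g. outside the field of view
    after resampling, or non-physical results); every operation either
    propagates or reports them, never silently interpolates across them.
    """

    grid: ImageGrid
    values: np.ndarray
    unit: str
    name: str = ""

    def __post_init__(self):
        self.values = _check_on_grid(self.values, self.grid, "value array")
        if not self.unit:
            raise ValueError("unit label must be non-empty")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def with_values(self, values: np.ndarray, unit: str | None = None,
                    name: str | None = None) -> "ParametricMap":
        return ParametricMap(
            grid=self.grid,
            values=values,
            unit=self.unit if unit is None else unit,
            name=self.name if name is None else name,
        )


@dataclass
class DynamicSeries:
    """Time-stamped stack of frames on one grid.

    Frame timing (seconds) is explicit because NIfTI headers carry no
    reliable frame schedule; it travels in a JSON sidecar on disk.
    """

    grid: ImageGrid
    frames: np.ndarray  # (n_frames, *grid.shape)
    frame_starts: np.ndarray  # s
    frame_durations: np.ndarray  # s
    unit: str

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_starts = np.asarray(self.frame_starts, dtype=float)
        self.frame_durations = np.asarray(self.frame_durations, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[1:] != self.grid.shape:
            raise GridError(
                f"frames must have shape (n, *{self.grid.shape}), got {self.frames.shape}"
            )
        n = self.frames.shape[0]
        if self.frame_starts.shape != (n,) or self.frame_durations.shape != (n,):
            raise ValueError("frame_starts/frame_durations must match frame count")
        if np.any(self.frame_durations <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(self.frame_starts) < 0):
            raise ValueError("frames must be sorted by start time")
        ends = self.frame_starts[:-1] + self.frame_durations[:-1]
        if np.any(self.frame_starts[1:] < ends - 1e-9):
            raise ValueError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations

    def frame_map(self, i: int, name: str = "") -> ParametricMap:
        return ParametricMap(self.grid, self.frames[i], self.unit, name)


@dataclass
class ROIMask:
    """Boolean voxel membership on a grid with a role label (GTV, muscle, carotid)."""

    grid: ImageGrid
    membership: np.ndarray
    label: str

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != self.grid.shape:
            raise GridError(
                f"mask shape {self.membership.shape} != grid shape {self.grid.shape}"
            )
        if not self.membership.any():
            raise ValueError(f"ROI mask '{self.label}' has no member voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _grid_from_affine(affine: np.ndarray, shape: Sequence[int]) -> ImageGrid:
    lin = affine[:3, :3]
    spacing = np.sqrt((lin ** 2).sum(axis=0))
    if np.any(spacing <= 0):
        raise FormatError("degenerate affine: zero column norm")
    # axis-aligned positive orientation only: off-diagonal must vanish
    off = lin - np.diag(np.diag(lin))
    if np.max(np.abs(off)) > 1e-4 * spacing.max() or np.any(np.diag(lin) <= 0):
        raise FormatError(
            "oblique or flipped affine; only axis-aligned grids with positive "
            "orientation are supported"
        )
    return ImageGrid(tuple(int(s) for s in shape[:3]),
                     tuple(float(s) for s in spacing),
                     tuple(float(o) for o in affine[:3, 3]))


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".timing.json")


def read_volume(path, unit: str | None = None,
                timing: dict | None = None) -> ParametricMap | DynamicSeries:
    """Read a NIfTI volume: 3D -> ParametricMap, 4D -> DynamicSeries.

    4D timing (``frame_starts``/``frame_durations`` in seconds) comes from
    the ``timing`` dict or, failing that, a ``<name>.timing.json`` sidecar
    written by :func:`write_series`; without either the read fails.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = _grid_from_affine(np.asarray(img.affine), data.shape)
    sidecar: dict = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    if unit is None:
        unit = sidecar.get("unit", "arbitrary")
    name = sidecar.get("name", path.name.split(".")[0])
    if data.ndim == 3:
        return ParametricMap(grid, data, unit=unit, name=name)
    if data.ndim != 4:
        raise FormatError(f"expected 3D or 4D volume, got {data.ndim}D")
    meta = timing if timing is not None else sidecar
    if "frame_starts" not in meta or "frame_durations" not in meta:
        raise MissingTimingError(
            f"4D volume {path} needs frame_starts/frame_durations "
            "(timing dict or .timing.json sidecar)"
        )
    return DynamicSeries(
        grid=grid,
        frames=np.moveaxis(data, 3, 0),
        frame_starts=np.asarray(meta["frame_starts"], dtype=float),
        frame_durations=np.asarray(meta["frame_durations"], dtype=float),
        unit=unit,
    )


def write_map(pmap: ParametricMap, path) -> Path:
    """Write a ParametricMap as NIfTI plus a JSON sidecar with unit/name."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(pmap.values.astype(np.float64), pmap.grid.affine())
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"unit": pmap.unit, "name": pmap.name}, indent=1)
    )
    return path


def write_series(series: DynamicSeries, path) -> Path:
    """Write a DynamicSeries as 4D NIfTI plus a timing sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.moveaxis(series.frames, 0, 3).astype(np.float64)
    img = nib.Nifti1Image(data, series.grid.affine())
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({
        "unit": series.unit,
        "frame_starts": series.frame_starts.tolist(),
        "frame_durations": series.frame_durations.tolist(),
    }, indent=1))
    return path


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_grid(pmap: ParametricMap, target: ImageGrid,
                     order: int = 3) -> ParametricMap:
    """Interpolate a map onto ``target`` with B-splines of degree 0, 1 or 3.

    Values are interpolated at target voxel centers in the shared world
    frame.  Target voxels outside the source field of view (the convex hull
    of source voxel centers) are flagged invalid (NaN), as are voxels whose
    interpolation support touches an invalid source voxel.
    """
    if order not in (0, 1, 3):
        raise ValueError(f"spline order must be 0, 1 or 3, got {order}")
    if pmap.grid == target:
        out = pmap.values.copy()
        return ParametricMap(target, out, pmap.unit, pmap.name)

    src = pmap.values
    invalid_src = ~np.isfinite(src)

    # index coordinates of target voxel centers in the source lattice
    axes = [
        (target.origin[a] + target.spacing[a] * np.arange(target.shape[a])
         - pmap.grid.origin[a]) / pmap.grid.spacing[a]
        for a in range(3)
    ]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([ii, jj, kk])

    eps = 1e-9
    inside = np.ones(target.shape, dtype=bool)
    for a in range(3):
        inside &= (coords[a] >= -eps) & (coords[a] <= pmap.grid.shape[a] - 1 + eps)

    filled = np.where(invalid_src, 0.0, src)
    out = ndimage.map_coordinates(filled, coords, order=order, mode="mirror")

    if invalid_src.any():
        # conservative invalidity: dilate by the spline support half-width and
        # carry through linear interpolation so no value is synthesised from
        # an invalid neighbour
        halfwidth = {0: 0, 1: 1, 3: 2}[order]
        marker = invalid_src
        if halfwidth:
            marker = ndimage.binary_dilation(invalid_src, iterations=halfwidth)
        w = ndimage.map_coordinates(marker.astype(float), coords, order=1,
                                    mode="constant", cval=0.0)
        out[w > 1e-12] = np.nan

    out[~inside] = np.nan
    return ParametricMap(target, out, pmap.unit, pmap.name)
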