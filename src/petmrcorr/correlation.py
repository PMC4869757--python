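"""Voxel- and regional-level Spearman correlation analysis within the GTV.

Per patient, every available pair of functional maps is sampled on the
shared PET grid inside the gross tumor volume, either voxel by voxel or as
means over non-overlapping 3x3x4-voxel sub-regions, and summarized by the
tie-corrected Spearman rank correlation coefficient.  Patients whose GTV
yields fewer than ten sub-regions are excluded from the regional level (but
still contribute at the voxel level).  Cohort tables report per-pair
medians, ranges and patient counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grids_io import ImageGrid, ParametricMap, ROIMask

__all__ = [
    "SampleSet",
    "CorrelationResult",
    "RegionSpec",
    "UndefinedCorrelationError",
    "InsufficientSamplesError",
    "MIN_REGIONS",
    "spearman",
    "voxel_samples",
    "partition_regions",
    "block_extent_mm",
    "regional_samples",
    "patient_correlation_matrix",
    "cohort_summary",
]

#: minimum number of sub-regions for a patient to enter regional analysis
MIN_REGIONS = 10


class UndefinedCorrelationError(ValueError):
    """Correlation of a constant vector is undefined."""


class InsufficientSamplesError(ValueError):
    """Fewer than two paired samples survive filtering."""


@dataclass(frozen=True)
class RegionSpec:
    """Sub-region tiling: block shape in voxels and the partial-block rule.

    Blocks tile the GTV bounding box from its minimal corner; a block is
    kept iff at least ``min_gtv_fraction`` of its voxels lie in the GTV, and
    a kept region contains only its GTV voxels.
    """

    block_shape: tuple[int, int, int] = (3, 3, 4)
    min_gtv_fraction: float = 0.5

    def __post_init__(self):
        if any(int(b) < 1 for b in self.block_shape):
            raise ValueError(f"block dimensions must be >= 1, got {self.block_shape}")
        if not (0.0 < self.min_gtv_fraction <= 1.0):
            raise ValueError(
                f"min_gtv_fraction must be in (0, 1], got {self.min_gtv_fraction}"
            )


def block_extent_mm(spec: RegionSpec, grid: ImageGrid) -> tuple[float, float, float]:
    """Physical size of one sub-region block on the given grid (mm)."""
    return tuple(b * s for b, s in zip(spec.block_shape, grid.spacing))


@dataclass
class SampleSet:
    """Paired samples of two maps inside the GTV at one analysis level."""

    labels: tuple[str, str]
    x: np.ndarray
    y: np.ndarray
    level: str  # "voxel" | "regional"
    patient_id: str = ""
    n_dropped: int = 0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("paired vectors must be 1D of equal length")
        if self.n < 2:
            raise InsufficientSamplesError(
                f"{self.labels} at {self.level} level: only {self.n} samples"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("sample vectors must be finite")

    @property
    def n(self) -> int:
        return int(self.x.size)


def spearman(x, y) -> float:
    """Tie-corrected Spearman coefficient: Pearson correlation of mean ranks.

    Ties receive their average rank.  A constant vector has no defined rank
    correlation and raises rather than silently contributing a zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be 1D vectors of equal length >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    return float((dx @ dy) / np.sqrt((dx @ dx) * (dy @ dy)))


def voxel_samples(map_a: ParametricMap, map_b: ParametricMap,
                  gtv: ROIMask) -> SampleSet:
    """Paired voxel values of two maps at GTV voxels where both are valid."""
    if not (map_a.grid == map_b.grid == gtv.grid):
        raise ValueError("maps and GTV mask must share one grid; resample upstream")
    keep = gtv.membership & map_a.valid & map_b.valid
    n_dropped = int(gtv.membership.sum() - keep.sum())
    return SampleSet(labels=(map_a.name, map_b.name),
                     x=map_a.values[keep], y=map_b.values[keep],
                     level="voxel", n_dropped=n_dropped)


def partition_regions(gtv: ROIMask,
                      spec: RegionSpec = RegionSpec()) -> list[np.ndarray]:
    """Tile the GTV bounding box into non-overlapping blocks of GTV voxels.

    Blocks of ``spec.block_shape`` are anchored at the bounding box's
    minimal corner; a block is kept iff its GTV occupancy reaches
    ``spec.min_gtv_fraction``.  Returns one (n, 3) voxel-index array per
    kept block (GTV voxels only); an empty list means the caller should
    apply the exclusion rule.
    """
    idx = np.argwhere(gtv.membership)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)  # inclusive
    bs = np.asarray(spec.block_shape, dtype=int)
    block_size = int(np.prod(bs))
    n_blocks = np.ceil((hi - lo + 1) / bs).astype(int)
    regions: list[np.ndarray] = []
    for bi in range(n_blocks[0]):
        for bj in range(n_blocks[1]):
            for bk in range(n_blocks[2]):
                start = lo + np.array([bi, bj, bk]) * bs
                stop = np.minimum(start + bs, gtv.grid.shape)
                sub = gtv.membership[start[0]:stop[0], start[1]:stop[1],
                                     start[2]:stop[2]]
                n_in = int(sub.sum())
                if n_in / block_size >= spec.min_gtv_fraction:
                    vox = np.argwhere(sub) + start
                    regions.append(vox)
    return regions


def regional_samples(map_a: ParametricMap, map_b: ParametricMap,
                     regions: list[np.ndarray]) -> SampleSet:
    """One paired sample per region: the mean of each map over its GTV voxels.

    Invalid voxels are excluded from the means; regions with no valid voxel
    in either map are dropped and counted in ``n_dropped``.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if map_a.grid != map_b.grid:
        raise ValueError("maps must share one grid")
    xs, ys = [], []
    n_dropped = 0
    for region in regions:
        region = np.asarray(region, dtype=int).reshape(-1, 3)
        va = map_a.values[region[:, 0], region[:, 1], region[:, 2]]
        vb = map_b.values[region[:, 0], region[:, 1], region[:, 2]]
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        if va.size == 0 or vb.size == 0:
            n_dropped += 1
            continue
        xs.append(va.mean())
        ys.append(vb.mean())
    return SampleSet(labels=(map_a.name, map_b.name), x=np.array(xs),
                     y=np.array(ys), level="regional", n_dropped=n_dropped)


@dataclass
class CorrelationResult:
    """Per-patient pairwise Spearman coefficients at one analysis level."""

    patient_id: str
    level: str
    labels: list[str]
    pairs: dict[tuple[str, str], tuple[float, int]] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str = ""
    n_regions: int | None = None

    def r(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.pairs else (b, a)
        return self.pairs[key][0]

    def matrix(self) -> pd.DataFrame:
        """Symmetric matrix of coefficients (unit diagonal, NaN where absent)."""
        m = pd.DataFrame(np.eye(len(self.labels)), index=self.labels,
                         columns=self.labels)
        m[:] = np.where(np.eye(len(self.labels)), 1.0, np.nan)
        for (a, b), (r, _n) in self.pairs.items():
            m.loc[a, b] = r
            m.loc[b, a] = r
        return m

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient": self.patient_id, "pair": f"{a}/{b}", "level": self.level,
             "r": r, "n": n, "excluded": self.excluded}
            for (a, b), (r, n) in sorted(self.pairs.items())
        ]
        if not rows and self.excluded:
            rows = [{"patient": self.patient_id, "pair": "", "level": self.level,
                     "r": np.nan, "n": 0, "excluded": True}]
        return pd.DataFrame(rows)


def patient_correlation_matrix(dataset: dict[str, ParametricMap], gtv: ROIMask,
                               level: str = "voxel",
                               spec: RegionSpec = RegionSpec(),
                               patient_id: str = "",
                               regional_values: dict[str, np.ndarray] | None = None,
                               ) -> CorrelationResult:
    """All pairwise Spearman coefficients among a patient's available maps.

    Pairs involving a map the patient lacks are simply absent (the cohort
    has modality availability gaps); no imputation.  At the regional level
    the <``MIN_REGIONS``-sub-regions exclusion rule applies and, when
    ``regional_values`` supplies per-region values for a label (e.g. from
    regional compartmental fits), those replace the block means for it.
    """
    if level not in ("voxel", "regional"):
        raise ValueError(f"level must be 'voxel' or 'regional', got {level!r}")
    labels = [k for k, v in dataset.items() if v is not None]
    if len(labels) < 2:
        raise ValueError("need at least two maps for pairwise correlations")
    result = CorrelationResult(patient_id=patient_id, level=level, labels=labels)

    regions: list[np.ndarray] = []
    if level == "regional":
        regions = partition_regions(gtv, spec)
        result.n_regions = len(regions)
        if len(regions) < MIN_REGIONS:
            result.excluded = True
            result.exclusion_reason = (
                f"only {len(regions)} sub-regions (< {MIN_REGIONS})"
            )
            return result

    def region_means(pmap: ParametricMap, label: str) -> np.ndarray:
        if regional_values is not None and label in regional_values:
            return np.asarray(regional_values[label], dtype=float)
        vals = []
        for region in regions:
            v = pmap.values[region[:, 0], region[:, 1], region[:, 2]]
            v = v[np.isfinite(v)]
            vals.append(v.mean() if v.size else np.nan)
        return np.array(vals)

    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if level == "voxel":
                try:
                    ss = voxel_samples(dataset[a], dataset[b], gtv)
                except InsufficientSamplesError:
                    continue
                result.pairs[(a, b)] = (spearman(ss.x, ss.y), ss.n)
            else:
                xa = region_means(dataset[a], a)
                xb = region_means(dataset[b], b)
                ok = np.isfinite(xa) & np.isfinite(xb)
                if ok.sum() < 2:
                    continue
                result.pairs[(a, b)] = (spearman(xa[ok], xb[ok]), int(ok.sum()))
    return result


def cohort_summary(results: list[CorrelationResult]) -> pd.DataFrame:
    """Per-pair cohort table: median r, (min, max) range and patient count.

    Excluded results contribute nothing at their level; pairs with zero
    contributing patients are absent from the table rather than zero.
    """
    buckets: dict[tuple[str, str, str], list[float]] = {}
    for res in results:
        if res.excluded:
            continue
        for (a, b), (r, _n) in res.pairs.items():
            key = (f"{a}/{b}", a, b) if a <= b else (f"{b}/{a}", b, a)
            buckets.setdefault((key[0], res.level), []).append(r)
    rows = []
    for (pair, level), rs in sorted(buckets.items()):
        rows.append({
            "pair": pair, "level": level, "median_r": float(np.median(rs)),
            "min_r": float(np.min(rs)), "max_r": float(np.max(rs)),
            "n_patients": len(rs),
        })
    return pd.DataFrame(rows)
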