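"""Axis-aligned 3D dose grids: resampling, subtraction, masked statistics,
and DVH extraction.

Frames are voxel-center based: world position of voxel (i, j, k) is
``origin + index * spacing`` (mm).  No direction-cosine rotations.  Voxels
that fall outside a source grid during resampling are marked missing (NaN)
and propagate through arithmetic; masked statistics exclude them and report
the excluded fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dvh import CumulativeDVH

__all__ = [
    "Frame",
    "DoseGrid",
    "StructureMask",
    "resample_to_frame",
    "subtract_grids",
    "dvh_from_grid",
    "masked_difference_stats",
    "save_grid",
    "load_grid",
]

_FRAME_ATOL = 1e-9


@dataclass(frozen=True)
class Frame:
    """Geometry of an axis-aligned grid: origin/spacing in mm, voxel counts."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(int(n) != n or n < 1 for n in self.shape):
            raise ValueError("shape must be positive integers")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "spacing", tuple(float(x) for x in self.spacing))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def equals(self, other: "Frame") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=_FRAME_ATOL)
            and np.allclose(self.spacing, other.spacing, atol=_FRAME_ATOL)
        )


def _check_values(frame: Frame, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != frame.shape:
        raise ValueError(f"values shape {values.shape} does not match frame shape {frame.shape}")
    return values


@dataclass(frozen=True)
class DoseGrid:
    """3D dose array (Gy) on a frame; NaN marks missing voxels."""

    frame: Frame
    values: np.ndarray

    def __post_init__(self) -> None:
        # signed difference maps are also DoseGrids, so negatives are legal here;
        # dvh_from_grid rejects them where a physical dose is required
        vals = _check_values(self.frame, self.values).astype(float)
        object.__setattr__(self, "values", vals)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass(frozen=True)
class StructureMask:
    """Binary mask on the same frame as its paired dose grid."""

    frame: Frame
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = _check_values(self.frame, self.values)
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary (0/1)")
        object.__setattr__(self, "values", vals.astype(bool))

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.frame.voxel_volume_cm3


def _require_same_frame(a_frame: Frame, b_frame: Frame, what: str) -> None:
    if not a_frame.equals(b_frame):
        raise ValueError(
            f"{what} requires identical frames; got {a_frame} vs {b_frame} "
            "(resample first)"
        )


def resample_to_frame(grid: DoseGrid, target: Frame) -> DoseGrid:
    """Trilinear resampling of a dose grid onto a target frame.

    Target voxel centers outside the source support become NaN (missing),
    never zero-filled.  Disjoint extents are rejected.
    """
    lo_s, hi_s = grid.frame.bounds()
    lo_t, hi_t = target.bounds()
    if np.any(hi_t < lo_s) or np.any(lo_t > hi_s):
        raise ValueError("target frame extent is disjoint from the source grid")
    if grid.frame.equals(target):
        return DoseGrid(target, grid.values.copy())
    # fractional source indices of target voxel centers
    idx = [
        (target.axis_coords(ax) - grid.frame.origin[ax]) / grid.frame.spacing[ax]
        for ax in range(3)
    ]
    mesh = np.meshgrid(*idx, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh])
    out = ndimage.map_coordinates(
        grid.values, coords, order=1, mode="constant", cval=np.nan
    ).reshape(target.shape)
    # map_coordinates keeps exact-boundary points; anything outside [0, n-1] is missing
    for ax in range(3):
        bad = (idx[ax] < -1e-9) | (idx[ax] > grid.frame.shape[ax] - 1 + 1e-9)
        if bad.any():
            sl = [slice(None)] * 3
            sl[ax] = bad
            out[tuple(sl)] = np.nan
    return DoseGrid(target, out)


def subtract_grids(a: DoseGrid, b: DoseGrid, resample: bool = False) -> DoseGrid:
    """Voxel-wise signed difference a - b; missing voxels propagate.

    With ``resample=True``, b is first resampled onto a's frame.
    """
    if not a.frame.equals(b.frame):
        if not resample:
            raise ValueError("frames differ; pass resample=True or resample explicitly")
        b = resample_to_frame(b, a.frame)
    return DoseGrid(a.frame, a.values - b.values)


def dvh_from_grid(grid: DoseGrid, mask: StructureMask, bin_width: float = 0.1) -> CumulativeDVH:
    """Cumulative DVH of the masked voxels.

    The curve is tabulated at bin edges 0, w, 2w, ...; the fraction at each
    edge is the exact count of masked voxels with dose >= edge, so queries at
    the edges reproduce brute-force voxel counting.
    """
    _require_same_frame(grid.frame, mask.frame, "dvh_from_grid")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    doses = grid.values[mask.values]
    doses = doses[~np.isnan(doses)]
    if doses.size == 0:
        raise ValueError("mask selects no (non-missing) voxels")
    if np.any(doses < 0):
        raise ValueError("dose grid has negative values; DVH is undefined")
    dmax = float(doses.max())
    n_edges = int(np.floor(dmax / bin_width + 1e-12)) + 2
    edges = np.arange(n_edges) * bin_width
    # fraction of voxels with dose >= edge
    frac = 1.0 - np.searchsorted(np.sort(doses), edges, side="left") / doses.size
    return CumulativeDVH(
        structure_name="", total_volume=doses.size * grid.frame.voxel_volume_cm3,
        dose_gy=edges, volume_fraction=frac,
    )


def masked_difference_stats(
    diff: DoseGrid, mask: StructureMask, thresholds: tuple[float, ...] = (0.5, 1.0, 2.0)
) -> dict[str, float]:
    """Summary of a signed difference map inside a structure.

    Missing voxels are excluded; their fraction of the mask is reported as
    ``missing_fraction``.  For each threshold t the fractions of voxels with
    difference > +t, < -t and |difference| > t are reported.
    """
    _require_same_frame(diff.frame, mask.frame, "masked_difference_stats")
    if mask.voxel_count == 0:
        raise ValueError("empty structure mask")
    vals = diff.values[mask.values]
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("all masked voxels are missing")
    v = vals[ok]
    stats: dict[str, float] = {
        "mean": float(v.mean()),
        "min": float(v.min()),
        "max": float(v.max()),
        "missing_fraction": float(1.0 - ok.mean()),
        "n_voxels": int(v.size),
    }
    for t in thresholds:
        stats[f"fraction_above_+{t:g}"] = float((v > t).mean())
        stats[f"fraction_below_-{t:g}"] = float((v < -t).mean())
        stats[f"fraction_abs_above_{t:g}"] = float((np.abs(v) > t).mean())
    return stats


def save_grid(path, grid: DoseGrid | StructureMask) -> None:
    """Write a grid to a self-describing single-file container (bit-exact)."""
    np.savez(
        path,
        origin=np.asarray(grid.frame.origin),
        spacing=np.asarray(grid.frame.spacing),
        values=grid.values,
        is_mask=np.asarray(isinstance(grid, StructureMask)),
    )


def load_grid(path) -> DoseGrid | StructureMask:
    with np.load(path) as data:
        frame = Frame(tuple(data["origin"]), tuple(data["spacing"]), data["values"].shape)
        cls = StructureMask if bool(data["is_mask"]) else DoseGrid
        return cls(frame, data["values"])
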