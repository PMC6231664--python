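"""Dose-volume histogram data model and query metrics.

Cumulative DVHs are stored as piecewise-linear curves of the fraction of a
structure's volume receiving at least a given dose.  Differential DVHs carry
point masses (fractional sub-volumes) at representative doses and are the
input to the radiobiological power-mean machinery.

Conventions
-----------
* Internal volumes are relative fractions in [0, 1]; the absolute structure
  volume is retained in ``total_volume`` (cm^3).
* All dose/volume queries interpolate linearly on the cumulative curve;
  ties on flat segments resolve to the lowest dose, except the full-volume
  query which follows the minimum-dose convention (highest dose still
  covering the whole structure).
* D_min is the highest dose received by the entire structure, D_max the
  lowest dose at which the covered fraction reaches zero (the end of the
  curve when it never does).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "CumulativeDVH",
    "DifferentialDVH",
    "PlanDVHSet",
    "DEFAULT_BIN_WIDTH",
    "cumulative_to_differential",
    "differential_to_cumulative",
    "dose_at_volume",
    "volume_at_dose",
    "v_x_percent",
    "dvh_summary",
]

#: Default differential bin width (Gy); fine enough that EUD is stable to <0.1%.
DEFAULT_BIN_WIDTH = 0.1

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: fraction of volume receiving >= dose, per dose point."""

    structure_name: str
    total_volume: float  # cm^3
    dose_gy: np.ndarray
    volume_fraction: np.ndarray
    air_excluded: bool | None = None  # optional variant flag; None = unspecified

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose_gy, dtype=float)
        frac = np.asarray(self.volume_fraction, dtype=float)
        object.__setattr__(self, "dose_gy", dose)
        object.__setattr__(self, "volume_fraction", frac)
        if dose.ndim != 1 or frac.ndim != 1 or dose.size != frac.size:
            raise ValueError("dose_gy and volume_fraction must be 1-D arrays of equal length")
        if dose.size < 2:
            raise ValueError("cumulative DVH needs at least two dose points")
        if not np.isfinite(dose).all() or not np.isfinite(frac).all():
            raise ValueError(f"non-finite values in DVH for {self.structure_name!r}")
        if self.total_volume <= 0:
            raise ValueError(f"total_volume must be > 0, got {self.total_volume}")
        if dose[0] != 0.0:
            raise ValueError("dose points must start at 0 Gy")
        bad = np.nonzero(np.diff(dose) <= 0)[0]
        if bad.size:
            raise ValueError(f"dose points not strictly increasing at index {bad[0] + 1}")
        if abs(frac[0] - 1.0) > _FRACTION_TOL:
            raise ValueError(f"volume fraction at 0 Gy must be 1.0, got {frac[0]}")
        if frac[-1] < -_FRACTION_TOL:
            raise ValueError("volume fractions must be >= 0")
        rising = np.nonzero(np.diff(frac) > _FRACTION_TOL)[0]
        if rising.size:
            raise ValueError(
                f"cumulative volume fraction increases at index {rising[0] + 1} "
                f"(structure {self.structure_name!r})"
            )

    @property
    def max_dose_point(self) -> float:
        return float(self.dose_gy[-1])


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential DVH: fractional sub-volumes v_i at doses D_i, sum(v_i) == 1."""

    structure_name: str
    bin_centers: np.ndarray
    fractional_volumes: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        vols = np.asarray(self.fractional_volumes, dtype=float)
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "fractional_volumes", vols)
        if centers.ndim != 1 or vols.ndim != 1 or centers.size != vols.size:
            raise ValueError("bin_centers and fractional_volumes must be 1-D, equal length")
        if centers.size == 0:
            raise ValueError("differential DVH must have at least one bin")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(vols < 0):
            raise ValueError("fractional volumes must be non-negative")
        total = float(vols.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractional volumes must sum to 1, got {total}")

    def normalized(self) -> "DifferentialDVH":
        """Return a copy with volumes renormalized to sum exactly to 1."""
        vols = self.fractional_volumes / self.fractional_volumes.sum()
        return replace(self, fractional_volumes=vols)


@dataclass(frozen=True)
class PlanDVHSet:
    """All structure DVHs of one patient under one plan variant."""

    patient_id: str
    algorithm: str
    grid_mm: float
    dvhs: Mapping[str, CumulativeDVH] = field(default_factory=dict)
    prescription_dose: float = 78.0
    n_fractions: int = 39

    def __post_init__(self) -> None:
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def variant(self) -> tuple[str, float]:
        return (self.algorithm, self.grid_mm)

    @property
    def variant_label(self) -> str:
        g = self.grid_mm
        gtxt = str(int(g)) if float(g).is_integer() else str(g)
        return f"{self.algorithm}{gtxt}"

    def validate_variant(self, allowed: set[tuple[str, float]]) -> None:
        if self.variant not in allowed:
            raise ValueError(
                f"variant {self.variant} not in the allowed set {sorted(allowed)}"
            )


def _interp_fraction(cdvh: CumulativeDVH, doses: np.ndarray) -> np.ndarray:
    """Fraction of volume receiving >= dose; 0 above the curve support."""
    out = np.interp(doses, cdvh.dose_gy, cdvh.volume_fraction)
    return np.where(np.asarray(doses) > cdvh.dose_gy[-1], 0.0, out)


def cumulative_to_differential(
    cdvh: CumulativeDVH, bin_width: float | None = DEFAULT_BIN_WIDTH
) -> DifferentialDVH:
    """Convert a cumulative DVH into a differential one.

    With a finite ``bin_width`` the dose axis is cut into uniform bins from
    0 Gy to the top of the curve support; each bin receives the drop of the
    cumulative fraction across it and is represented at its arithmetic
    midpoint.  Any residual fraction still covered at the top edge is
    assigned to the terminal bin, so the volumes always sum to 1.

    ``bin_width=None`` requests the exact decomposition of the piecewise
    linear curve: one point mass per curve segment at the segment's dose
    midpoint (plus a terminal mass at the last dose point when the curve
    does not reach zero).  This path has no discretization error.
    """
    if bin_width is None:
        d, f = cdvh.dose_gy, cdvh.volume_fraction
        drops = f[:-1] - f[1:]
        centers = 0.5 * (d[:-1] + d[1:])
        masses = list(drops)
        cpts = list(centers)
        if f[-1] > _FRACTION_TOL:
            cpts.append(float(d[-1]))
            masses.append(float(f[-1]))
        centers_arr = np.asarray(cpts)
        masses_arr = np.asarray(masses)
        keep = masses_arr > 0
        if not keep.any():
            raise ValueError("cumulative DVH carries no volume drop")
        return DifferentialDVH(
            cdvh.structure_name, centers_arr[keep], masses_arr[keep]
        ).normalized()

    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = max(1, int(np.ceil(cdvh.max_dose_point / bin_width - 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    frac_at_edges = _interp_fraction(cdvh, np.minimum(edges, cdvh.max_dose_point))
    vols = frac_at_edges[:-1] - frac_at_edges[1:]
    # residual volume still covered above the top edge goes to the last bin
    vols[-1] += frac_at_edges[-1]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DifferentialDVH(cdvh.structure_name, centers, vols).normalized()


def differential_to_cumulative(
    ddvh: DifferentialDVH, total_volume: float = 1.0, step_width: float = 1e-6
) -> CumulativeDVH:
    """Rebuild a cumulative curve from differential bin masses.

    Each mass v_i is spread uniformly over its bin, with bin edges at the
    midpoints between adjacent centers (outer edges extend by half the
    adjacent gap, clipped at 0 Gy); the cumulative fraction at edge e_k is
    the sum of v_i over bins at or above e_k, and interpolation between
    edges is linear.  A single-bin input degenerates to a (near-)step at
    its center, rendered over ``step_width``.
    """
    ddvh = ddvh.normalized()
    centers = ddvh.bin_centers.astype(float)
    vols = ddvh.fractional_volumes
    if centers.size == 1:
        c = float(centers[0])
        half = step_width / 2.0
        edges = np.array([max(c - half, c * 0.5), c + half])
    else:
        mids = 0.5 * (centers[:-1] + centers[1:])
        first = max(0.0, centers[0] - (centers[1] - centers[0]) / 2.0)
        last = centers[-1] + (centers[-1] - centers[-2]) / 2.0
        edges = np.concatenate([[first], mids, [last]])
    suffix = np.cumsum(vols[::-1])[::-1]  # fraction receiving >= edges[i]
    fracs = np.concatenate([suffix, [0.0]])
    if edges[0] > 0:
        edges = np.concatenate([[0.0], edges])
        fracs = np.concatenate([[1.0], fracs])
    return CumulativeDVH(ddvh.structure_name, total_volume, edges, fracs)


def dose_at_volume(cdvh: CumulativeDVH, fraction: float) -> float:
    """Smallest dose at which the covered fraction equals ``fraction`` (D_x).

    ``fraction=1.0`` returns the minimum structure dose (the highest dose
    still covering the full volume); any other value interpolates linearly
    and resolves flat-segment ties to the lowest dose.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    d, f = cdvh.dose_gy, cdvh.volume_fraction
    if fraction >= 1.0 - _FRACTION_TOL:
        covered = np.nonzero(f >= 1.0 - _FRACTION_TOL)[0]
        return float(d[covered[-1]])
    if f[-1] > fraction + _FRACTION_TOL:
        # requested fraction lies beyond the exported curve support
        return float(d[-1])
    # first index where the curve has dropped to or below the requested fraction
    idx = int(np.argmax(f <= fraction + _FRACTION_TOL))
    if f[idx] >= fraction - _FRACTION_TOL:  # exact hit (within tol), maybe flat
        return float(d[idx])
    lo = idx - 1
    # linear interpolation between the bracketing points
    f0, f1 = f[lo], f[idx]
    d0, d1 = d[lo], d[idx]
    return float(d0 + (f0 - fraction) * (d1 - d0) / (f0 - f1))


def volume_at_dose(cdvh: CumulativeDVH, dose: float) -> float:
    """Fraction of the structure receiving at least ``dose`` (V_d)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return float(_interp_fraction(cdvh, np.asarray(dose, dtype=float)))


def v_x_percent(cdvh: CumulativeDVH, x: float, prescription: float) -> float:
    """V_x%: percent of the volume receiving >= x% of the prescription dose."""
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    return 100.0 * volume_at_dose(cdvh, x / 100.0 * prescription)


def dvh_summary(cdvh: CumulativeDVH) -> dict[str, float]:
    """Min/max/mean/median dose of a cumulative DVH.

    The mean is the exact first moment of the piecewise-linear curve
    (equivalently the limit of sum(v_i * D_i) at vanishing bin width);
    residual volume above the last dose point is counted at that dose.
    """
    d, f = cdvh.dose_gy, cdvh.volume_fraction
    covered = np.nonzero(f >= 1.0 - _FRACTION_TOL)[0]
    dmin = float(d[covered[-1]]) if covered.size else float(d[0])
    zero = np.nonzero(f <= _FRACTION_TOL)[0]
    dmax = float(d[zero[0]]) if zero.size else float(d[-1])
    drops = f[:-1] - f[1:]
    mids = 0.5 * (d[:-1] + d[1:])
    mean = float(np.sum(drops * mids) + f[-1] * d[-1])
    return {
        "min": dmin,
        "max": dmax,
        "mean": mean,
        "median": dose_at_volume(cdvh, 0.5),
    }
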