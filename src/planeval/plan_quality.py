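"""Target-dose indices and reference-relative deviation.

Homogeneity index HI = (D2 - D98) / D50; conformity index CI = V_RI / TV;
conformation number CN = (TV_RI / TV) * (TV_RI / V_RI), where V_RI is the
reference-isodose volume on the body, TV the target volume and TV_RI the
part of the target covered by the reference isodose.  The reference isodose
defaults to 95% of the prescription dose.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dvh import CumulativeDVH, PlanDVHSet, dose_at_volume, volume_at_dose

__all__ = [
    "TargetIndexInputs",
    "homogeneity_index",
    "conformity_index",
    "conformation_number",
    "percent_deviation",
    "target_index_inputs_from_dvhs",
    "target_indices",
]

DEFAULT_REFERENCE_ISODOSE_PCT = 95.0


@dataclass(frozen=True)
class TargetIndexInputs:
    """Scalar inputs for HI/CI/CN (doses in Gy, volumes in cm^3)."""

    d2: float
    d98: float
    d50: float
    v_ri: float
    tv: float
    tv_ri: float

    def __post_init__(self) -> None:
        if self.tv <= 0:
            raise ValueError("target volume must be > 0")
        if not (0.0 <= self.tv_ri <= min(self.tv, self.v_ri) + 1e-9):
            raise ValueError(
                f"tv_ri={self.tv_ri} must lie in [0, min(tv={self.tv}, v_ri={self.v_ri})]"
            )


def homogeneity_index(d2: float, d98: float, d50: float) -> float:
    """(D2 - D98) / D50; lower is more homogeneous."""
    if d50 <= 0:
        raise ValueError(f"D50 must be > 0, got {d50}")
    if d2 < d98:
        raise ValueError(f"D2 ({d2}) must be >= D98 ({d98})")
    return (d2 - d98) / d50


def conformity_index(v_ri: float, tv: float) -> float:
    """Reference-isodose volume over target volume; ideal value 1."""
    if tv <= 0:
        raise ValueError(f"target volume must be > 0, got {tv}")
    if v_ri < 0:
        raise ValueError("reference isodose volume must be >= 0")
    return v_ri / tv


def conformation_number(tv_ri: float, tv: float, v_ri: float) -> float:
    """Coverage term times spill term; in [0, 1], 1 iff tv_ri = tv = v_ri."""
    if tv <= 0:
        raise ValueError("target volume must be > 0")
    if v_ri <= 0:
        raise ValueError("conformation number is undefined for zero reference-isodose volume")
    if not (0.0 <= tv_ri <= min(tv, v_ri) + 1e-9):
        raise ValueError(f"tv_ri={tv_ri} outside [0, min(tv, v_ri)]")
    return (tv_ri / tv) * (tv_ri / v_ri)


def percent_deviation(ref: float, eval_: float) -> float:
    """|ref - eval| / |ref| * 100."""
    if ref == 0:
        raise ValueError("deviation is undefined for a zero reference value")
    return abs(ref - eval_) / abs(ref) * 100.0


def target_index_inputs_from_dvhs(
    target: CumulativeDVH,
    ri_dose: float,
    body: CumulativeDVH | None = None,
    v_ri: float | None = None,
) -> TargetIndexInputs:
    """Assemble HI/CI/CN inputs from the target DVH plus a body DVH or a
    directly supplied reference-isodose volume (cm^3)."""
    if (body is None) == (v_ri is None):
        raise ValueError("provide exactly one of body DVH or v_ri")
    if v_ri is None:
        v_ri = volume_at_dose(body, ri_dose) * body.total_volume
    tv = target.total_volume
    tv_ri = volume_at_dose(target, ri_dose) * tv
    return TargetIndexInputs(
        d2=dose_at_volume(target, 0.02),
        d98=dose_at_volume(target, 0.98),
        d50=dose_at_volume(target, 0.50),
        v_ri=v_ri,
        tv=tv,
        tv_ri=min(tv_ri, v_ri),
    )


def target_indices(inputs: TargetIndexInputs) -> dict[str, float]:
    """HI, CI and CN from one set of scalar inputs."""
    return {
        "HI": homogeneity_index(inputs.d2, inputs.d98, inputs.d50),
        "CI": conformity_index(inputs.v_ri, inputs.tv),
        "CN": conformation_number(inputs.tv_ri, inputs.tv, inputs.v_ri),
    }


def reference_isodose_dose(plan: PlanDVHSet, ri_pct: float = DEFAULT_REFERENCE_ISODOSE_PCT) -> float:
    """Absolute dose (Gy) of the reference isodose level for a plan."""
    return ri_pct / 100.0 * plan.prescription_dose
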