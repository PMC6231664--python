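"""Equivalent uniform dose and logistic dose-response scores.

EUD is the generalized power mean (sum_i v_i D_i^a)^(1/a) over a
differential DVH.  Tumor control and normal-tissue complication
probabilities are logistic sigmoids in EUD with half-point TCD50 / TD50 and
slope parameter gamma50:

    P = 1 / (1 + (D50 / EUD)^(4 * gamma50))

An optional EQD2 fractionation correction (linear-quadratic, tissue alpha/beta)
maps every bin dose to its 2 Gy/fraction equivalent before the power mean.
Whether the published scores were computed on physical or EQD2 doses is not
settled; both paths are exposed and the correction is on by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .dvh import CumulativeDVH, DifferentialDVH, PlanDVHSet, cumulative_to_differential

__all__ = [
    "RadiobioParams",
    "ParamRegistry",
    "default_registry",
    "eqd2_transform",
    "eud",
    "ntcp",
    "tcp",
    "evaluate_plan_radiobiology",
]

_ZERO_MASS_TOL = 1e-9


@dataclass(frozen=True)
class RadiobioParams:
    """One organ's dose-response parameter row.

    ``d50_ref`` is TD50 for normal tissue and TCD50 for tumor.
    """

    organ: str
    a: float
    gamma50: float
    d50_ref: float
    alpha_beta: float
    kind: Literal["tumor", "normal"]

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("a = 0 (geometric-mean limit) is not supported")
        if self.gamma50 <= 0:
            raise ValueError("gamma50 must be > 0")
        if self.d50_ref <= 0:
            raise ValueError("d50_ref must be > 0")
        if self.alpha_beta <= 0:
            raise ValueError("alpha/beta must be > 0")
        if self.kind not in ("tumor", "normal"):
            raise ValueError(f"kind must be 'tumor' or 'normal', got {self.kind!r}")


class ParamRegistry:
    """Organ -> dose-response parameters, round-trippable to plain CSV."""

    def __init__(self, params: Iterable[RadiobioParams]):
        self._params: dict[str, RadiobioParams] = {}
        for p in params:
            if p.organ in self._params:
                raise ValueError(f"duplicate organ {p.organ!r} in registry")
            self._params[p.organ] = p

    def __getitem__(self, organ: str) -> RadiobioParams:
        return self._params[organ]

    def __contains__(self, organ: str) -> bool:
        return organ in self._params

    def __iter__(self):
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    @property
    def organs(self) -> list[str]:
        return list(self._params)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["organ", "a", "gamma50", "d50_ref", "alpha_beta", "kind"])
            for p in self:
                w.writerow([p.organ, repr(p.a), repr(p.gamma50), repr(p.d50_ref),
                            repr(p.alpha_beta), p.kind])

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParamRegistry":
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append(RadiobioParams(
                    organ=rec["organ"], a=float(rec["a"]), gamma50=float(rec["gamma50"]),
                    d50_ref=float(rec["d50_ref"]), alpha_beta=float(rec["alpha_beta"]),
                    kind=rec["kind"],  # type: ignore[arg-type]
                ))
        return cls(rows)


def default_registry() -> ParamRegistry:
    """Built-in prostate-plan parameter set (literature values)."""
    return ParamRegistry([
        RadiobioParams("PTV", a=-13.0, gamma50=2.2, d50_ref=67.5, alpha_beta=1.5, kind="tumor"),
        RadiobioParams("Rectum", a=8.33, gamma50=2.66, d50_ref=80.0, alpha_beta=5.4, kind="normal"),
        RadiobioParams("Bladder", a=2.0, gamma50=3.63, d50_ref=80.0, alpha_beta=7.5, kind="normal"),
        RadiobioParams("FemoralHead_L", a=13.0, gamma50=2.7, d50_ref=65.0, alpha_beta=3.0, kind="normal"),
        RadiobioParams("FemoralHead_R", a=13.0, gamma50=2.7, d50_ref=65.0, alpha_beta=3.0, kind="normal"),
    ])


def eqd2_transform(ddvh: DifferentialDVH, alpha_beta: float, n_fractions: int) -> DifferentialDVH:
    """Map every bin dose D to D * (ab + D/n) / (ab + 2); volumes unchanged.

    2 Gy/fraction doses are fixed points for every alpha/beta.
    """
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be > 0")
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    d = ddvh.bin_centers
    mapped = d * (alpha_beta + d / n_fractions) / (alpha_beta + 2.0)
    return replace(ddvh, bin_centers=mapped)


def eud(ddvh: DifferentialDVH, a: float) -> float:
    """Generalized power-mean EUD: (sum_i v_i D_i^a)^(1/a).

    Bins with negligible mass (< 1e-9) are dropped first; a genuine
    zero-dose bin with mass combined with a < 0 is a hard error (the
    cold-spot singularity is physical, not a numerical nuisance).
    """
    if a == 0:
        raise ValueError("a = 0 is not supported (geometric-mean limit excluded)")
    keep = ddvh.fractional_volumes > _ZERO_MASS_TOL
    d = ddvh.bin_centers[keep]
    v = ddvh.fractional_volumes[keep]
    if d.size == 0:
        raise ValueError("differential DVH has no bins with volume")
    if a < 0 and np.any(d <= 0):
        raise ValueError(
            "EUD with a < 0 is singular for zero-dose sub-volumes "
            f"(structure {ddvh.structure_name!r} has mass at 0 Gy)"
        )
    v = v / v.sum()
    return float(np.sum(v * np.power(d, a)) ** (1.0 / a))


def _sigmoid(eud_gy: float, d50: float, gamma50: float) -> float:
    return 1.0 / (1.0 + (d50 / eud_gy) ** (4.0 * gamma50))


def ntcp(eud_gy: float, params: RadiobioParams) -> float:
    """Normal-tissue complication probability at a given EUD (unit interval)."""
    if params.kind != "normal":
        raise ValueError(f"NTCP requires normal-tissue parameters, got kind={params.kind!r}")
    if eud_gy <= 0:
        raise ValueError("EUD must be > 0")
    return _sigmoid(eud_gy, params.d50_ref, params.gamma50)


def tcp(eud_gy: float, params: RadiobioParams) -> float:
    """Tumor control probability at a given EUD (unit interval)."""
    if params.kind != "tumor":
        raise ValueError(f"TCP requires tumor parameters, got kind={params.kind!r}")
    if eud_gy <= 0:
        raise ValueError("EUD must be > 0")
    return _sigmoid(eud_gy, params.d50_ref, params.gamma50)


def structure_radiobiology(
    cdvh: CumulativeDVH,
    params: RadiobioParams,
    n_fractions: int,
    apply_eqd2: bool = True,
    bin_width: float | None = None,
) -> dict[str, float]:
    """EUD plus TCP or NTCP for one structure.

    ``bin_width=None`` uses the exact piecewise-linear decomposition of the
    cumulative curve (no discretization error).
    """
    ddvh = cumulative_to_differential(cdvh, bin_width)
    if apply_eqd2:
        ddvh = eqd2_transform(ddvh, params.alpha_beta, n_fractions)
    e = eud(ddvh, params.a)
    out = {"eud_gy": e}
    if params.kind == "tumor":
        out["tcp"] = tcp(e, params)
    else:
        out["ntcp"] = ntcp(e, params)
    return out


def evaluate_plan_radiobiology(
    plan: PlanDVHSet,
    registry: ParamRegistry | None = None,
    apply_eqd2: bool = True,
    bin_width: float | None = None,
) -> pd.DataFrame:
    """EUD and TCP/NTCP for every registry organ found in the plan.

    Registry organs missing from the plan, or present with zero volume, are
    skipped (recorded in the ``skipped`` attribute of the returned frame).
    Probabilities are unit-interval; table formatting to percent happens at
    the presentation layer.
    """
    registry = registry or default_registry()
    rows = []
    skipped: list[str] = []
    for params in registry:
        cdvh = plan.dvhs.get(params.organ)
        if cdvh is None or cdvh.total_volume <= 0:
            skipped.append(params.organ)
            continue
        res = structure_radiobiology(
            cdvh, params, plan.n_fractions, apply_eqd2=apply_eqd2, bin_width=bin_width
        )
        rows.append({
            "structure": params.organ,
            "kind": params.kind,
            "eud_gy": res["eud_gy"],
            "tcp": res.get("tcp", np.nan),
            "ntcp": res.get("ntcp", np.nan),
        })
    df = pd.DataFrame(rows, columns=["structure", "kind", "eud_gy", "tcp", "ntcp"])
    df.attrs["skipped"] = skipped
    return df
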