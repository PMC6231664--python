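"""Named per-plan metrics used by the cohort tables and statistics.

Metric names understood by :func:`compute_metric`:

* ``min`` / ``max`` / ``mean`` / ``median`` — summary doses (Gy),
* ``vXX`` (e.g. ``v95``, ``v30``) — percent volume receiving >= XX% of the
  prescription dose,
* ``hi`` / ``ci`` / ``cn`` — target indices (require a ``BODY`` DVH in the
  plan for ci/cn),
* ``eud`` / ``tcp`` / ``ntcp`` — radiobiological scores (probabilities as
  percent, to match the table convention).
"""

from __future__ import annotations

from .dvh import PlanDVHSet, dvh_summary, v_x_percent
from .plan_quality import (
    DEFAULT_REFERENCE_ISODOSE_PCT,
    target_index_inputs_from_dvhs,
    target_indices,
)
from .radiobio import ParamRegistry, default_registry, structure_radiobiology

__all__ = ["compute_metric", "BODY_STRUCTURE"]

BODY_STRUCTURE = "BODY"


def compute_metric(
    plan: PlanDVHSet,
    structure: str,
    metric: str,
    ri_pct: float = DEFAULT_REFERENCE_ISODOSE_PCT,
    registry: ParamRegistry | None = None,
    apply_eqd2: bool = True,
) -> float:
    """Evaluate one named metric for one structure of one plan."""
    metric = metric.lower()
    if structure not in plan.dvhs:
        raise KeyError(f"structure {structure!r} not in plan {plan.patient_id}/{plan.variant_label}")
    cdvh = plan.dvhs[structure]

    if metric in ("min", "max", "mean", "median"):
        return dvh_summary(cdvh)[metric]

    if metric.startswith("v") and metric[1:].replace(".", "", 1).isdigit():
        return v_x_percent(cdvh, float(metric[1:]), plan.prescription_dose)

    if metric in ("hi", "ci", "cn"):
        body = plan.dvhs.get(BODY_STRUCTURE)
        if body is None and metric != "hi":
            raise KeyError(f"plan has no {BODY_STRUCTURE!r} DVH; cannot compute {metric}")
        ri_dose = ri_pct / 100.0 * plan.prescription_dose
        if metric == "hi":
            from .dvh import dose_at_volume
            from .plan_quality import homogeneity_index

            return homogeneity_index(
                dose_at_volume(cdvh, 0.02), dose_at_volume(cdvh, 0.98), dose_at_volume(cdvh, 0.50)
            )
        inputs = target_index_inputs_from_dvhs(cdvh, ri_dose, body=body)
        return target_indices(inputs)[metric.upper()]

    if metric in ("eud", "tcp", "ntcp"):
        registry = registry or default_registry()
        if structure not in registry:
            raise KeyError(f"no radiobiological parameters for structure {structure!r}")
        res = structure_radiobiology(
            cdvh, registry[structure], plan.n_fractions, apply_eqd2=apply_eqd2
        )
        if metric == "eud":
            return res["eud_gy"]
        if metric not in res:
            raise ValueError(f"{metric} not applicable to {structure!r} (kind mismatch)")
        return 100.0 * res[metric]

    raise ValueError(f"unknown metric {metric!r}")
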