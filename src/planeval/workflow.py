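"""End-to-end cohort analysis: per-plan metrics, summary tables, deviations,
radiobiological scores and paired statistics, written as tidy CSVs.

All emitted tables keep full-precision value columns; display rounding is
confined to ``*_display`` columns.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .cohort_stats import check_balance, comparison_table
from .config import AnalysisConfig
from .dvh import PlanDVHSet
from .metrics import compute_metric
from .plan_quality import percent_deviation
from .radiobio import ParamRegistry, default_registry

__all__ = [
    "plan_metrics_table",
    "summary_table",
    "deviation_table",
    "run_full_analysis",
]

PTV_METRICS = ["v95", "median", "mean", "max", "min", "ci", "cn", "hi"]
OAR_METRICS = ["max", "min", "mean", "median", "v30", "v50", "v70"]
OAR_STRUCTURES = ["Bladder", "Rectum", "FemoralHead_R", "FemoralHead_L"]
DEVIATION_METRICS = ["max", "min", "mean", "median"]
STAT_METRICS: list[tuple[str, str]] = (
    [("PTV", m) for m in ["mean", "median", "tcp", "v95", "hi", "ci", "cn"]]
    + [(s, m) for s in OAR_STRUCTURES for m in ["mean", "median", "max", "v30", "v50", "v70", "ntcp"]]
)


def _variant_label(variant: tuple[str, float]) -> str:
    alg, g = variant
    return f"{alg}{int(g) if float(g).is_integer() else g}"


def plan_metrics_table(
    cohort: Iterable[PlanDVHSet],
    config: AnalysisConfig | None = None,
    registry: ParamRegistry | None = None,
) -> pd.DataFrame:
    """Long table: one row per (patient, variant, structure, metric).

    Doses are reported in Gy for the target and in % of the prescription
    for organs at risk (the two table conventions used side by side);
    probabilities in percent.
    """
    config = config or AnalysisConfig()
    registry = registry or default_registry()
    rows = []

    def add(plan: PlanDVHSet, structure: str, metric: str, value: float) -> None:
        rows.append({
            "patient": plan.patient_id,
            "algorithm": plan.algorithm,
            "grid_mm": plan.grid_mm,
            "structure": structure,
            "metric": metric,
            "value": value,
        })

    for plan in cohort:
        for metric in PTV_METRICS:
            add(plan, "PTV", metric, compute_metric(
                plan, "PTV", metric, ri_pct=config.reference_isodose_pct,
                registry=registry, apply_eqd2=config.apply_eqd2))
        add(plan, "PTV", "tcp", compute_metric(
            plan, "PTV", "tcp", registry=registry, apply_eqd2=config.apply_eqd2))
        for structure in OAR_STRUCTURES:
            if structure not in plan.dvhs:
                continue
            for metric in OAR_METRICS:
                value = compute_metric(plan, structure, metric,
                                       ri_pct=config.reference_isodose_pct)
                if metric in ("max", "min", "mean", "median"):
                    value = value / plan.prescription_dose * 100.0
                add(plan, structure, metric, value)
            add(plan, structure, "ntcp", compute_metric(
                plan, structure, "ntcp", registry=registry, apply_eqd2=config.apply_eqd2))
    return pd.DataFrame(rows)


def summary_table(plan_metrics: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean and SD per (structure, metric, variant), with a 2-decimal
    display column."""
    grouped = (
        plan_metrics.groupby(["structure", "metric", "algorithm", "grid_mm"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"std": "sd", "count": "n"})
    )
    grouped["sd"] = grouped["sd"].fillna(0.0)
    grouped["display"] = grouped.apply(
        lambda r: f"{r['mean']:.2f} ({r['sd']:.2f})", axis=1
    )
    return grouped


def deviation_table(
    plan_metrics: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Percent deviation of each variant's cohort-average dose parameters
    from the reference variant."""
    ref_alg, ref_grid = config.reference_variant
    dose_rows = plan_metrics[plan_metrics["metric"].isin(DEVIATION_METRICS)]
    means = (
        dose_rows.groupby(["structure", "metric", "algorithm", "grid_mm"])["value"]
        .mean()
        .reset_index()
    )
    ref = means[(means["algorithm"] == ref_alg) & (means["grid_mm"] == ref_grid)]
    if ref.empty:
        raise ValueError(
            f"reference variant {_variant_label(config.reference_variant)} absent from cohort"
        )
    ref_map = {(r.structure, r.metric): r.value for r in ref.itertuples()}
    rows = []
    for r in means.itertuples():
        if (r.algorithm, r.grid_mm) == (ref_alg, ref_grid):
            continue
        ref_val = ref_map[(r.structure, r.metric)]
        dev = percent_deviation(ref_val, r.value)
        rows.append({
            "structure": r.structure,
            "metric": r.metric,
            "algorithm": r.algorithm,
            "grid_mm": r.grid_mm,
            "reference": _variant_label(config.reference_variant),
            "deviation_pct": dev,
            "deviation_display": f"{dev:.2f}",
        })
    return pd.DataFrame(rows)


def _validate_cohort(cohort: Sequence[PlanDVHSet], config: AnalysisConfig,
                     registry: ParamRegistry) -> list[str]:
    problems = []
    try:
        by_patient = check_balance(cohort)
    except ValueError as exc:
        problems.append(str(exc))
        by_patient = {}
    variants = {p.variant for p in cohort}
    if tuple(config.reference_variant) not in variants:
        problems.append(
            f"reference variant {_variant_label(config.reference_variant)} not in cohort"
        )
    for pair in config.contrasts:
        for v in pair:
            if tuple(v) not in variants:
                problems.append(f"contrast variant {_variant_label(v)} not in cohort")
    for plan in cohort:
        missing = [o for o in ("PTV", "BODY") if o not in plan.dvhs]
        if missing:
            problems.append(
                f"plan {plan.patient_id}/{plan.variant_label} lacks structures {missing}"
            )
    del by_patient
    return problems


def run_full_analysis(
    cohort: Sequence[PlanDVHSet] | str | Path,
    config: AnalysisConfig | None = None,
    registry: ParamRegistry | None = None,
    output_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Compute the five result tables for a cohort (or cohort directory).

    Returns ``{"plan_metrics", "ptv_summary", "oar_summary", "deviations",
    "radiobio_summary", "pvalues"}``; also writes them as CSVs plus a JSON
    run log when an output directory is given (or set in the config).
    """
    config = config or AnalysisConfig()
    input_digest = None
    if isinstance(cohort, (str, Path)):
        from .io import read_cohort

        cohort_dir = Path(cohort)
        digest = hashlib.sha256()
        for f in sorted(cohort_dir.glob("*")):
            if f.is_file():
                digest.update(f.name.encode())
                digest.update(f.read_bytes())
        input_digest = digest.hexdigest()
        cohort = read_cohort(cohort_dir)
    cohort = list(cohort)
    if registry is None:
        registry = (
            ParamRegistry.from_csv(config.param_registry_path)
            if config.param_registry_path
            else default_registry()
        )

    problems = _validate_cohort(cohort, config, registry)
    if problems:
        raise ValueError("invalid cohort/config:\n- " + "\n- ".join(problems))

    pm = plan_metrics_table(cohort, config, registry)
    summaries = summary_table(pm)
    tables = {
        "plan_metrics": pm,
        "ptv_summary": summaries[summaries["structure"] == "PTV"].reset_index(drop=True),
        "oar_summary": summaries[
            summaries["structure"].isin(OAR_STRUCTURES)
            & ~summaries["metric"].isin(["tcp", "ntcp"])
        ].reset_index(drop=True),
        "deviations": deviation_table(pm, config),
        "radiobio_summary": summaries[
            summaries["metric"].isin(["tcp", "ntcp"])
        ].reset_index(drop=True),
        "pvalues": comparison_table(
            cohort,
            contrasts=list(config.contrasts),
            metrics=STAT_METRICS,
            metric_fn=lambda plan, s, m: compute_metric(
                plan, s, m, ri_pct=config.reference_isodose_pct,
                registry=registry, apply_eqd2=config.apply_eqd2,
            ),
        ),
    }

    out = output_dir or config.output_dir
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            # repr gives shortest round-trippable float text (exact read-back)
            df.to_csv(out / f"{name}.csv", index=False,
                      float_format=lambda x: repr(float(x)))
        log = {
            "version": __version__,
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "input_digest": input_digest,
            "n_plans": len(cohort),
            "n_patients": len({p.patient_id for p in cohort}),
        }
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
    return tables
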