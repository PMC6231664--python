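"""Readers and writers for DVH exports and cohort directories.

Two input dialects are supported:

* plain CSV with columns ``structure,total_cm3,dose_gy,volume_fraction``
  (one row per curve point, structure rows contiguous);
* TPS-style text export: per-structure header block (``Structure:``,
  ``Volume [cm3]:``) followed by a two-column table whose headers declare
  the units (dose in Gy or % of prescription, volume in cm3 or %).

Both are converted to relative-volume curves internally.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dvh import CumulativeDVH, PlanDVHSet

__all__ = [
    "ParseError",
    "read_dvh_csv",
    "write_dvh_csv",
    "parse_tps_text",
    "parse_dvh_export",
    "write_cohort",
    "read_cohort",
]


class ParseError(ValueError):
    """Input file not understood; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# CSV dialect


def write_dvh_csv(path, dvhs: Iterable[CumulativeDVH]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["structure", "total_cm3", "dose_gy", "volume_fraction"])
        for dvh in dvhs:
            for d, f in zip(dvh.dose_gy, dvh.volume_fraction):
                w.writerow([dvh.structure_name, repr(dvh.total_volume), repr(float(d)), repr(float(f))])


def read_dvh_csv(path) -> list[CumulativeDVH]:
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"structure", "total_cm3", "dose_gy", "volume_fraction"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(
                f"expected columns {sorted(required)}, got {reader.fieldnames}", path, 1
            )
        for i, rec in enumerate(reader, start=2):
            try:
                name = rec["structure"]
                if name not in rows:
                    rows[name] = {"total": float(rec["total_cm3"]), "d": [], "f": []}
                    order.append(name)
                rows[name]["d"].append(float(rec["dose_gy"]))
                rows[name]["f"].append(float(rec["volume_fraction"]))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"bad row: {exc}", path, i) from exc
    return [
        CumulativeDVH(name, rows[name]["total"], np.asarray(rows[name]["d"]),
                      np.asarray(rows[name]["f"]))
        for name in order
    ]


# ---------------------------------------------------------------------------
# TPS text dialect

_STRUCT_RE = re.compile(r"^\s*Structure\s*:\s*(.+?)\s*$")
_VOLUME_RE = re.compile(r"^\s*Volume\s*\[cm.?3?.?\]\s*:\s*([0-9.eE+-]+)\s*$")
_HEADER_RE = re.compile(r"^\s*Dose\s*\[(Gy|%)\]\s+.*Volume\s*\[(cm.?3?.?|%)\]\s*$", re.IGNORECASE)
_DATA_RE = re.compile(r"^\s*([0-9.eE+-]+)\s+([0-9.eE+-]+)\s*$")


def parse_tps_text(path, prescription: float | None = None) -> list[tuple[str, CumulativeDVH]]:
    """Parse a TPS-style text export; returns (structure name, DVH) pairs.

    ``prescription`` (Gy) is required when the dose column is in percent.
    """
    out: list[tuple[str, CumulativeDVH]] = []
    name = volume = None
    dose_unit = vol_unit = None
    d_pts: list[float] = []
    v_pts: list[float] = []

    def flush(line_no: int) -> None:
        nonlocal name, volume, dose_unit, vol_unit, d_pts, v_pts
        if name is None:
            return
        if volume is None:
            raise ParseError(f"structure block {name!r} has no volume line", path, line_no)
        if not d_pts:
            raise ParseError(f"structure block {name!r} has no data rows", path, line_no)
        dose = np.asarray(d_pts)
        vol = np.asarray(v_pts)
        if dose_unit == "%":
            if prescription is None:
                raise ParseError("dose column in % requires a prescription dose", path, line_no)
            dose = dose * prescription / 100.0
        if vol_unit == "%":
            vol = vol / 100.0
        else:  # absolute cm3
            vol = vol / volume
        out.append((name, CumulativeDVH(name, volume, dose, vol)))
        name = volume = dose_unit = vol_unit = None
        d_pts, v_pts = [], []

    with open(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            m = _STRUCT_RE.match(line)
            if m:
                flush(line_no)
                name = m.group(1)
                continue
            m = _VOLUME_RE.match(line)
            if m:
                volume = float(m.group(1))
                continue
            m = _HEADER_RE.match(line)
            if m:
                dose_unit = "%" if m.group(1) == "%" else "Gy"
                vol_unit = "%" if m.group(2) == "%" else "cm3"
                continue
            m = _DATA_RE.match(line)
            if m:
                if name is None or dose_unit is None:
                    raise ParseError("data row before a structure/column header", path, line_no)
                d_pts.append(float(m.group(1)))
                v_pts.append(float(m.group(2)))
                continue
            raise ParseError(f"unrecognized line: {line.strip()!r}", path, line_no)
        flush(line_no + 1)
    if not out:
        raise ParseError("no structure blocks found", path, 1)
    return out


def parse_dvh_export(path, prescription: float | None = None) -> list[tuple[str, CumulativeDVH]]:
    """Dialect auto-detection: CSV when the first line is the CSV header,
    TPS text otherwise."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.strip().startswith("structure,"):
        return [(dvh.structure_name, dvh) for dvh in read_dvh_csv(path)]
    return parse_tps_text(path, prescription)


# ---------------------------------------------------------------------------
# cohort directories


def _plan_filename(plan: PlanDVHSet) -> str:
    return f"{plan.patient_id}_{plan.variant_label}.csv"


def write_cohort(cohort: Sequence[PlanDVHSet], out_dir, spec=None) -> Path:
    """One DVH CSV per (patient, variant) plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for plan in cohort:
        fname = _plan_filename(plan)
        write_dvh_csv(out_dir / fname, plan.dvhs.values())
        entries.append({
            "file": fname,
            "patient_id": plan.patient_id,
            "algorithm": plan.algorithm,
            "grid_mm": plan.grid_mm,
            "prescription_dose": plan.prescription_dose,
            "n_fractions": plan.n_fractions,
        })
    manifest = {"plans": entries}
    if spec is not None:
        manifest["generator"] = {
            "n_patients": spec.n_patients,
            "seed": spec.seed,
            "prescription": spec.prescription,
            "n_fractions": spec.n_fractions,
            "variants": [list(v) for v in spec.variants],
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out_dir


def read_cohort(cohort_dir) -> list[PlanDVHSet]:
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.json"
    if not manifest_path.exists():
        raise ParseError("missing manifest.json", cohort_dir)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    plans = []
    for entry in manifest["plans"]:
        dvhs = read_dvh_csv(cohort_dir / entry["file"])
        plans.append(PlanDVHSet(
            patient_id=entry["patient_id"],
            algorithm=entry["algorithm"],
            grid_mm=float(entry["grid_mm"]),
            dvhs={dvh.structure_name: dvh for dvh in dvhs},
            prescription_dose=float(entry["prescription_dose"]),
            n_fractions=int(entry["n_fractions"]),
        ))
    return plans
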