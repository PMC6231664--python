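"""Analysis configuration: defaults, file loading (YAML/JSON) and validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .cohort_stats import DEFAULT_CONTRASTS

__all__ = ["AnalysisConfig", "load_config"]

Variant = tuple[str, float]


@dataclass(frozen=True)
class AnalysisConfig:
    prescription: float = 78.0
    n_fractions: int = 39
    reference_isodose_pct: float = 95.0
    reference_variant: Variant = ("AXB", 1.0)
    apply_eqd2: bool = True
    param_registry_path: str | None = None
    contrasts: tuple[tuple[Variant, Variant], ...] = tuple(
        (tuple(a), tuple(b)) for a, b in DEFAULT_CONTRASTS
    )
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.prescription <= 0:
            raise ValueError("prescription must be > 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if not (0 < self.reference_isodose_pct <= 100):
            raise ValueError("reference_isodose_pct must be in (0, 100]")

    @property
    def reference_isodose_dose(self) -> float:
        return self.reference_isodose_pct / 100.0 * self.prescription

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reference_variant"] = list(self.reference_variant)
        d["contrasts"] = [[list(a), list(b)] for a, b in self.contrasts]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Read a YAML or JSON key-value config file; missing keys keep defaults."""
    if path is None:
        return AnalysisConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "reference_variant" in data:
        alg, grid = data["reference_variant"]
        data["reference_variant"] = (str(alg), float(grid))
    if "contrasts" in data:
        data["contrasts"] = tuple(
            ((str(a[0]), float(a[1])), (str(b[0]), float(b[1])))
            for a, b in data["contrasts"]
        )
    return AnalysisConfig(**data)
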