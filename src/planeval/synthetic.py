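"""Seeded virtual prostate-plan cohorts for end-to-end pipeline testing.

No radiation transport is simulated.  Each patient gets a parametric base
DVH per structure (target: sigmoid falloff near the prescription with a
cold tail from the rectal air cavity; rectum: broad serial-organ curve with
a high-dose shoulder from target overlap; bladder / femoral heads: low- and
mid-dose curves; body: background bath plus target spill).  Plan variants
(algorithm x calculation grid) are then derived deterministically from the
base through an explicit effect model:

* the AAA-like algorithm credits extra target coverage inside the air
  cavity and a higher rectal dose,
* coarser grids soften the dose falloff edge (strongly for AAA-like,
  weakly for AXB-like) and shift the AXB-like median dose upward.

Effect magnitudes default to published cohort-level gaps (target coverage
gap ~2.4 percentage points, rectal mean-dose gap ~2.9% of the prescription
dose); they are calibration targets, not reproductions of any patient data.

Randomness: one child stream per (seed, patient) for anatomy and one per
(seed, patient, variant) for residual noise, so enlarging a cohort never
perturbs existing patients.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dose_grid import DoseGrid, Frame, StructureMask
from .dvh import CumulativeDVH, PlanDVHSet

__all__ = [
    "NoiseModel",
    "EffectModel",
    "CohortSpec",
    "PhantomSpec",
    "generate_patient",
    "generate_cohort",
    "generate_dose_phantom",
    "STRUCTURES",
]

Variant = tuple[str, float]

DEFAULT_VARIANTS: tuple[Variant, ...] = (
    ("AAA", 1.0), ("AAA", 3.0), ("AAA", 5.0),
    ("AXB", 1.0), ("AXB", 2.0), ("AXB", 3.0),
)

STRUCTURES = ("PTV", "Rectum", "Bladder", "FemoralHead_L", "FemoralHead_R", "BODY")

_DOSE_AXIS = np.round(np.arange(0.0, 90.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class NoiseModel:
    """Per-(patient, variant) residual noise scales; zero means the variants
    are exact deterministic transforms of the patient base."""

    edge_jitter_gy: float = 0.05
    coverage_jitter_pct: float = 0.12
    oar_scale_jitter: float = 0.004

    def zeroed(self) -> "NoiseModel":
        return NoiseModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class EffectModel:
    """Deterministic algorithm/grid effects applied in DVH space."""

    air_overlap_fraction: float = 0.10
    aaa_air_coverage_boost: float = 2.38  # percentage points of target V95
    grid_falloff_blur: dict = field(
        default_factory=lambda: {"AAA": 0.35, "AXB": 0.02}
    )  # relative edge widening per mm above 1 mm
    axb_grid_median_shift_gy_per_mm: float = 0.33
    rectum_dose_shift: float = 2.87  # % of prescription added to AAA rectal mean
    rectum_grid_trend: dict = field(
        default_factory=lambda: {"AAA": -0.004, "AXB": 0.008}
    )  # relative mean-dose change per mm above 1 mm
    bladder_dose_shift: float = 0.60  # % of prescription, AAA bladder mean
    femur_dose_shift: float = 0.55  # % of prescription, AAA femoral mean
    aaa_spill: float = 0.05  # extra body spill at the reference isodose (CI effect)

    def __post_init__(self) -> None:
        if not (0.0 <= self.air_overlap_fraction <= 1.0):
            raise ValueError("air_overlap_fraction must be in [0, 1]")
        if any(b < 0 for b in self.grid_falloff_blur.values()):
            raise ValueError("grid blur must be >= 0")
        for name in ("aaa_air_coverage_boost", "rectum_dose_shift",
                     "bladder_dose_shift", "femur_dose_shift"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def zeroed(self) -> "EffectModel":
        return dataclasses.replace(
            self,
            aaa_air_coverage_boost=0.0,
            grid_falloff_blur={"AAA": 0.0, "AXB": 0.0},
            axb_grid_median_shift_gy_per_mm=0.0,
            rectum_dose_shift=0.0,
            rectum_grid_trend={"AAA": 0.0, "AXB": 0.0},
            bladder_dose_shift=0.0,
            femur_dose_shift=0.0,
            aaa_spill=0.0,
        )


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 20
    seed: int = 0
    prescription: float = 78.0
    n_fractions: int = 39
    variants: tuple[Variant, ...] = DEFAULT_VARIANTS
    effects: EffectModel = field(default_factory=EffectModel)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.prescription <= 0 or self.n_fractions < 1:
            raise ValueError("invalid prescription/fractionation")

    @property
    def allowed_variants(self) -> set[Variant]:
        return set(self.variants)


# ---------------------------------------------------------------------------
# base curve primitives


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _finalize(curve: np.ndarray) -> np.ndarray:
    curve = np.clip(curve, 0.0, 1.0)
    curve[0] = 1.0
    return curve


def _ptv_curve(d, mu, width, cold_mass, cold_mu, cold_w, d_min, d_max):
    f = (1.0 - cold_mass) * _logistic((mu - d) / width)
    f += cold_mass * _logistic((cold_mu - d) / cold_w)
    f /= f[0]
    f = np.where(d <= d_min, 1.0, f)
    f = np.where(d >= d_max, 0.0, f)
    return _finalize(f)


def _rectum_curve(d, overlap, mid_mu, mid_w, hi_mu, hi_w, d_min, d_max):
    f = (1.0 - overlap) * _logistic((mid_mu - d) / mid_w)
    f += overlap * _logistic((hi_mu - d) / hi_w)
    f /= f[0]
    f = np.where(d <= d_min, 1.0, f)
    f = np.where(d >= d_max, 0.0, f)
    return _finalize(f)


def _weibull_curve(d, lam, k, d_min, d_max):
    f = np.exp(-np.power(d / lam, k, where=d > 0, out=np.zeros_like(d)))
    f = np.where(d <= d_min, 1.0, f)
    f = np.where(d >= d_max, 0.0, f)
    return _finalize(f)


def _femur_curve(d, mu, width, d_min, d_max):
    f = _logistic((mu - d) / width)
    f /= f[0]
    f = np.where(d <= d_min, 1.0, f)
    f = np.where(d >= d_max, 0.0, f)
    return _finalize(f)


def _coverage_bump(d: np.ndarray, ri_dose: float) -> np.ndarray:
    """Unit bump: ramps up from 30 Gy, flat 1 around the reference isodose
    (so interpolated queries at the isodose see the full boost), back to 0."""
    knots = [30.0, ri_dose - 1.5, ri_dose + 1.5, ri_dose + 7.0]
    return np.interp(d, knots, [0.0, 1.0, 1.0, 0.0])


def _curve_mean(d: np.ndarray, f: np.ndarray) -> float:
    drops = f[:-1] - f[1:]
    return float(np.sum(drops * 0.5 * (d[:-1] + d[1:])) + f[-1] * d[-1])


# ---------------------------------------------------------------------------
# patient generation


def _patient_anatomy(spec: CohortSpec, patient_index: int) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1000 + patient_index]))
    presc = spec.prescription
    return {
        "ptv_mu": presc * 1.020 + rng.normal(0.0, 0.15),
        "ptv_w": 0.9 * np.exp(rng.normal(0.0, 0.08)),
        "cold_mass": 0.040 + rng.normal(0.0, 0.003),
        "cold_mu": presc * 0.91 + rng.normal(0.0, 0.6),
        "cold_w": 2.5 * np.exp(rng.normal(0.0, 0.1)),
        "ptv_dmin": presc * 0.795 + rng.normal(0.0, 2.5),
        "ptv_dmax": presc * 1.083 + rng.normal(0.0, 0.5),
        "tv_cm3": max(40.0, rng.normal(80.0, 10.0)),
        "overlap": np.clip(
            spec.effects.air_overlap_fraction + rng.normal(0.0, 0.015), 0.02, 0.5
        ),
        "rect_mid_mu": presc * 0.43 + rng.normal(0.0, 2.0),
        "rect_mid_w": 9.0 * np.exp(rng.normal(0.0, 0.08)),
        "rect_hi_mu": presc * 0.99 + rng.normal(0.0, 0.3),
        "rect_hi_w": 1.5,
        "rect_dmin": presc * 0.023 + rng.normal(0.0, 0.3),
        "rect_dmax": presc * 1.045 + rng.normal(0.0, 0.4),
        "rect_cm3": max(80.0, rng.normal(165.0, 15.0)),
        "blad_lam": 18.0 * np.exp(rng.normal(0.0, 0.12)),
        "blad_k": 0.75 + rng.normal(0.0, 0.04),
        "blad_dmin": presc * 0.013 + rng.normal(0.0, 0.2),
        "blad_dmax": presc * 1.065 + rng.normal(0.0, 0.5),
        "blad_cm3": max(90.0, rng.normal(220.0, 30.0)),
        "fem_mu": {
            "L": presc * 0.275 + rng.normal(0.0, 1.2),
            "R": presc * 0.288 + rng.normal(0.0, 1.2),
        },
        "fem_w": 5.0 * np.exp(rng.normal(0.0, 0.08)),
        "fem_dmin": presc * 0.05 + rng.normal(0.0, 0.4),
        "fem_dmax": presc * 0.47 + rng.normal(0.0, 0.8),
        "fem_cm3": max(30.0, rng.normal(60.0, 8.0)),
        "body_cm3": max(5000.0, rng.normal(9000.0, 500.0)),
        "body_lam": 7.3 * np.exp(rng.normal(0.0, 0.05)),
        "spill": 1.035 + rng.normal(0.0, 0.008),
    }


def _build_structure(name: str, total_volume: float, curve: np.ndarray,
                     context: str) -> CumulativeDVH:
    try:
        return CumulativeDVH(name, total_volume, _DOSE_AXIS.copy(), curve)
    except ValueError as exc:  # pragma: no cover - guarded by effect validation
        raise ValueError(
            f"effect model produced an invalid cumulative DVH for {name} ({context}): {exc}"
        ) from exc


def _variant_plan(spec: CohortSpec, anatomy: dict, patient_index: int,
                  variant_index: int) -> PlanDVHSet:
    alg, grid = spec.variants[variant_index]
    eff, noise = spec.effects, spec.noise
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 1000 + patient_index, variant_index])
    )
    d = _DOSE_AXIS
    presc = spec.prescription
    ri_dose = 0.95 * presc
    context = f"patient {patient_index}, variant {alg}{grid:g}"

    blur = eff.grid_falloff_blur.get(alg, 0.0) * max(grid - 1.0, 0.0)
    width = anatomy["ptv_w"] * (1.0 + blur)
    mu = anatomy["ptv_mu"] + rng.normal(0.0, noise.edge_jitter_gy)
    if alg == "AXB":
        mu += eff.axb_grid_median_shift_gy_per_mm * max(grid - 1.0, 0.0)
    ptv = _ptv_curve(
        d, mu, width, anatomy["cold_mass"], anatomy["cold_mu"],
        anatomy["cold_w"] * (1.0 + blur), anatomy["ptv_dmin"], anatomy["ptv_dmax"],
    )
    boost = 0.0
    if alg == "AAA":
        boost = eff.aaa_air_coverage_boost + rng.normal(0.0, noise.coverage_jitter_pct)
        ptv = np.clip(ptv + boost / 100.0 * _coverage_bump(d, ri_dose), 0.0, 1.0)
        ptv[0] = 1.0

    def oar_scale(shift_pct: float, base_mean: float, trend: float) -> float:
        k = 1.0
        if alg == "AAA" and shift_pct != 0.0:
            k *= 1.0 + shift_pct / 100.0 * presc / base_mean
        k *= 1.0 + trend * max(grid - 1.0, 0.0)
        k *= 1.0 + rng.normal(0.0, noise.oar_scale_jitter)
        return k

    rect_base = _rectum_curve(
        d, anatomy["overlap"], anatomy["rect_mid_mu"], anatomy["rect_mid_w"],
        anatomy["rect_hi_mu"], anatomy["rect_hi_w"], anatomy["rect_dmin"],
        anatomy["rect_dmax"],
    )
    k_rect = oar_scale(
        eff.rectum_dose_shift, _curve_mean(d, rect_base),
        eff.rectum_grid_trend.get(alg, 0.0),
    )
    rectum = _rectum_curve(
        d / k_rect, anatomy["overlap"], anatomy["rect_mid_mu"], anatomy["rect_mid_w"],
        anatomy["rect_hi_mu"], anatomy["rect_hi_w"], anatomy["rect_dmin"],
        anatomy["rect_dmax"],
    )

    blad_base = _weibull_curve(d, anatomy["blad_lam"], anatomy["blad_k"],
                               anatomy["blad_dmin"], anatomy["blad_dmax"])
    k_blad = oar_scale(eff.bladder_dose_shift, _curve_mean(d, blad_base), 0.0)
    bladder = _weibull_curve(d / k_blad, anatomy["blad_lam"], anatomy["blad_k"],
                             anatomy["blad_dmin"], anatomy["blad_dmax"])

    femurs = {}
    for side in ("L", "R"):
        fem_base = _femur_curve(d, anatomy["fem_mu"][side], anatomy["fem_w"],
                                anatomy["fem_dmin"], anatomy["fem_dmax"])
        k_fem = oar_scale(eff.femur_dose_shift, _curve_mean(d, fem_base), 0.0)
        femurs[side] = _femur_curve(d / k_fem, anatomy["fem_mu"][side], anatomy["fem_w"],
                                    anatomy["fem_dmin"], anatomy["fem_dmax"])

    # body: low-dose background bath plus spill around the covered target
    tv, vbody = anatomy["tv_cm3"], anatomy["body_cm3"]
    spill = anatomy["spill"] + (eff.aaa_spill if alg == "AAA" else 0.0)
    body_abs = (vbody - tv) * np.exp(
        -np.power(d / anatomy["body_lam"], 0.9, where=d > 0, out=np.zeros_like(d))
    )
    body_abs += tv * spill * ptv
    body = _finalize(body_abs / body_abs[0])

    dvhs = {
        "PTV": _build_structure("PTV", tv, ptv, context),
        "Rectum": _build_structure("Rectum", anatomy["rect_cm3"], rectum, context),
        "Bladder": _build_structure("Bladder", anatomy["blad_cm3"], bladder, context),
        "FemoralHead_L": _build_structure("FemoralHead_L", anatomy["fem_cm3"], femurs["L"], context),
        "FemoralHead_R": _build_structure("FemoralHead_R", anatomy["fem_cm3"], femurs["R"], context),
        "BODY": _build_structure("BODY", vbody, body, context),
    }
    return PlanDVHSet(
        patient_id=f"P{patient_index:03d}", algorithm=alg, grid_mm=grid, dvhs=dvhs,
        prescription_dose=presc, n_fractions=spec.n_fractions,
    )


def generate_patient(spec: CohortSpec, patient_index: int) -> dict[str, PlanDVHSet]:
    """All plan variants of one virtual patient, keyed by variant label.

    Deterministic in (spec.seed, patient_index): repeated calls are
    bitwise-identical, and other patients' draws never interfere.
    """
    if patient_index < 0:
        raise ValueError("patient_index must be >= 0")
    anatomy = _patient_anatomy(spec, patient_index)
    plans = {}
    for vi in range(len(spec.variants)):
        plan = _variant_plan(spec, anatomy, patient_index, vi)
        plans[plan.variant_label] = plan
    return plans


def generate_cohort(spec: CohortSpec, out_dir=None) -> list[PlanDVHSet]:
    """Flat list of all patients x variants; optionally written to disk in
    the plain DVH CSV dialect with a manifest (see :mod:`planeval.io`)."""
    cohort: list[PlanDVHSet] = []
    for i in range(spec.n_patients):
        cohort.extend(generate_patient(spec, i).values())
    if out_dir is not None:
        from .io import write_cohort

        write_cohort(cohort, out_dir, spec)
    return cohort


# ---------------------------------------------------------------------------
# dose phantom


@dataclass(frozen=True)
class PhantomSpec:
    """ERB-like geometry: target ellipsoid, rectal tube with ~70 cm^3 air
    cavity, cylindrical body; one dose grid per plan variant."""

    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    shape: tuple[int, int, int] = (69, 69, 50)
    variants: tuple[Variant, ...] = (("AAA", 1.0), ("AAA", 3.0), ("AXB", 1.0), ("AXB", 3.0))
    plateau_dose: float = 81.0
    air_bump_gy: float = 4.0  # AAA-like extra dose inside the air cavity
    blur_mm_per_mm: float = 0.8  # gaussian sigma per mm of grid above 1 mm
    ptv_center: tuple[float, float, float] = (0.0, -10.0, 0.0)
    ptv_semiaxes: tuple[float, float, float] = (28.0, 25.0, 22.0)
    air_center: tuple[float, float, float] = (0.0, 28.0, 0.0)
    air_semiaxes: tuple[float, float, float] = (22.5, 22.5, 33.0)
    rectum_center_xy: tuple[float, float] = (0.0, 28.0)
    rectum_radius: float = 26.0
    rectum_half_length: float = 40.0
    body_radius: float = 65.0


def _phantom_frame(spec: PhantomSpec) -> Frame:
    half = [(n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing_mm)]
    return Frame(tuple(-h for h in half), spec.spacing_mm, spec.shape)


def generate_dose_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[dict[str, DoseGrid], dict[str, StructureMask]]:
    """Smooth 3D dose field with variant-dependent perturbations plus
    structure masks, all on one frame.

    The AAA-like variants get an additive bump inside the air cavity (added
    after the grid blur, so same-grid algorithm differences live exactly in
    the cavity); coarser grids get a gaussian edge blur.
    """
    spec = spec or PhantomSpec()
    frame = _phantom_frame(spec)
    x, y, z = np.meshgrid(*(frame.axis_coords(ax) for ax in range(3)), indexing="ij")

    def ellipsoid_rho(center, semi):
        return np.sqrt(((x - center[0]) / semi[0]) ** 2
                       + ((y - center[1]) / semi[1]) ** 2
                       + ((z - center[2]) / semi[2]) ** 2)

    body = (np.sqrt(x**2 + y**2) <= spec.body_radius)
    ptv = ellipsoid_rho(spec.ptv_center, spec.ptv_semiaxes) <= 1.0
    air = ellipsoid_rho(spec.air_center, spec.air_semiaxes) <= 1.0
    cx, cy = spec.rectum_center_xy
    rectum = (np.sqrt((x - cx) ** 2 + (y - cy) ** 2) <= spec.rectum_radius) & (
        np.abs(z) <= spec.rectum_half_length
    )
    if not (air <= rectum).all():
        raise ValueError("inconsistent geometry: air cavity extends outside the rectum")
    if not (ptv <= body).all() or not (rectum <= body).all():
        raise ValueError("inconsistent geometry: structures extend outside the body")

    rho = ellipsoid_rho(spec.ptv_center, spec.ptv_semiaxes)
    base = spec.plateau_dose / (1.0 + np.exp(np.clip((rho - 1.06) / 0.045, -60, 60)))
    base += 3.0 * np.exp(-rho / 2.0)
    base[~body] = 0.0

    grids: dict[str, DoseGrid] = {}
    for alg, grid_mm in spec.variants:
        sigma_mm = spec.blur_mm_per_mm * max(grid_mm - 1.0, 0.0)
        values = base
        if sigma_mm > 0:
            sigma_vox = [sigma_mm / s for s in spec.spacing_mm]
            values = ndimage.gaussian_filter(base, sigma_vox)
        values = values.copy()
        if alg == "AAA" and spec.air_bump_gy:
            values[air] += spec.air_bump_gy
        gtxt = str(int(grid_mm)) if float(grid_mm).is_integer() else str(grid_mm)
        grids[f"{alg}{gtxt}"] = DoseGrid(frame, values)

    masks = {
        "BODY": StructureMask(frame, body),
        "PTV": StructureMask(frame, ptv),
        "Rectum": StructureMask(frame, rectum),
        "AirCavity": StructureMask(frame, air),
    }
    return grids, masks
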