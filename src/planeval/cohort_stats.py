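"""Paired nonparametric comparison of plan variants.

The Wilcoxon signed-rank test is implemented from first principles because
the cohort analysis needs the exact null distribution with midranks under
ties, which off-the-shelf routines decline to compute.  The exact
distribution is obtained by dynamic programming over the attainable
rank sums, which is mathematically identical to full enumeration of the
2^n sign assignments (each rank contributes or not), at polynomial cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dvh import PlanDVHSet

__all__ = [
    "PairedSample",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "comparison_table",
    "DEFAULT_CONTRASTS",
    "format_p",
]

Variant = tuple[str, float]

#: Default contrast list for the six-variant two-algorithm design.
DEFAULT_CONTRASTS: list[tuple[Variant, Variant]] = [
    (("AAA", 1.0), ("AXB", 1.0)),
    (("AAA", 3.0), ("AXB", 3.0)),
    (("AAA", 1.0), ("AAA", 3.0)),
    (("AAA", 1.0), ("AAA", 5.0)),
    (("AXB", 1.0), ("AXB", 2.0)),
    (("AXB", 1.0), ("AXB", 3.0)),
]


@dataclass(frozen=True)
class PairedSample:
    """Per-patient value pairs for one metric under two plan variants."""

    label_a: str
    label_b: str
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if self.label_a == self.label_b:
            raise ValueError("paired sample labels must be distinct")
        if a.ndim != 1 or a.shape != b.shape:
            raise ValueError("values_a and values_b must be 1-D arrays of equal length")
        if a.size < 1:
            raise ValueError("paired sample needs at least one pair")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("missing pairs are not allowed")

    @property
    def n(self) -> int:
        return int(self.values_a.size)

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_two_sided: float
    n_used: int  # nonzero differences entering the ranking
    n_zeros: int
    method: str  # "exact" or "normal_approx"
    degenerate: bool = False


def _exact_p_two_sided(double_ranks: np.ndarray, double_w_plus: int) -> float:
    """Exact two-sided p from the null distribution of W+.

    ``double_ranks`` are the (mid)ranks doubled so they are integers; the
    distribution of the doubled positive-rank sum is built by DP over sign
    assignments (equivalent to enumerating all 2^n of them).
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    n_assign = counts.sum()  # == 2^n, exact in float64 for n <= 45
    p_le = counts[: double_w_plus + 1].sum() / n_assign
    p_ge = counts[double_w_plus:].sum() / n_assign
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    sample: PairedSample,
    mode: Literal["exact", "normal_approx", "auto"] = "auto",
    zero_method: Literal["wilcox", "pratt"] = "wilcox",
    exact_cutoff: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired plan metrics.

    Midranks are used for tied |differences|.  In ``auto`` mode the exact
    distribution is used for up to ``exact_cutoff`` nonzero pairs, the
    tie-corrected normal approximation with continuity correction beyond.
    Zero differences are dropped before ranking (``wilcox``) or ranked and
    then discarded from the statistic (``pratt``); an all-zero sample is
    degenerate and reported with p = 1.
    """
    d = sample.differences
    n_zeros = int((d == 0).sum())
    if zero_method == "wilcox":
        d_ranked = d[d != 0]
        ranks = sps.rankdata(np.abs(d_ranked)) if d_ranked.size else np.array([])
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        d_ranked = d[keep]
        ranks = ranks_all[keep]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    m = d_ranked.size
    if m == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_zeros, "degenerate", degenerate=True)

    w_plus = float(ranks[d_ranked > 0].sum())
    if mode == "auto":
        mode = "exact" if m <= exact_cutoff else "normal_approx"

    if mode == "exact":
        double_ranks = np.rint(2 * ranks).astype(np.int64)
        p = _exact_p_two_sided(double_ranks, int(round(2 * w_plus)))
        return WilcoxonResult(w_plus, p, m, n_zeros, "exact")

    if mode != "normal_approx":
        raise ValueError(f"unknown mode {mode!r}")
    mu = float(ranks.sum()) / 2.0
    # variance of W+ under random signs: sum(r_i^2) / 4, which reduces to the
    # textbook m(m+1)(2m+1)/24 - tie-correction form for untied ranks
    sigma2 = float(np.sum(ranks**2)) / 4.0
    if sigma2 == 0:
        return WilcoxonResult(w_plus, 1.0, m, n_zeros, "degenerate", degenerate=True)
    num = w_plus - mu
    num -= 0.5 * np.sign(num)  # continuity correction toward the mean
    z = num / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, m, n_zeros, "normal_approx")


def format_p(p: float, floor: float = 0.01) -> str:
    """Display formatting used in the result tables: '< .01' below the floor."""
    if p < floor:
        return f"< {floor:.2f}".replace("0.", ".")
    return f"{p:.2f}"


def _variant_label(variant: Variant) -> str:
    alg, g = variant
    gtxt = str(int(g)) if float(g).is_integer() else str(g)
    return f"{alg}{gtxt}"


def check_balance(
    cohort: Iterable[PlanDVHSet], required_variants: Sequence[Variant] | None = None
) -> dict[str, dict[Variant, PlanDVHSet]]:
    """Group a cohort by patient and verify every patient has every variant."""
    by_patient: dict[str, dict[Variant, PlanDVHSet]] = {}
    for plan in cohort:
        by_patient.setdefault(plan.patient_id, {})[plan.variant] = plan
    if required_variants is None:
        required = sorted({v for plans in by_patient.values() for v in plans})
    else:
        required = list(required_variants)
    missing = [
        (pid, v)
        for pid, plans in by_patient.items()
        for v in required
        if v not in plans
    ]
    if missing:
        listing = ", ".join(f"({pid}, {_variant_label(v)})" for pid, v in missing)
        raise ValueError(f"unbalanced cohort; missing (patient, variant) pairs: {listing}")
    return by_patient


def comparison_table(
    cohort: Iterable[PlanDVHSet],
    contrasts: Sequence[tuple[Variant, Variant]] | None = None,
    metrics: Sequence[tuple[str, str]] | None = None,
    metric_fn: Callable[[PlanDVHSet, str, str], float] | None = None,
    mode: Literal["exact", "normal_approx", "auto"] = "auto",
    zero_method: Literal["wilcox", "pratt"] = "wilcox",
) -> pd.DataFrame:
    """Matrix of two-sided p-values per (structure, metric) x contrast.

    ``metric_fn(plan, structure, metric_name)`` evaluates one metric on one
    plan; the default covers the dose/index/probability metrics shipped in
    :mod:`planeval.metrics`.  Output is long format with raw p, display p
    ('< .01' below 0.01), degeneracy flag and the median paired difference.
    """
    if metric_fn is None:
        from .metrics import compute_metric

        metric_fn = compute_metric
    if contrasts is None:
        contrasts = DEFAULT_CONTRASTS
    if metrics is None:
        metrics = [("PTV", "median"), ("PTV", "v95")]
    needed = {v for pair in contrasts for v in pair}
    by_patient = check_balance(cohort, sorted(needed))
    patients = sorted(by_patient)
    rows = []
    for structure, metric in metrics:
        for va, vb in contrasts:
            a_vals = np.array([metric_fn(by_patient[p][va], structure, metric) for p in patients])
            b_vals = np.array([metric_fn(by_patient[p][vb], structure, metric) for p in patients])
            sample = PairedSample(_variant_label(va), _variant_label(vb), a_vals, b_vals)
            res = wilcoxon_signed_rank(sample, mode=mode, zero_method=zero_method)
            rows.append({
                "structure": structure,
                "metric": metric,
                "contrast": f"{sample.label_a} vs {sample.label_b}",
                "p_raw": res.p_two_sided,
                "p_display": format_p(res.p_two_sided),
                "degenerate": res.degenerate,
                "n_pairs": sample.n,
                "n_zeros": res.n_zeros,
                "median_paired_diff": float(np.median(sample.differences)),
            })
    return pd.DataFrame(rows)
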