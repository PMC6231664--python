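"""Unit tests for the power-mean EUD and logistic dose-response scores.

The EUD oracle used throughout is an independent extended-precision
(80-bit long double) evaluation of the sum-then-root formula.
"""

import numpy as np
import pytest

from planeval import (
    CumulativeDVH,
    DifferentialDVH,
    ParamRegistry,
    PlanDVHSet,
    RadiobioParams,
    default_registry,
    differential_to_cumulative,
    eqd2_transform,
    eud,
    evaluate_plan_radiobiology,
    ntcp,
    tcp,
)
from planeval.radiobio import structure_radiobiology


def eud_oracle(volumes, doses, a) -> float:
    """Brute-force power mean at extended precision."""
    v = np.asarray(volumes, dtype=np.longdouble)
    d = np.asarray(doses, dtype=np.longdouble)
    v = v / v.sum()
    acc = np.longdouble(0)
    for vi, di in zip(v, d):
        acc += vi * di ** np.longdouble(a)
    return float(acc ** (np.longdouble(1) / np.longdouble(a)))


class TestDefaultRegistry:
    def test_shipped_parameter_rows(self):
        reg = default_registry()
        assert (reg["PTV"].a, reg["PTV"].gamma50, reg["PTV"].d50_ref,
                reg["PTV"].alpha_beta, reg["PTV"].kind) == (-13.0, 2.2, 67.5, 1.5, "tumor")
        assert (reg["Rectum"].a, reg["Rectum"].gamma50, reg["Rectum"].d50_ref,
                reg["Rectum"].alpha_beta) == (8.33, 2.66, 80.0, 5.4)
        assert (reg["Bladder"].a, reg["Bladder"].gamma50, reg["Bladder"].d50_ref,
                reg["Bladder"].alpha_beta) == (2.0, 3.63, 80.0, 7.5)
        for side in ("L", "R"):
            p = reg[f"FemoralHead_{side}"]
            assert (p.a, p.gamma50, p.d50_ref, p.alpha_beta) == (13.0, 2.7, 65.0, 3.0)

    def test_csv_round_trip(self, tmp_path):
        reg = default_registry()
        path = tmp_path / "params.csv"
        reg.to_csv(path)
        back = ParamRegistry.from_csv(path)
        assert back.organs == reg.organs
        for p in reg:
            assert back[p.organ] == p

    def test_duplicate_organ_rejected(self):
        row = RadiobioParams("X", 2.0, 1.0, 50.0, 3.0, "normal")
        with pytest.raises(ValueError, match="duplicate"):
            ParamRegistry([row, row])

    def test_param_validation(self):
        with pytest.raises(ValueError, match="a = 0"):
            RadiobioParams("X", 0.0, 1.0, 50.0, 3.0, "normal")
        with pytest.raises(ValueError, match="gamma50"):
            RadiobioParams("X", 2.0, 0.0, 50.0, 3.0, "normal")
        with pytest.raises(ValueError, match="kind"):
            RadiobioParams("X", 2.0, 1.0, 50.0, 3.0, "other")


class TestEqd2Transform:
    def test_two_gray_per_fraction_fixed_point(self):
        d = DifferentialDVH("x", [78.0], [1.0])
        for ab in (1.5, 5.4, 7.5):
            out = eqd2_transform(d, ab, 39)
            assert out.bin_centers[0] == pytest.approx(78.0)

    def test_hand_arithmetic(self):
        d = DifferentialDVH("x", [40.0], [1.0])
        out = eqd2_transform(d, 5.4, 39)
        assert out.bin_centers[0] == pytest.approx(40.0 * (5.4 + 40.0 / 39.0) / 7.4)
        assert out.bin_centers[0] == pytest.approx(34.73, abs=5e-3)

    def test_large_alpha_beta_limit(self):
        d = DifferentialDVH("x", [40.0, 60.0], [0.5, 0.5])
        out = eqd2_transform(d, 1e9, 39)
        np.testing.assert_allclose(out.bin_centers, d.bin_centers, rtol=1e-6)

    def test_volumes_unchanged(self):
        d = DifferentialDVH("x", [40.0, 60.0], [0.3, 0.7])
        out = eqd2_transform(d, 3.0, 39)
        np.testing.assert_array_equal(out.fractional_volumes, d.fractional_volumes)

    def test_invalid_inputs(self):
        d = DifferentialDVH("x", [40.0], [1.0])
        with pytest.raises(ValueError):
            eqd2_transform(d, 0.0, 39)
        with pytest.raises(ValueError):
            eqd2_transform(d, 3.0, 0)


class TestEud:
    def test_uniform_dose_identity(self):
        for a in (-13.0, -1.0, 1.0, 2.0, 8.33, 13.0):
            d = DifferentialDVH("x", [63.0], [1.0])
            assert eud(d, a) == pytest.approx(63.0, rel=1e-12)

    def test_hand_arithmetic_quadratic_mean(self):
        d = DifferentialDVH("x", [60.0, 80.0], [0.5, 0.5])
        assert eud(d, 2.0) == pytest.approx(np.sqrt(5000.0), rel=1e-12)

    def test_cold_spot_weighted_negative_a(self):
        d = DifferentialDVH("x", [60.0, 80.0], [0.5, 0.5])
        expected = eud_oracle([0.5, 0.5], [60.0, 80.0], -13.0)
        assert eud(d, -13.0) == pytest.approx(expected, rel=1e-12)
        assert 63.0 < eud(d, -13.0) < 64.0  # dominated by the cold spot

    def test_matches_oracle_on_random_dvhs(self):
        rng = np.random.default_rng(21)
        for a in (-13.0, -1.0, 1.0, 2.0, 8.33, 13.0):
            for _ in range(40):
                n = rng.integers(1, 60)
                doses = np.sort(rng.uniform(0.5, 90.0, n))
                doses = np.unique(doses)
                vols = rng.dirichlet(np.ones(doses.size))
                d = DifferentialDVH("x", doses, vols)
                assert eud(d, a) == pytest.approx(
                    eud_oracle(vols, doses, a), rel=1e-10
                )

    def test_bounded_and_monotone(self):
        rng = np.random.default_rng(22)
        for a in (-13.0, -2.0, 1.0, 8.33):
            doses = np.sort(rng.uniform(1, 90, 10))
            vols = rng.dirichlet(np.ones(10))
            d = DifferentialDVH("x", doses, vols)
            e = eud(d, a)
            assert doses.min() - 1e-9 <= e <= doses.max() + 1e-9
            bumped = DifferentialDVH("x", doses + 1.0, vols)
            assert eud(bumped, a) > e

    def test_zero_dose_cold_spot_rejected(self):
        d = DifferentialDVH("x", [0.0, 80.0], [0.1, 0.9])
        with pytest.raises(ValueError, match="singular"):
            eud(d, -13.0)

    def test_negligible_mass_bins_dropped(self):
        d = DifferentialDVH("x", [0.0, 80.0], [1e-12, 1.0 - 1e-12])
        assert eud(d, -13.0) == pytest.approx(80.0, rel=1e-9)

    def test_a_zero_rejected(self):
        d = DifferentialDVH("x", [80.0], [1.0])
        with pytest.raises(ValueError, match="a = 0"):
            eud(d, 0.0)

    def test_bin_width_stability(self):
        # smooth target-like curve (support bounded away from 0, where the
        # a = -13 power mean would be singular); halving bin width moves EUD < 0.1%
        dose = np.linspace(0.0, 85.0, 500)
        frac = 1.0 / (1.0 + np.exp((dose - 74.0) / 3.0))
        frac = np.where(dose <= 55.0, 1.0, frac)
        frac[0] = 1.0
        c = CumulativeDVH("s", 10.0, dose, frac)
        from planeval import cumulative_to_differential

        for a in (-13.0, 2.0, 8.33):
            e1 = eud(cumulative_to_differential(c, 0.1), a)
            e2 = eud(cumulative_to_differential(c, 0.05), a)
            assert abs(e2 - e1) / e1 < 1e-3


class TestSigmoids:
    def test_half_point_fixed_points(self):
        reg = default_registry()
        for p in reg:
            d = DifferentialDVH(p.organ, [p.d50_ref], [1.0])
            e = eud(d, p.a)
            prob = tcp(e, p) if p.kind == "tumor" else ntcp(e, p)
            assert prob == pytest.approx(0.5, abs=1e-12)

    def test_ntcp_scalar_oracle(self):
        reg = default_registry()
        expected = 1.0 / (1.0 + (80.0 / 60.0) ** (4 * 2.66))
        assert ntcp(60.0, reg["Rectum"]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.045, abs=5e-3)

    def test_tcp_scalar_oracle(self):
        reg = default_registry()
        expected = 1.0 / (1.0 + (67.5 / 78.0) ** (4 * 2.2))
        assert tcp(78.0, reg["PTV"]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.781, abs=5e-3)

    def test_limits(self):
        reg = default_registry()
        assert ntcp(1e-6, reg["Rectum"]) < 1e-10
        assert tcp(1e6, reg["PTV"]) > 1.0 - 1e-10

    def test_kind_dispatch_enforced(self):
        reg = default_registry()
        with pytest.raises(ValueError, match="normal-tissue"):
            ntcp(70.0, reg["PTV"])
        with pytest.raises(ValueError, match="tumor"):
            tcp(70.0, reg["Rectum"])

    def test_monotone_in_eud(self):
        reg = default_registry()
        euds = np.linspace(10, 120, 50)
        probs = [ntcp(e, reg["Rectum"]) for e in euds]
        assert np.all(np.diff(probs) > 0)

    def test_normalized_slope_at_half_point(self):
        # d(P)/d(EUD) at EUD = D50 equals gamma50 / D50 (analytic derivative)
        reg = default_registry()
        for p in reg:
            f = tcp if p.kind == "tumor" else ntcp
            h = 1e-6 * p.d50_ref
            slope = (f(p.d50_ref + h, p) - f(p.d50_ref - h, p)) / (2 * h)
            assert slope == pytest.approx(p.gamma50 / p.d50_ref, rel=1e-5)


class TestEvaluatePlan:
    def _plan(self, structures: dict[str, float]) -> PlanDVHSet:
        dvhs = {
            name: differential_to_cumulative(
                DifferentialDVH(name, [dose], [1.0]), total_volume=50.0
            )
            for name, dose in structures.items()
        }
        return PlanDVHSet("p1", "AXB", 1.0, dvhs)

    def test_uniform_80_rectum_is_half_point(self):
        plan = self._plan({"Rectum": 80.0})
        df = evaluate_plan_radiobiology(plan, apply_eqd2=False)
        row = df[df.structure == "Rectum"].iloc[0]
        assert row.ntcp == pytest.approx(0.5, abs=1e-6)
        assert df.attrs["skipped"] == ["PTV", "Bladder", "FemoralHead_L", "FemoralHead_R"]

    def test_determinism(self):
        plan = self._plan({"Rectum": 60.0, "PTV": 78.0, "Bladder": 30.0})
        df1 = evaluate_plan_radiobiology(plan)
        df2 = evaluate_plan_radiobiology(plan)
        assert df1.equals(df2)

    def test_eqd2_noop_at_two_gray_per_fraction(self):
        plan = self._plan({"Rectum": 78.0, "PTV": 78.0})
        on = evaluate_plan_radiobiology(plan, apply_eqd2=True)
        off = evaluate_plan_radiobiology(plan, apply_eqd2=False)
        np.testing.assert_allclose(on.eud_gy.values, off.eud_gy.values, rtol=1e-6)

    def test_eqd2_changes_off_fixed_point_doses(self):
        plan = self._plan({"Rectum": 40.0})
        on = evaluate_plan_radiobiology(plan, apply_eqd2=True)
        off = evaluate_plan_radiobiology(plan, apply_eqd2=False)
        assert on.eud_gy.iloc[0] < off.eud_gy.iloc[0]  # 40 Gy in 39 fx shrinks

    def test_structure_radiobiology_kinds(self, uniform_dvh):
        reg = default_registry()
        res = structure_radiobiology(uniform_dvh, reg["PTV"], 39, apply_eqd2=False)
        assert "tcp" in res and "ntcp" not in res
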