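import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planeval import (
    CumulativeDVH,
    DifferentialDVH,
    PlanDVHSet,
    cumulative_to_differential,
    differential_to_cumulative,
    dose_at_volume,
    dvh_summary,
    v_x_percent,
    volume_at_dose,
)

from conftest import random_cumulative


class TestCumulativeDVHValidation:
    def test_valid_curve_accepted(self, linear_dvh):
        assert linear_dvh.total_volume == 80.0
        assert linear_dvh.max_dose_point == 80.0

    def test_nonmonotone_rejected_with_index(self):
        with pytest.raises(ValueError, match="increases at index 2"):
            CumulativeDVH("x", 1.0, [0.0, 10.0, 20.0], [1.0, 0.4, 0.6])

    def test_must_start_at_zero_dose_full_volume(self):
        with pytest.raises(ValueError, match="start at 0"):
            CumulativeDVH("x", 1.0, [1.0, 10.0], [1.0, 0.0])
        with pytest.raises(ValueError, match="must be 1.0"):
            CumulativeDVH("x", 1.0, [0.0, 10.0], [0.9, 0.0])

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError, match="total_volume"):
            CumulativeDVH("x", 0.0, [0.0, 10.0], [1.0, 0.0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            CumulativeDVH("x", 1.0, [0.0, np.nan], [1.0, 0.0])

    def test_decreasing_dose_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            CumulativeDVH("x", 1.0, [0.0, 10.0, 10.0], [1.0, 0.5, 0.0])


class TestDifferentialDVHValidation:
    def test_sum_to_one_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DifferentialDVH("x", [10.0, 20.0], [0.5, 0.4])

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            DifferentialDVH("x", [10.0, 20.0], [1.1, -0.1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one bin"):
            DifferentialDVH("x", [], [])


class TestPlanDVHSet:
    def test_variant_validation_configurable(self, uniform_dvh):
        plan = PlanDVHSet("p1", "AAA", 2.0, {"PTV": uniform_dvh})
        allowed = {("AAA", 1.0), ("AAA", 3.0), ("AAA", 5.0),
                   ("AXB", 1.0), ("AXB", 2.0), ("AXB", 3.0)}
        with pytest.raises(ValueError, match="not in the allowed set"):
            plan.validate_variant(allowed)
        plan.validate_variant(allowed | {("AAA", 2.0)})

    def test_defaults(self, uniform_dvh):
        plan = PlanDVHSet("p1", "AXB", 1.0, {"PTV": uniform_dvh})
        assert plan.prescription_dose == 78.0
        assert plan.n_fractions == 39
        assert plan.variant_label == "AXB1"


class TestCumulativeToDifferential:
    def test_mass_conservation_step(self):
        # all mass drops in the (78, 80] bin
        c = CumulativeDVH("x", 1.0, [0.0, 78.0, 80.0], [1.0, 1.0, 0.0])
        d = cumulative_to_differential(c, 2.0)
        assert d.fractional_volumes.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.fractional_volumes[-1] == pytest.approx(1.0, abs=1e-12)
        assert d.bin_centers[-1] == pytest.approx(79.0)

    def test_bin_differencing_by_hand(self):
        c = CumulativeDVH("x", 1.0, [0.0, 10.0, 20.0], [1.0, 0.6, 0.0])
        d = cumulative_to_differential(c, 10.0)
        np.testing.assert_allclose(d.bin_centers, [5.0, 15.0])
        np.testing.assert_allclose(d.fractional_volumes, [0.4, 0.6], atol=1e-12)

    def test_residual_mass_goes_to_terminal_bin(self):
        c = CumulativeDVH("x", 1.0, [0.0, 10.0], [1.0, 0.3])
        d = cumulative_to_differential(c, 5.0)
        assert d.fractional_volumes.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_mode_point_masses(self):
        c = CumulativeDVH("x", 1.0, [0.0, 80.0, 80.0 + 1e-9], [1.0, 1.0, 0.0])
        d = cumulative_to_differential(c, None)
        assert d.bin_centers.size == 1
        assert d.bin_centers[0] == pytest.approx(80.0, abs=1e-6)

    def test_bad_bin_width(self, linear_dvh):
        with pytest.raises(ValueError, match="bin_width"):
            cumulative_to_differential(linear_dvh, 0.0)

    def test_round_trip_at_bin_edges(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            c = random_cumulative(rng)
            w = float(rng.uniform(0.05, 4.0))
            d = cumulative_to_differential(c, w)
            c2 = differential_to_cumulative(d, c.total_volume)
            n_bins = d.bin_centers.size
            edges = np.arange(n_bins + 1) * w
            expected = np.interp(np.minimum(edges, c.max_dose_point),
                                 c.dose_gy, c.volume_fraction)
            expected[edges > c.max_dose_point] = 0.0
            got = np.array([volume_at_dose(c2, e) for e in edges])
            # terminal bin absorbs any residual volume above the top edge
            np.testing.assert_allclose(got[:-1], expected[:-1], atol=1e-9)

    def test_sum_is_one_after_every_conversion(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            c = random_cumulative(rng)
            for w in (0.1, 1.0, None):
                d = cumulative_to_differential(c, w)
                assert d.fractional_volumes.sum() == pytest.approx(1.0, abs=1e-9)


class TestDifferentialToCumulative:
    def test_single_bin_step(self):
        c = differential_to_cumulative(DifferentialDVH("x", [78.0], [1.0]))
        assert volume_at_dose(c, 77.0) == pytest.approx(1.0)
        assert volume_at_dose(c, 79.0) == 0.0

    def test_two_bin_hand_summation(self, two_level_ddvh):
        c = differential_to_cumulative(two_level_ddvh)
        # at the bin edges (50, 70, 90): suffix sums 1.0, 0.5, 0.0
        assert volume_at_dose(c, 50.0) == pytest.approx(1.0)
        assert volume_at_dose(c, 70.0) == pytest.approx(0.5)
        assert volume_at_dose(c, 90.0) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            differential_to_cumulative(DifferentialDVH("x", [], []))


class TestDoseAtVolume:
    def test_linear_interpolation_by_hand(self, linear_dvh):
        assert dose_at_volume(linear_dvh, 0.5) == pytest.approx(75.0)

    def test_uniform_dose_identity(self, uniform_dvh):
        for frac in (0.02, 0.5, 0.98):
            assert dose_at_volume(uniform_dvh, frac) == pytest.approx(78.0, abs=1e-5)

    def test_full_volume_minimum_dose_convention(self, linear_dvh):
        assert dose_at_volume(linear_dvh, 1.0) == pytest.approx(70.0)

    def test_fraction_out_of_range(self, linear_dvh):
        for frac in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="fraction"):
                dose_at_volume(linear_dvh, frac)

    def test_flat_segment_tie_resolves_to_lowest_dose(self):
        c = CumulativeDVH("x", 1.0, [0.0, 10.0, 20.0, 30.0], [1.0, 0.5, 0.5, 0.0])
        assert dose_at_volume(c, 0.5) == pytest.approx(10.0)


class TestVolumeAtDose:
    def test_uniform_v95(self, uniform_dvh):
        assert v_x_percent(uniform_dvh, 95.0, 78.0) == pytest.approx(100.0)

    def test_linear_interpolation_v95(self, linear_dvh):
        # evaluated at 74.1 Gy on the 70->80 ramp: (80 - 74.1) / 10 = 59%
        assert v_x_percent(linear_dvh, 95.0, 78.0) == pytest.approx(59.0)

    def test_above_support_returns_zero(self, linear_dvh):
        assert volume_at_dose(linear_dvh, 200.0) == 0.0

    def test_negative_dose_rejected(self, linear_dvh):
        with pytest.raises(ValueError):
            volume_at_dose(linear_dvh, -1.0)

    def test_mutual_inverse_on_strictly_decreasing_segment(self, linear_dvh):
        rng = np.random.default_rng(3)
        for frac in rng.uniform(0.01, 0.99, 25):
            d = dose_at_volume(linear_dvh, frac)
            assert volume_at_dose(linear_dvh, d) == pytest.approx(frac, abs=1e-9)


class TestDvhSummary:
    def test_uniform(self, uniform_dvh):
        s = dvh_summary(uniform_dvh)
        for key in ("min", "max", "mean", "median"):
            assert s[key] == pytest.approx(78.0, abs=1e-5)

    def test_two_level_mean_and_median(self, two_level_ddvh):
        s = dvh_summary(differential_to_cumulative(two_level_ddvh))
        assert s["mean"] == pytest.approx(70.0, abs=1e-9)
        assert s["median"] == pytest.approx(70.0, abs=1e-9)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            CumulativeDVH("x", 1.0, [0.0], [1.0])

    def test_ordering_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            s = dvh_summary(random_cumulative(rng))
            assert s["min"] <= s["median"] <= s["max"]
            assert s["min"] <= s["mean"] <= s["max"]


@st.composite
def monotone_curves(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    incs = draw(st.lists(st.floats(0.1, 10.0), min_size=n, max_size=n))
    drops = draw(st.lists(st.floats(0.0, 1.0), min_size=n, max_size=n))
    dose = np.concatenate([[0.0], np.cumsum(incs)])
    total = sum(drops) or 1.0
    frac = np.concatenate([[1.0], 1.0 - np.cumsum(drops) / total])
    frac = np.clip(frac, 0.0, 1.0)
    return CumulativeDVH("h", 10.0, dose, frac)


@given(curve=monotone_curves(), w=st.floats(0.05, 5.0))
@settings(max_examples=80, deadline=None)
def test_property_conversion_round_trip(curve, w):
    d = cumulative_to_differential(curve, w)
    assert d.fractional_volumes.sum() == pytest.approx(1.0, abs=1e-9)
    c2 = differential_to_cumulative(d, curve.total_volume)
    edges = np.arange(d.bin_centers.size) * w  # interior edges
    expected = np.interp(edges, curve.dose_gy, curve.volume_fraction)
    expected[edges > curve.max_dose_point] = 0.0
    got = np.array([volume_at_dose(c2, e) for e in edges])
    np.testing.assert_allclose(got, expected, atol=1e-9)
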