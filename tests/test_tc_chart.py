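"""Mixture forward model, decision boundaries, classification, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcchart.errors import DomainError, UndefinedRatioError, ValidationError
from tcchart.tc_chart import (
    SamplePoint,
    TCChartConfig,
    TCLabel,
    TumorCellParams,
    boundary_ratio,
    chart_curves,
    classify,
    estimate_b_prime,
    estimate_ba_ratio,
    forward_ratio,
)


class TestForwardRatio:
    def test_pure_stroma_is_unity(self):
        """At x = 0 every mixture is diploid stroma: r = 1 regardless of (A, B)."""
        for a, b in [(2, 4), (8, 1), (4.15, 23.61)]:
            assert forward_ratio(TumorCellParams(a, b), 0.0) == pytest.approx(1.0)

    def test_h522_pure_tumor_matches_dish_ratio(self):
        r = forward_ratio(TumorCellParams(2.05, 4.25), 1.0)
        assert round(r, 2) == 2.07

    def test_skbr3_pure_tumor_matches_dpcr_ratio(self):
        r = forward_ratio(TumorCellParams(4.15, 23.61), 1.0)
        assert round(r, 2) == 5.69

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedRatioError):
            forward_ratio(TumorCellParams(0.0, 4.0), 1.0)

    def test_x_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            forward_ratio(TumorCellParams(2, 4), 1.5)


class TestBoundaryRatio:
    @pytest.mark.parametrize("x", [0.0, 0.25, 0.5, 1.0])
    def test_reduces_to_straight_line_at_a2(self, x):
        assert boundary_ratio(x, 2.0) == pytest.approx(x + 1.0, abs=1e-15)

    def test_a8_midpoint(self):
        assert boundary_ratio(0.5, 8.0) == pytest.approx(1.8)

    @pytest.mark.parametrize("a", [2.0, 3.5, 8.0, 20.0])
    def test_convergence_points_exact(self, a):
        """All iso-curves pass through (0, 1) and (1, 2) exactly."""
        assert boundary_ratio(0.0, a) == 1.0
        assert boundary_ratio(1.0, a) == 2.0

    def test_below_domain_raises(self):
        with pytest.raises(DomainError):
            boundary_ratio(0.5, 1.9)

    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=2.0, max_value=8.0),
        st.floats(min_value=0.0, max_value=6.0),
    )
    def test_monotone_in_a_and_x(self, x, a, da):
        assert boundary_ratio(x, a + da) >= boundary_ratio(x, a) - 1e-12
        x2 = min(1.0, x + 0.01)
        assert boundary_ratio(x2, a) > boundary_ratio(x, a)


class TestClassify:
    @pytest.mark.parametrize(
        "r,x,label",
        [
            (2.38, 0.517, TCLabel.POSITIVE),   # case #29
            (1.10, 0.087, TCLabel.EQUIVOCAL),  # case #8
            (1.39, 0.341, TCLabel.EQUIVOCAL),  # case #1
            (0.90, 0.30, TCLabel.NEGATIVE),    # r < 1 <= x + 1
        ],
    )
    def test_published_and_trivial_calls(self, r, x, label):
        assert classify(SamplePoint(r, x)).label is label

    def test_low_tumor_content_is_undetermined_with_warning(self):
        with pytest.warns(UserWarning, match="below floor"):
            call = classify(SamplePoint(1.5, 0.01))
        assert call.label is TCLabel.UNDETERMINED

    def test_boundary_ties_go_upward(self):
        """r exactly on a boundary takes the less-negative label."""
        x = 0.4
        lo, hi = boundary_ratio(x, 2.0), boundary_ratio(x, 8.0)
        assert classify(SamplePoint(lo, x)).label is TCLabel.EQUIVOCAL
        assert classify(SamplePoint(hi, x)).label is TCLabel.POSITIVE

    def test_regions_partition_the_strip(self):
        """Every (r, x) point above the floor gets exactly one call."""
        rng = np.random.default_rng(7)
        for _ in range(500):
            point = SamplePoint(rng.uniform(0.05, 12.0), rng.uniform(0.05, 1.0))
            assert classify(point).label in (
                TCLabel.NEGATIVE, TCLabel.EQUIVOCAL, TCLabel.POSITIVE
            )

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            TCChartConfig(a_min=1.0)
        with pytest.raises(ValidationError):
            TCChartConfig(a_min=5.0, a_max=3.0)


class TestInversion:
    @pytest.mark.parametrize(
        "r,x,a,expected",
        [
            (28.25, 0.414, 3.2, 52.36),  # case #25
            (1.49, 0.264, 3.0, 2.40),    # case #44
            (2.38, 0.517, 2.4, 3.45),    # case #29
            (1.95, 0.531, 3.1, 2.49),    # case #33
        ],
    )
    def test_published_ba_estimates(self, r, x, a, expected):
        assert round(estimate_ba_ratio(SamplePoint(r, x), a), 2) == expected

    def test_pure_tumor_reduces_to_r(self):
        assert estimate_ba_ratio(SamplePoint(3.7, 1.0), 5.0) == pytest.approx(3.7)

    def test_inversion_at_zero_x_raises(self):
        with pytest.raises(UndefinedRatioError):
            estimate_ba_ratio(SamplePoint(2.0, 0.0), 3.0)

    @pytest.mark.parametrize(
        "r,a,expected",
        [(5.69, 4.15, 23.61), (28.25, 3.2, 90.4), (1.0, 2.0, 2.0)],
    )
    def test_b_prime_products(self, r, a, expected):
        assert round(estimate_b_prime(r, a), 2) == pytest.approx(expected)

    @settings(deadline=None)
    @given(
        st.floats(min_value=0.5, max_value=20.0),
        st.floats(min_value=0.0, max_value=100.0),
        st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_round_trip_identity(self, a, b, x):
        """estimate_ba_ratio inverts forward_ratio exactly (algebraic inverse)."""
        r = forward_ratio(TumorCellParams(a, b), x)
        recovered = estimate_ba_ratio(SamplePoint(max(r, 1e-300), x), a)
        assert recovered == pytest.approx(b / a, rel=1e-9, abs=1e-9)


class TestChartCurves:
    def test_endpoints_and_midpoint(self):
        curves = chart_curves(a_values=[2.0, 8.0], n_points=3)
        a2, a8 = curves.curves["A=2"], curves.curves["A=8"]
        for curve in (a2, a8, curves.negative_boundary, curves.positive_boundary):
            assert curve[0] == pytest.approx(1.0, abs=1e-12)
            assert curve[-1] == pytest.approx(2.0, abs=1e-12)
        assert a8[1] == pytest.approx(1.8)

    def test_table_long_format(self):
        table = chart_curves(n_points=5).to_table()
        assert set(table.columns) == {"x", "r", "curve_label"}
        assert len(table) == 10  # two boundary curves, five points each

    def test_invalid_requests_rejected(self):
        with pytest.raises(DomainError):
            chart_curves(a_values=[1.5])
        with pytest.raises(ValidationError):
            chart_curves(n_points=1)


def test_boundary_theorem_brute_force():
    """No sub-amplified truth (B/A < 2) is ever called POSITIVE and no
    amplified truth (B/A >= 2) is ever called NEGATIVE, across the full
    admissible grid of A, B/A and x."""
    config = TCChartConfig()
    a_grid = np.arange(2.0, 8.0 + 1e-9, 0.5)
    x_grid = np.minimum(np.arange(0.05, 1.0 + 1e-9, 0.01), 1.0)
    ba_below = np.arange(0.1, 1.99 + 1e-9, 0.01)
    ba_above = np.arange(2.0, 10.0 + 1e-9, 0.1)
    for a in a_grid:
        for ba in ba_below:
            params = TumorCellParams(a, ba * a)
            for x in x_grid:
                r = forward_ratio(params, float(x))
                assert classify(SamplePoint(r, float(x)), config).label is not TCLabel.POSITIVE
        for ba in ba_above:
            params = TumorCellParams(a, ba * a)
            for x in x_grid:
                r = forward_ratio(params, float(x))
                call = classify(SamplePoint(r, float(x)), config)
                if call.label is TCLabel.NEGATIVE:
                    # at B/A exactly 2 the float forward ratio can land one
                    # ulp below the boundary; the exact value ties upward
                    assert r == pytest.approx(call.negative_boundary, rel=1e-12)
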