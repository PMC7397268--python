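"""Head-disc geometry, area ratios and OTR aggregation."""

import math

import numpy as np
import pytest

from otrcooper import (BarrelSpec, InfeasibleLayoutError, barrel_otr, body_feasible,
                       body_ratios, element_otr, head_feasible, head_ratios, layout_head)
from otrcooper.geometry import segment_area

from conftest import make_body_stave, make_head_stave

R = 298.5  # default head radius, mm


class TestHeadLayout:
    def test_central_stave_requires_full_diameter(self, uniform_head_staves):
        layout = layout_head(uniform_head_staves[:9])
        assert layout.required_lengths[4] == pytest.approx(597.0)

    def test_required_length_away_from_center(self):
        # interval [0.5R, 0.9R]: nearest point 0.5R -> chord 2R*sqrt(1 - 0.25)
        area_interval = segment_area(0.5 * R, 0.9 * R, R)
        assert area_interval > 0
        from otrcooper.geometry import _required_length
        assert _required_length(0.5 * R, 0.9 * R, R) == pytest.approx(2 * R * math.sqrt(0.75))

    def test_areas_sum_to_disc_area(self, uniform_head_staves):
        layout = layout_head(uniform_head_staves[:9])
        assert layout.total_area_m2 == pytest.approx(math.pi * 0.2985**2, rel=1e-9)

    def test_clipped_edge_stave_required_length(self):
        # nine 67 mm staves: first interval clips to [-298.5, -234.5]
        layout = layout_head([make_head_stave(i, 67.0, 600.0) for i in range(9)])
        expected = 2 * math.sqrt(298.5**2 - 234.5**2)
        assert layout.required_lengths[0] == pytest.approx(expected)
        assert expected == pytest.approx(369.389, abs=0.01)

    def test_narrow_total_width_is_infeasible(self):
        with pytest.raises(InfeasibleLayoutError, match="below the head diameter"):
            layout_head([make_head_stave(i, 60.0, 600.0) for i in range(7)])

    def test_stave_fully_outside_disc_is_infeasible(self):
        staves = [make_head_stave(0, 40.0, 600.0)] + \
                 [make_head_stave(i, 700.0, 600.0) for i in (1, 2)]
        with pytest.raises(InfeasibleLayoutError, match="outside the head disc"):
            layout_head(staves)

    def test_required_length_profile_peaks_at_center(self, rng):
        for _ in range(20):
            k = int(rng.choice([7, 9, 11]))
            widths = rng.uniform(55, 95, size=k)
            if widths.sum() < 600:
                continue
            staves = [make_head_stave(i, w, 700.0) for i, w in enumerate(widths)]
            try:
                layout = layout_head(staves)
            except InfeasibleLayoutError:
                continue
            req = layout.required_lengths
            peak = int(np.argmax(req))
            assert all(req[i] >= req[i + 1] - 1e-9 for i in range(peak, k - 1))
            assert all(req[i + 1] >= req[i] - 1e-9 for i in range(0, peak))

    def test_segment_area_matches_numerical_integration(self, rng):
        for _ in range(200):
            a, b = np.sort(rng.uniform(-R, R, size=2))
            if b - a < 1e-6:
                continue
            xs = np.linspace(a, b, 2001)
            numeric = np.trapezoid(2 * np.sqrt(np.maximum(R**2 - xs**2, 0.0)), xs)
            assert segment_area(a, b, R) == pytest.approx(numeric, rel=1e-5, abs=1e-6)


class TestFeasibility:
    def test_even_stave_count_is_infeasible(self):
        ok, why = head_feasible([make_head_stave(i, 80.0, 600.0) for i in range(8)])
        assert not ok and "count" in why

    def test_nine_wide_long_staves_feasible(self):
        ok, why = head_feasible([make_head_stave(i, 67.0, 600.0) for i in range(9)])
        assert ok, why

    def test_short_edge_stave_infeasible(self):
        staves = [make_head_stave(i, 67.0, 600.0) for i in range(9)]
        staves[0] = make_head_stave(0, 67.0, 300.0)  # required ~369.4 mm
        ok, why = head_feasible(staves)
        assert not ok and "too short" in why

    @pytest.mark.parametrize("widths,expected", [
        ((110.0, 100.0, 90.0), True),    # sum 300, one stave > 100
        ((100.0, 100.0, 100.0), False),  # bung rule is strict
        ((110.0, 100.0, 89.0), False),   # sum 299 outside the window
    ])
    def test_toy_body_rules(self, toy_body_spec, widths, expected):
        staves = [make_body_stave(i, w) for i, w in enumerate(widths)]
        assert body_feasible(staves, toy_body_spec)[0] is expected


class TestRatios:
    def test_body_ratio_values(self):
        staves = [make_body_stave(i, w) for i, w in enumerate([100.0, 50.0, 50.0])]
        ratios = body_ratios(staves)
        assert ratios * 100 == pytest.approx([37.385, 18.6925, 18.6925])

    def test_equal_widths_split_share_evenly(self):
        ratios = body_ratios([70.0] * 10)
        assert np.allclose(ratios, 0.7477 / 10)

    def test_body_ratios_sum_to_share(self, rng):
        for _ in range(20):
            widths = rng.uniform(40, 130, size=rng.integers(5, 40))
            assert body_ratios(widths).sum() == pytest.approx(0.7477, abs=1e-12)

    def test_head_ratio_of_normalizing_area(self):
        spec = BarrelSpec()
        assert spec.head_area_share * 0.28 / spec.head_area_norm == pytest.approx(0.1261)

    def test_half_disc_ratio(self):
        half_disc_m2 = math.pi * 0.2985**2 / 2
        assert 0.1261 * half_disc_m2 / 0.28 * 100 == pytest.approx(6.3033, abs=1e-3)

    def test_full_head_ratios_sum_slightly_below_share(self, uniform_head_staves):
        layout = layout_head(uniform_head_staves[:9])
        total = head_ratios(layout).sum()
        assert total == pytest.approx(0.1261 * math.pi * 0.2985**2 / 0.28, rel=1e-9)
        assert 0.1259 < total < 0.1261  # 0.28 m^2 normalizer exceeds the disc area


class TestElementOTR:
    def test_body_is_width_weighted_mean(self):
        staves = [make_body_stave(0, 70.0, otr=0.02), make_body_stave(1, 70.0, otr=0.04)]
        assert element_otr(staves) == pytest.approx(0.03)

    def test_single_stave_identity(self):
        assert element_otr([make_body_stave(0, 70.0, otr=0.0123)]) == pytest.approx(0.0123)

    def test_body_order_invariance(self, rng):
        widths = rng.uniform(40, 130, size=25)
        otrs = rng.uniform(0.01, 0.06, size=25)
        staves = [make_body_stave(i, w, otr=o) for i, (w, o) in enumerate(zip(widths, otrs))]
        perm = [staves[i] for i in rng.permutation(25)]
        assert element_otr(perm) == pytest.approx(element_otr(staves), rel=1e-12)

    def test_head_order_matters_but_mirror_does_not(self, rng):
        widths = [80, 60, 90, 70, 85, 65, 75, 95, 77]
        otrs = rng.uniform(0.01, 0.06, size=9)
        staves = [make_head_stave(i, float(w), 700.0, otr=float(o))
                  for i, (w, o) in enumerate(zip(widths, otrs))]
        mirrored = list(reversed(staves))
        assert element_otr(mirrored) == pytest.approx(element_otr(staves), rel=1e-12)
        swapped = staves.copy()
        swapped[0], swapped[4] = swapped[4], swapped[0]
        assert element_otr(swapped) != pytest.approx(element_otr(staves), rel=1e-9)

    def test_element_otr_is_convex_combination(self, rng):
        widths = rng.uniform(40, 130, size=30)
        otrs = rng.uniform(0.01, 0.06, size=30)
        staves = [make_body_stave(i, w, otr=o) for i, (w, o) in enumerate(zip(widths, otrs))]
        val = element_otr(staves)
        assert otrs.min() <= val <= otrs.max()


class TestBarrelOTR:
    def test_published_class_means_combine_to_table_value(self):
        val = barrel_otr(0.0165681, 0.0148985, 0.0148985)
        assert val == pytest.approx(0.7477 * 0.0165681 + 0.2522 * 0.0148985)
        assert val == pytest.approx(0.0161454, abs=5e-7)

    def test_equal_elements_scale_by_printed_share_sum(self):
        assert barrel_otr(0.03, 0.03, 0.03) == pytest.approx(0.9999 * 0.03)

    def test_zero_everywhere(self):
        assert barrel_otr(0.0, 0.0, 0.0) == 0.0
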