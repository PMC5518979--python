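"""Section properties, the combined stress field, filtering and the monitor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstress.geometry import polygon_moments, regular_polygon
from gaitstress.stress import (
    LoadState,
    SectionProperties,
    StressTrace,
    bending_stress,
    butterworth_lowpass,
    circular_section,
    compressive_stress,
    hollow_section_from_outline,
    peak_boundary_stress,
    polygon_section_properties,
    stress_fail_monitor,
)

UNIT_SQUARE = np.array([[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]])


class TestSectionProperties:
    def test_unit_square_closed_form(self):
        s = polygon_section_properties(UNIT_SQUARE)
        assert s.area == pytest.approx(1.0, rel=1e-12)
        assert s.ix == pytest.approx(1.0 / 12.0, rel=1e-12)
        assert s.iy == pytest.approx(1.0 / 12.0, rel=1e-12)
        assert s.ixy == pytest.approx(0.0, abs=1e-15)
        assert np.allclose(s.centroid, 0.0)

    def test_orientation_independent(self):
        a = polygon_section_properties(UNIT_SQUARE)
        b = polygon_section_properties(UNIT_SQUARE[::-1])
        assert a.area == pytest.approx(b.area)
        assert a.ix == pytest.approx(b.ix)

    def test_256gon_matches_circle(self):
        R = 0.05
        s = polygon_section_properties(regular_polygon(256, R))
        assert s.area == pytest.approx(np.pi * R**2, rel=1e-3)
        assert s.ix == pytest.approx(np.pi * R**4 / 4.0, rel=1e-3)
        assert s.iy == pytest.approx(s.ix, rel=1e-9)

    def test_rectangle_product_moment_zero_by_symmetry(self):
        rect = np.array([[-2.0, -0.5], [2.0, -0.5], [2.0, 0.5], [-2.0, 0.5]])
        s = polygon_section_properties(rect)
        assert abs(s.ixy) < 1e-12 * s.ix

    def test_self_intersecting_rejected(self):
        bow = np.array([[0, 0], [1, 1], [1, 0], [0, 1]])
        with pytest.raises(ValueError):
            polygon_section_properties(bow)

    @given(st.integers(3, 12), st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_regular_polygons_symmetric(self, n, r):
        s = polygon_section_properties(regular_polygon(n, r))
        assert s.ixy == pytest.approx(0.0, abs=1e-9 * s.ix)
        assert s.ix == pytest.approx(s.iy, rel=1e-9)


class TestHollowSections:
    def test_hollow_circle_closed_form_femur_fraction(self):
        # 38% cortical wall of a 5 cm mean radius: inner radius 3.1 cm
        R, frac = 0.05, 0.38
        ri = (1 - frac) * R
        s = circular_section(R, frac)
        assert s.area == pytest.approx(np.pi * (R**2 - ri**2), rel=1e-3)
        assert s.ix == pytest.approx(np.pi / 4 * (R**4 - ri**4), rel=1e-3)
        assert s.inner_boundary is not None

    def test_fraction_one_is_solid(self):
        R = 0.03
        hollow = circular_section(R, 1.0)
        solid = polygon_section_properties(regular_polygon(256, R))
        assert hollow.area == pytest.approx(solid.area, rel=1e-12)
        assert hollow.inner_boundary is None

    def test_fibula_like_nearly_solid(self):
        # a 96% wall leaves almost no medullary cavity
        s96 = circular_section(0.01, 0.96)
        solid = circular_section(0.01, 1.0)
        assert s96.area == pytest.approx(solid.area, rel=0.01)

    def test_additivity_solid_equals_hollow_plus_plug(self):
        R, frac = 0.04, 0.4
        hollow = circular_section(R, frac)
        inner_poly = hollow.inner_boundary + hollow.centroid
        plug = polygon_section_properties(inner_poly)
        solid = polygon_section_properties(
            hollow.outer_boundary + hollow.centroid
        )
        assert hollow.area + plug.area == pytest.approx(solid.area, rel=1e-9)
        assert hollow.ix + plug.ix == pytest.approx(solid.ix, rel=1e-9)
        assert hollow.iy + plug.iy == pytest.approx(solid.iy, rel=1e-9)
        assert hollow.ixy + plug.ixy == pytest.approx(solid.ixy, abs=1e-9 * solid.ix)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            hollow_section_from_outline(regular_polygon(32, 0.05), 0.0)
        with pytest.raises(ValueError):
            hollow_section_from_outline(regular_polygon(32, 0.05), 1.5)


class TestStressField:
    def test_compressive_stress_is_force_over_area(self):
        s = SectionProperties(0.005, 1e-5, 1e-5, 0.0, np.zeros(2), UNIT_SQUARE)
        assert compressive_stress(LoadState(axial_force=1e4), s) == pytest.approx(2e6)
        assert compressive_stress(LoadState(), s) == 0.0

    def test_symmetric_bending_reduces_to_m_y_over_i(self):
        s = SectionProperties(0.005, 1e-5, 2e-5, 0.0, np.zeros(2), UNIT_SQUARE)
        load = LoadState(moment_x=1000.0)
        assert bending_stress(load, s, (0.0, 0.05)) == pytest.approx(5e6)
        assert bending_stress(load, s, (0.0, 0.0)) == 0.0
        assert bending_stress(load, s, (0.123, 0.0)) == 0.0

    def test_asymmetric_formula_as_printed(self):
        # cross-check the full product-moment expression term by term
        s = SectionProperties(1.0, 3e-5, 2e-5, 1e-5, np.zeros(2), UNIT_SQUARE)
        mx, my, x, y = 700.0, -300.0, 0.01, -0.02
        d = s.ix * s.iy - s.ixy**2
        expected = (mx * s.iy + my * s.ixy) / d * y - (my * s.ix + mx * s.ixy) / d * x
        got = bending_stress(LoadState(0.0, mx, my), s, (x, y))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_bending_integrates_to_zero_over_section(self):
        # no net axial force from pure bending (centroidal axes)
        from shapely.geometry import Point, Polygon

        tri = np.array([[0.0, 0.0], [0.1, 0.0], [0.02, 0.08]])
        s = polygon_section_properties(tri)
        poly = Polygon(s.outer_boundary)
        xs = np.linspace(-0.06, 0.08, 120)
        ys = np.linspace(-0.06, 0.08, 120)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        inside = np.array([poly.contains(Point(p)) for p in pts])
        sig = bending_stress(LoadState(0.0, 500.0, 200.0), s, pts[inside])
        scale = np.abs(sig).max()
        assert abs(sig.mean()) < 5e-2 * scale

    def test_peak_hollow_circle_pure_bending(self):
        R, frac, M = 0.05, 0.38, 2000.0
        s = circular_section(R, frac)
        mx, mn, pmax, _ = peak_boundary_stress(LoadState(0.0, M, 0.0), s)
        expected = M * R / s.ix
        assert mx == pytest.approx(expected, rel=1e-3)
        assert mn == pytest.approx(-expected, rel=1e-3)
        assert abs(pmax[1]) == pytest.approx(R, rel=1e-3)

    def test_pure_axial_uniform_field(self):
        s = circular_section(0.05, 1.0)
        mx, mn, *_ = peak_boundary_stress(LoadState(axial_force=5e3), s)
        assert mx == pytest.approx(5e3 / s.area)
        assert mn == pytest.approx(mx)

    def test_bending_plus_compression_superposition(self):
        # max + min = 2 F/A flags bending-dominated loading symmetry
        s = circular_section(0.05, 0.38)
        load = LoadState(axial_force=-8e3, moment_x=1500.0)
        mx, mn, *_ = peak_boundary_stress(load, s)
        assert mx + mn == pytest.approx(2 * load.axial_force / s.area, rel=1e-6)

    @pytest.mark.parametrize("phi", [0.3, 1.2, -2.4])
    def test_peak_invariant_under_joint_rotation(self, phi):
        tri = np.array([[0.0, 0.0], [0.1, 0.0], [0.02, 0.08]])
        s = polygon_section_properties(tri)
        load = LoadState(0.0, 900.0, -400.0)
        m0 = peak_boundary_stress(load, s)[0]
        c, sn = np.cos(phi), np.sin(phi)
        rot = np.array([[c, -sn], [sn, c]])
        s2 = polygon_section_properties(tri @ rot.T)
        load2 = LoadState(
            0.0,
            c * load.moment_x - sn * load.moment_y,
            sn * load.moment_x + c * load.moment_y,
        )
        assert peak_boundary_stress(load2, s2)[0] == pytest.approx(m0, rel=1e-6)

    def test_peak_monotone_in_moment_magnitude(self):
        s = circular_section(0.04, 0.5)
        peaks = [
            peak_boundary_stress(LoadState(-2e3, m, 0.0), s)[0]
            for m in [0.0, 100.0, 400.0, 1600.0]
        ]
        assert np.all(np.diff(peaks) >= 0)


class TestButterworth:
    def test_dc_gain_unity(self):
        x = np.full(500, 3.7)
        y = butterworth_lowpass(x, sample_rate=500.0)
        assert np.allclose(y, 3.7, rtol=1e-9)

    def test_zero_in_zero_out(self):
        assert np.allclose(butterworth_lowpass(np.zeros(100), 200.0), 0.0)

    def test_minus_3db_at_cutoff(self):
        fs, fc = 1000.0, 5.0
        t = np.arange(0, 20.0, 1 / fs)
        y = butterworth_lowpass(np.sin(2 * np.pi * fc * t), fs, cutoff=fc)
        amp = np.abs(y[int(10 * fs):]).max()
        assert amp == pytest.approx(2.0 ** -0.5, rel=0.01)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        s1, s2 = rng.normal(size=400), rng.normal(size=400)
        a, b = 2.5, -1.3
        lhs = butterworth_lowpass(a * s1 + b * s2, 200.0)
        rhs = a * butterworth_lowpass(s1, 200.0) + b * butterworth_lowpass(s2, 200.0)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butterworth_lowpass(np.zeros(10), sample_rate=8.0, cutoff=5.0)

    def test_zero_phase_mode_has_no_lag(self):
        fs = 200.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 0.5 * t)
        y = butterworth_lowpass(x, fs, zero_phase=True)
        assert np.argmax(y[: int(fs)]) == pytest.approx(np.argmax(x[: int(fs)]), abs=2)


class TestFailMonitor:
    def _trace(self, values, limit=np.inf):
        t = np.arange(len(values)) * 0.01
        v = np.asarray(values, dtype=float)
        return StressTrace("femur", t, v, -v, v, -v, limit)

    def test_all_below_limit_passes(self):
        assert stress_fail_monitor([self._trace([1e6] * 10)], 1e8) is None

    def test_first_crossing_reported(self):
        vals = np.concatenate([np.full(80, 1e6), np.full(20, 3e8)])
        fail = stress_fail_monitor([self._trace(vals)], 1e8)
        assert fail is not None
        assert fail.bone == "femur"
        assert fail.time == pytest.approx(0.80)

    def test_magnitude_uses_both_extremes(self):
        t = np.arange(5) * 0.01
        z = np.zeros(5)
        big_min = StressTrace("tibia", t, z, np.full(5, -2e8), z, np.full(5, -2e8))
        fail = stress_fail_monitor([big_min], 1e8)
        assert fail is not None and fail.time == 0.0
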