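"""Wetting thermodynamics: fillet geometry, phase energies, phase separation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tensioncoat import wetting as w

PI = math.pi
ALC0 = 1.0 - PI / 4.0  # critical saturation at theta = 0


class TestWettingSystem:
    @pytest.mark.parametrize(
        "theta, g_sl, g_s",
        [(0.0, 0.0, 1.0), (PI / 2, 0.5, 0.5), (PI / 3, 1.0, 1.5)],
    )
    def test_young_closure(self, theta, g_sl, g_s):
        system = w.make_system(theta, g_sl)
        assert system.gamma_s_ratio == pytest.approx(g_s, abs=1e-12)

    def test_rejects_out_of_range_theta(self):
        with pytest.raises(ValueError):
            w.make_system(-0.1)
        with pytest.raises(ValueError):
            w.make_system(PI)

    def test_rejects_broken_young_closure(self):
        with pytest.raises(ValueError, match="Young"):
            w.WettingSystem(theta=0.0, gamma_sl_ratio=0.0, gamma_s_ratio=0.5)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        theta=st.floats(0.0, PI - 1e-9, exclude_max=True),
        g_sl=st.floats(-2.0, 2.0),
    )
    def test_young_closure_property(self, theta, g_sl):
        system = w.make_system(theta, g_sl)
        resid = system.gamma_s_ratio - system.gamma_sl_ratio - math.cos(system.theta)
        assert abs(resid) <= 1e-12


class TestFilletGeometry:
    def test_zero_contact_angle_is_square_minus_quarter_disk(self):
        state = w.fillet_geometry(1.0, 0.0)
        assert state.area == pytest.approx(1.0 - PI / 4.0, abs=1e-12)
        assert state.x0 == pytest.approx(1.0, abs=1e-12)
        assert state.arc_angle == pytest.approx(PI / 2.0, abs=1e-12)

    def test_ninety_degrees_is_quarter_disk_at_corner(self):
        state = w.fillet_geometry(1.0, PI / 2.0)
        assert state.area == pytest.approx(PI / 4.0, abs=1e-12)
        assert state.x0 == pytest.approx(1.0, abs=1e-12)
        assert state.arc_angle == pytest.approx(-PI / 2.0, abs=1e-12)

    def test_straight_interface_limit_shape_ratio(self):
        # at 45 deg the meniscus is straight: the fillet is a right isoceles
        # triangle, so area/x0^2 -> 1/2 (a finite arc radius degenerates)
        assert w.fillet_shape_ratio(PI / 4.0) == pytest.approx(0.5, abs=1e-12)
        near = w.fillet_geometry(1.0, PI / 4.0 - 1e-6)
        assert near.area / near.x0**2 == pytest.approx(0.5, rel=1e-5)

    def test_rejects_degenerate_angles(self):
        with pytest.raises(ValueError):
            w.fillet_geometry(1.0, 3.0 * PI / 4.0)
        with pytest.raises(ValueError):
            w.fillet_geometry(-1.0, 0.1)

    def test_flags_extrapolated_angles(self):
        with pytest.warns(UserWarning, match="105"):
            w.fillet_geometry(1.0, math.radians(120.0))

    @pytest.mark.parametrize("theta_deg", [0, 15, 30, 45, 60, 75, 90, 105])
    @pytest.mark.parametrize("r", [0.1, 1.0, 3.0])
    def test_closed_form_matches_polygon_oracle(self, theta_deg, r):
        theta = math.radians(theta_deg)
        state = w.fillet_geometry(r, theta)
        oracle = w.fillet_area_polygon(r, theta, n_segments=120_000)
        if theta_deg == 45:  # degenerate zero-area fillet
            assert abs(state.area - oracle) <= 1e-4 * r * r
        else:
            assert state.area == pytest.approx(oracle, rel=1e-4)

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(
        theta=st.floats(0.0, math.radians(130.0)).filter(
            lambda t: abs(t - PI / 4.0) > 1e-3
        ),
        r=st.floats(0.1, 3.0),
    )
    def test_oracle_equivalence_property(self, theta, r):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = w.fillet_geometry(r, theta)
            oracle = w.fillet_area_polygon(r, theta, n_segments=20_000)
        assert state.area == pytest.approx(oracle, rel=1e-3, abs=1e-9 * r * r)


class TestCriticalSaturation:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (0.0, ALC0),  # prints as 0.215
            (PI / 4.0, 0.5),
            (PI / 2.0, PI / 4.0),
        ],
    )
    def test_reference_values(self, theta, expected):
        assert w.critical_saturation(theta) == pytest.approx(expected, abs=1e-12)

    def test_touching_fillets_define_the_critical_radius(self):
        # alpha_Lc equals 4*area/l^2 evaluated where 2*x0 = l
        for theta in (0.0, math.radians(30.0), math.radians(70.0)):
            l = 1.0
            state_unit = w.fillet_geometry(1.0, theta)
            r_star = (l / 2.0) / state_unit.x0
            touching = w.fillet_geometry(r_star, theta)
            assert 4.0 * touching.area / l**2 == pytest.approx(
                w.critical_saturation(theta), rel=1e-12
            )

    def test_saturates_at_unity_above_114_degrees(self):
        # fillets can no longer touch before the cell fills completely
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert w.critical_saturation(math.radians(114.0)) < 1.0
            assert w.critical_saturation(math.radians(114.2)) == 1.0


class TestPhaseEnergies:
    def test_phase1_printed_form_at_theta_zero(self):
        system = w.make_system(0.0, 0.0)
        assert w.reduced_energy_phase1(0.0, system) == pytest.approx(4.0, abs=1e-12)
        assert w.reduced_energy_phase1(ALC0, system) == pytest.approx(PI, abs=1e-12)
        # direct evaluation of the theta=0 closed form at alpha = 0.05
        assert w.reduced_energy_phase1(0.05, system) == pytest.approx(
            4.0 - (8.0 - 2.0 * PI) * math.sqrt(0.05 / (4.0 - PI)), abs=1e-12
        )
        assert w.reduced_energy_phase1(0.05, system) == pytest.approx(
            3.585655373774389, abs=1e-12
        )

    def test_theta_zero_reduction_recovers_printed_coefficients(self):
        # assembled general-theta energy == 4(1+g_sl) - (8-2pi) sqrt(a/(4-pi))
        system = w.make_system(0.0, 0.7)
        alphas = np.linspace(0.0, ALC0, 57)
        assembled = w.reduced_energy_phase1(alphas, system)
        printed = 4.0 * (1.0 + 0.7) - (8.0 - 2.0 * PI) * np.sqrt(alphas / (4.0 - PI))
        np.testing.assert_allclose(assembled, printed, atol=1e-12)

    def test_phase1_rejects_saturation_beyond_critical(self):
        system = w.make_system(0.0, 0.0)
        with pytest.raises(ValueError, match="critical_saturation"):
            w.reduced_energy_phase1(0.5, system)

    @pytest.mark.parametrize(
        "alpha, g_sl, expected",
        [(1.0, 0.0, 0.0), (0.0, 0.0, 2.0 * math.sqrt(PI)), (ALC0, 0.0, PI)],
    )
    def test_phase2_reference_values(self, alpha, g_sl, expected):
        system = w.make_system(0.0, g_sl)
        assert w.reduced_energy_phase2(alpha, system) == pytest.approx(
            expected, abs=1e-12
        )

    def test_phase2_independent_of_contact_angle(self):
        alphas = np.linspace(0.0, 1.0, 11)
        g_sl = 0.4
        reference = w.reduced_energy_phase2(alphas, w.make_system(0.0, g_sl))
        for deg in (15, 30, 45, 60, 75, 90, 105):
            other = w.reduced_energy_phase2(
                alphas, w.make_system(math.radians(deg), g_sl)
            )
            assert np.array_equal(reference, other)

    def test_continuity_at_critical_saturation(self):
        for g_sl in (0.0, 0.3, 1.2):
            system = w.make_system(0.0, g_sl)
            f1 = w.reduced_energy_phase1(ALC0, system)
            f2 = w.reduced_energy_phase2(ALC0, system)
            assert f1 == pytest.approx(f2, abs=1e-9)
            assert f1 == pytest.approx(4.0 * g_sl + PI, abs=1e-9)

    def test_monotonic_decrease_at_theta_zero(self):
        system = w.make_system(0.0, 0.0)
        a1 = np.linspace(1e-6, ALC0, 200)
        f1 = w.reduced_energy_phase1(a1, system)
        assert np.all(np.diff(f1) < 0)
        a2 = np.linspace(ALC0, 1.0, 200)
        f2 = w.reduced_energy_phase2(a2, system)
        assert np.all(np.diff(f2) < 0)


class TestEnergyCurve:
    def test_endpoint_values_and_exact_critical_point(self):
        system = w.make_system(0.0, 0.0)
        curve = w.energy_curve(system, 101)
        assert curve.saturations[0] == 0.0 and curve.saturations[-1] == 1.0
        assert np.any(curve.saturations == curve.alpha_lc)
        assert curve.reduced_energy[0] == pytest.approx(4.0, abs=1e-12)
        at_crit = curve.reduced_energy[curve.saturations == curve.alpha_lc][0]
        assert at_crit == pytest.approx(PI, abs=1e-12)
        assert curve.reduced_energy[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(curve.saturations) > 0)

    def test_phase_labels_split_at_critical_saturation(self):
        curve = w.energy_curve(w.make_system(0.0, 0.0), 10)
        in_phase1 = curve.saturations <= curve.alpha_lc
        assert np.all(curve.phase_label[in_phase1] == "I")
        assert np.all(curve.phase_label[~in_phase1] == "II")

    def test_rejects_tiny_grids(self):
        with pytest.raises(ValueError):
            w.energy_curve(w.make_system(0.0, 0.0), 9)


def _brute_force_lower_hull(points):
    """Monotone-chain lower convex hull; returns its vertices in order."""
    pts = sorted(map(tuple, points))
    hull = []
    for p in pts:
        # keep left (counter-clockwise) turns only: pop while the last two
        # hull points and p do not turn left
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            if (x2 - x1) * (p[1] - y1) - (y2 - y1) * (p[0] - x1) > 0:
                break
            hull.pop()
        hull.append(p)
    return hull


class TestPhaseSeparation:
    def test_separation_detected_with_inflection_at_critical_saturation(self):
        curve = w.energy_curve(w.make_system(0.0, 0.0), 2001)
        result = w.detect_phase_separation(curve)
        assert result.is_separating
        assert result.inflection_at == pytest.approx(ALC0, abs=1e-3)

    def test_coexistence_window_spans_critical_to_full(self):
        curve = w.energy_curve(w.make_system(0.0, 0.0), 10_001)
        result = w.detect_phase_separation(curve)
        assert result.coexist_lo == pytest.approx(ALC0, abs=1e-3)
        assert result.coexist_hi == pytest.approx(1.0, abs=1e-3)
        assert result.coexist_lo < result.coexist_hi <= 1.0

    def test_matches_brute_force_hull_beyond_the_inflection(self):
        curve = w.energy_curve(w.make_system(0.0, 0.0), 10_001)
        result = w.detect_phase_separation(curve)
        mask = curve.saturations >= result.coexist_lo - 1e-12
        hull = _brute_force_lower_hull(
            np.column_stack((curve.saturations[mask], curve.reduced_energy[mask]))
        )
        # the concave branch collapses onto a single chord: the hull of the
        # coexistence region is just its two endpoints
        assert hull[0][0] == pytest.approx(result.coexist_lo, abs=1e-3)
        assert hull[1][0] == pytest.approx(result.coexist_hi, abs=1e-3)

    def test_rejects_coarse_curves(self):
        curve = w.energy_curve(w.make_system(0.0, 0.0), 20)
        with pytest.raises(ValueError, match="n_points"):
            w.detect_phase_separation(curve)


class TestCoatability:
    @pytest.mark.parametrize(
        "deg, verdict",
        [(60.0, "favorable"), (90.0, "neutral"), (120.0, "unfavorable")],
    )
    def test_verdicts(self, deg, verdict):
        system = w.make_system(math.radians(deg), 0.2)
        assert w.coatability(system).value == verdict

    def test_empty_vs_filled_energy_difference_is_four_cos_theta(self):
        import warnings

        for deg in (10.0, 50.0, 100.0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                system = w.make_system(math.radians(deg), 0.3)
                empty = w.reduced_energy_phase1(0.0, system)
            filled = w.reduced_energy_phase2(1.0, system)
            assert empty - filled == pytest.approx(
                4.0 * math.cos(system.theta), abs=1e-12
            )
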