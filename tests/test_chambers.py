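"""Simpson's-rule volumes, LA landmarks, LA and LV function parameters."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vesselpulse.chambers import (
    LandmarkError,
    VolumeCurve,
    la_function,
    la_landmarks,
    lv_function,
    simpson_volume,
    volume_curve,
)
from vesselpulse.contours import contours_from_polygons
from vesselpulse.phantoms import (
    EllipsoidStackSpec,
    la_volume_profile,
    make_ellipsoid_stack,
)

ELLIPSOID_ML = 4.0 / 3.0 * np.pi * 20 * 20 * 30 / 1000.0  # ~50.265


def square(side, cx=0.0, cy=0.0):
    h = side / 2.0
    return [(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)]


class TestSimpsonVolume:
    def test_uniform_stack(self):
        recs = [("LA", i, 0, square(10.0)) for i in range(5)]  # 5 x 100 mm^2
        cs = contours_from_polygons(recs, slice_thickness=6.0)
        assert simpson_volume(cs, "LA", 0) == pytest.approx(3.0)

    @pytest.mark.parametrize("thickness, tol", [(6.0, 0.05), (1.0, 0.01)])
    def test_ellipsoid_convergence(self, thickness, tol):
        stack = make_ellipsoid_stack(
            EllipsoidStackSpec(semi_axes=(20, 20, 30), slice_thickness=thickness)
        )
        v = simpson_volume(stack.contours, "LA", 0)
        assert v == pytest.approx(ELLIPSOID_ML, rel=tol)
        assert stack.analytic_volumes_ml[0] == pytest.approx(ELLIPSOID_ML, rel=1e-12)

    def test_convergence_order_at_least_one(self):
        errs = []
        for th in (8.0, 4.0, 2.0):
            stack = make_ellipsoid_stack(
                EllipsoidStackSpec(semi_axes=(20, 20, 30), slice_thickness=th)
            )
            errs.append(abs(simpson_volume(stack.contours, "LA", 0) - ELLIPSOID_ML))
        # halving the thickness should at least halve the error
        assert errs[1] <= errs[0] / 2.0 * 1.1
        assert errs[2] <= errs[1] / 2.0 * 1.1

    def test_degenerate_short_ellipsoid_emits_centre_slice(self):
        stack = make_ellipsoid_stack(
            EllipsoidStackSpec(semi_axes=(20, 20, 2.0), slice_thickness=6.0)
        )
        assert stack.contours.data["slice_index"].nunique() == 1

    def test_missing_phase_is_error_not_zero(self):
        recs = [("LA", 0, 0, square(10.0))]
        cs = contours_from_polygons(recs, slice_thickness=6.0)
        with pytest.raises(KeyError):
            simpson_volume(cs, "LA", 3)

    def test_additive_over_slice_subsets(self):
        recs = [("LA", i, 0, square(10.0 + i)) for i in range(6)]
        cs = contours_from_polygons(recs, 6.0)
        lower = contours_from_polygons(
            [("LA", i, 0, square(10.0 + i)) for i in range(3)], 6.0
        )
        upper = contours_from_polygons(
            [("LA", i, 0, square(10.0 + i)) for i in range(3, 6)], 6.0
        )
        assert simpson_volume(cs, "LA", 0) == pytest.approx(
            simpson_volume(lower, "LA", 0) + simpson_volume(upper, "LA", 0)
        )

    def test_cubic_scaling(self):
        k = 1.7
        base = make_ellipsoid_stack(
            EllipsoidStackSpec(semi_axes=(15, 15, 24), slice_thickness=3.0)
        )
        scaled = make_ellipsoid_stack(
            EllipsoidStackSpec(semi_axes=(15 * k, 15 * k, 24 * k), slice_thickness=3.0 * k)
        )
        assert simpson_volume(scaled.contours, "LA", 0) == pytest.approx(
            k**3 * simpson_volume(base.contours, "LA", 0), rel=1e-9
        )

    def test_inconsistent_thickness_rejected_on_merge(self):
        from vesselpulse.contours import concat_contour_sets

        a = contours_from_polygons([("LA", 0, 0, square(10.0))], 6.0)
        b = contours_from_polygons([("LA", 1, 0, square(10.0))], 8.0)
        with pytest.raises(ValueError, match="inconsistent slice thickness"):
            concat_contour_sets([a, b])


class TestLaLandmarks:
    def test_canonical_biphasic_curve_exact(self):
        vols, (pm, pa, pn) = la_volume_profile(80.0, 55.0, 40.0, 25)
        lm = la_landmarks(VolumeCurve("LA", vols, 6.0))
        assert (lm.phase_max, lm.phase_ac, lm.phase_min) == (pm, pa, pn)
        assert not lm.ac_fallback

    def test_no_kick_plateau_fallback_matches_brute_force(self):
        """Without an atrial-kick shoulder the minimal-downslope rule fires."""
        n = 25
        pm, pn = 10, 23
        v = np.empty(n)
        v[: pm + 1] = 45.0 + 35.0 * np.sin(np.pi / 2 * np.arange(pm + 1) / pm)
        # strictly decreasing, flattest in the middle of the descent
        t = np.linspace(0.0, 1.0, pn - pm + 1)
        v[pm : pn + 1] = 80.0 - 40.0 * (t + 0.4 * (t - 0.5) ** 3 - 0.4 * (-0.5) ** 3)
        v[pn + 1 :] = v[pn] + 2.0
        lm = la_landmarks(VolumeCurve("LA", v, 6.0))
        assert lm.ac_fallback
        # independent brute-force scan for the minimal-|downslope| phase
        mid = pm + (pn - pm) // 2
        cands = range(max(pm + 1, mid), pn)
        expected = min(cands, key=lambda i: abs(v[i + 1] - v[i]))
        assert lm.phase_ac == expected

    def test_time_reversed_curve_rejected(self):
        vols, _ = la_volume_profile(80.0, 55.0, 40.0, 25)
        with pytest.raises(LandmarkError, match="no atrial cycle"):
            la_landmarks(VolumeCurve("LA", vols[::-1].copy(), 6.0))

    def test_monotone_curve_rejected(self):
        with pytest.raises(LandmarkError):
            la_landmarks(VolumeCurve("LA", np.linspace(40, 80, 25), 6.0))

    def test_constant_curve_rejected(self):
        with pytest.raises(LandmarkError):
            la_landmarks(VolumeCurve("LA", np.full(25, 50.0), 6.0))


class TestLaFunction:
    def test_printed_patient_contractile_volume(self):
        """V_Contractile from the patient group means: 32.3 - 24.6 = 7.7 ml/m^2."""
        f = la_function(47.5, 32.3, 24.6, bsa=1.0)
        assert f.v_contractile == pytest.approx(7.7, abs=1e-9)

    def test_printed_control_contractile_volume(self):
        f = la_function(43.2, 27.4, 20.9, bsa=1.0)
        assert f.v_contractile == pytest.approx(6.5, abs=1e-9)

    def test_motionless_atrium(self):
        f = la_function(50.0, 50.0, 50.0, bsa=1.0)
        assert f.total_emptying == f.v_passive == f.v_contractile == 0.0
        assert f.laef_passive == f.laef_contractile == f.laef_reservoir == 0.0

    def test_bsa_indexing(self):
        f = la_function(80.0, 55.0, 40.0, bsa=2.0)
        assert f.vol_max == pytest.approx(40.0)
        # fractions unchanged by indexing
        g = la_function(80.0, 55.0, 40.0, bsa=1.0)
        assert f.laef_reservoir == pytest.approx(g.laef_reservoir)

    @given(
        vol_max=st.floats(1.0, 300.0),
        f_ac=st.floats(0.0, 1.0),
        f_min=st.floats(0.0, 1.0),
    )
    def test_reservoir_identity_and_volume_split(self, vol_max, f_ac, f_min):
        """LAEF_Reservoir = 1 - (1-LAEF_Passive)(1-LAEF_Contractile), exactly."""
        vol_ac = vol_max * f_ac
        vol_min = vol_ac * f_min
        f = la_function(vol_max, vol_ac, vol_min, bsa=1.3)
        lhs = f.laef_reservoir / 100.0
        rhs = 1.0 - (1.0 - f.laef_passive / 100.0) * (1.0 - f.laef_contractile / 100.0)
        assert lhs == pytest.approx(rhs, abs=1e-12)
        assert f.total_emptying == f.v_passive + f.v_contractile

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            la_function(40.0, 50.0, 30.0, bsa=1.0)


class TestLvFunction:
    def test_printed_stroke_volume(self):
        """LVSV from the patient group means: 81.0 - 30.4 = 50.6 ml/m^2."""
        f = lv_function(81.0, 30.4, 81.0, bsa=1.0)
        assert f.sv == pytest.approx(50.6, abs=1e-9)

    def test_zero_stroke_volume(self):
        f = lv_function(50.0, 50.0, 60.0, bsa=1.0)
        assert f.sv == 0.0
        assert f.ef == 0.0

    def test_shell_mass_against_closed_form(self):
        """Epi-endo ellipsoid shell: mass within 5 % of 1.05 x shell volume."""
        a, c, wall = 20.0, 30.0, 2.0
        endo = make_ellipsoid_stack(
            EllipsoidStackSpec(semi_axes=(a, a, c), slice_thickness=1.0, structure="LV-endo")
        )
        epi = make_ellipsoid_stack(
            EllipsoidStackSpec(
                semi_axes=(a + wall, a + wall, c + wall), slice_thickness=1.0,
                structure="LV-epi",
            )
        )
        endo_ml = simpson_volume(endo.contours, "LV-endo", 0)
        epi_ml = simpson_volume(epi.contours, "LV-epi", 0)
        f = lv_function(endo_ml, 0.4 * endo_ml, epi_ml, bsa=1.0)
        shell_ml = 4.0 / 3.0 * np.pi * ((a + wall) ** 2 * (c + wall) - a**2 * c) / 1000.0
        assert f.mass == pytest.approx(1.05 * shell_ml, rel=0.05)

    def test_volume_curve_helper(self):
        stack = make_ellipsoid_stack(
            EllipsoidStackSpec(
                semi_axes=(20, 20, 30), slice_thickness=6.0, phases=3,
                volume_time_profile=np.array([1.0, 0.8, 0.9]),
            )
        )
        vc = volume_curve(stack.contours, "LA")
        assert vc.volumes.shape == (3,)
        assert np.argmax(vc.volumes) == 0
        assert np.argmin(vc.volumes) == 1
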