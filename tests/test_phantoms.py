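"""Synthetic generators: reproducibility, ground-truth round trips, cohorts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from vesselpulse.lumen import BloodPressure, area_extremes, distensibility
from vesselpulse.phantoms import (
    CohortSpec,
    EllipsoidStackSpec,
    LumenPulsationSpec,
    WaveformSpec,
    default_cohort_spec,
    draw_cohort_parameters,
    make_area_curve,
    make_cohort,
    make_ellipsoid_stack,
    make_waveform_pair,
    materialize_subject,
)


def half_sine(t, spec):
    """Independent closed-form evaluation of the generator's pulse."""
    s = (np.asarray(t, float) - spec.systole_onset) / (2 * spec.upstroke_duration)
    out = np.full(np.shape(t), spec.baseline_flow)
    m = (s >= 0) & (s <= 1)
    out[m] = spec.baseline_flow + (spec.peak_flow - spec.baseline_flow) * np.sin(np.pi * s[m])
    return out


class TestWaveformPair:
    def test_integer_shift_is_exact_sample_shift(self):
        spec = WaveformSpec(true_delay=18.0, noise_sd=0.0)
        prox, dist = make_waveform_pair(spec)
        scaled = spec.baseline_flow + spec.attenuation * (prox.flow[:-2] - spec.baseline_flow)
        np.testing.assert_allclose(dist.flow[2:], scaled, atol=1e-12)

    def test_zero_delay_full_attenuation_identity(self):
        prox, dist = make_waveform_pair(
            WaveformSpec(true_delay=0.0, attenuation=1.0, noise_sd=0.0)
        )
        np.testing.assert_allclose(prox.flow, dist.flow, atol=1e-12)

    def test_subsample_shift_matches_closed_form(self):
        spec = WaveformSpec(true_delay=4.5, attenuation=1.0, noise_sd=0.0)
        prox, dist = make_waveform_pair(spec)
        np.testing.assert_allclose(dist.flow, half_sine(dist.times - 4.5, spec), atol=1e-9)
        np.testing.assert_allclose(prox.flow, half_sine(prox.times, spec), atol=1e-9)

    def test_seeded_generation_bit_reproducible(self):
        a = make_waveform_pair(WaveformSpec(noise_sd=5.0, seed=42))
        b = make_waveform_pair(WaveformSpec(noise_sd=5.0, seed=42))
        np.testing.assert_array_equal(a[0].flow, b[0].flow)
        np.testing.assert_array_equal(a[1].flow, b[1].flow)

    def test_delay_leaving_window_rejected(self):
        with pytest.raises(ValueError, match="leave"):
            WaveformSpec(rr_interval=400.0, systole_onset=50.0,
                         upstroke_duration=120.0, true_delay=250.0)


class TestAreaCurve:
    def test_formula_inversion(self):
        c = make_area_curve(
            LumenPulsationSpec(a_min=250.0, target_distensibility=4.0, pulse_pressure=50.0)
        )
        assert c.areas.max() == pytest.approx(300.0, abs=1e-9)
        assert c.areas.min() == pytest.approx(250.0, abs=1e-12)

    def test_rigid_vessel_constant(self):
        c = make_area_curve(LumenPulsationSpec(a_min=250.0, target_distensibility=0.0,
                                               pulse_pressure=50.0))
        np.testing.assert_allclose(c.areas, 250.0)

    def test_round_trip_through_estimator(self):
        spec = LumenPulsationSpec(a_min=120.0, target_distensibility=6.8, pulse_pressure=47.0)
        a_min, a_max = area_extremes(make_area_curve(spec))
        got = distensibility(a_min, a_max, BloodPressure(107.0, 60.0))
        assert got == pytest.approx(6.8, rel=1e-12)


class TestEllipsoidStack:
    def test_analytic_volume_recorded(self):
        stack = make_ellipsoid_stack(EllipsoidStackSpec(semi_axes=(20, 20, 30)))
        assert stack.analytic_volumes_ml[0] == pytest.approx(50.265, rel=1e-3)

    def test_scale_profile_cubes_volume(self):
        stack = make_ellipsoid_stack(
            EllipsoidStackSpec(phases=2, volume_time_profile=np.array([1.0, 0.8]))
        )
        v = stack.analytic_volumes_ml
        assert v[1] == pytest.approx(v[0] * 0.8**3, rel=1e-12)


class TestCohort:
    def test_seeded_draw_bit_reproducible(self):
        a = draw_cohort_parameters(default_cohort_spec(seed=5))
        b = draw_cohort_parameters(default_cohort_spec(seed=5))
        assert a.equals(b)

    def test_group_sizes_and_carotid_subgroup(self):
        subs = draw_cohort_parameters(default_cohort_spec(seed=1))
        assert (subs["group"] == "patient").sum() == 51
        assert (subs["group"] == "control").sum() == 54
        assert subs.loc[subs["group"] == "patient", "has_carotid"].sum() == 11
        assert subs.loc[subs["group"] == "control", "has_carotid"].sum() == 13

    def test_moments_match_specification(self):
        """Sample means land within 3 SD/sqrt(n) for mildly truncated marginals."""
        spec = default_cohort_spec(seed=9, n_patients=400, n_controls=400)
        subs = draw_cohort_parameters(spec)
        pat = subs[subs["group"] == "patient"]
        for name in ("pwv_arch", "la_vol_max_i", "lvedv_i", "systolic"):
            p = spec.parameters[name]
            tol = 3.0 * p.patient_sd / np.sqrt(len(pat))
            # allow the (small) truncation shift on top of sampling error
            assert abs(pat[name].mean() - p.patient_mean) < tol + 0.05 * p.patient_sd

    def test_zero_sd_gives_identical_subjects(self):
        from vesselpulse.phantoms import GroupParam

        spec = default_cohort_spec(seed=2)
        spec.parameters["pwv_arch"] = GroupParam(4.6, 0.0, 3.5, 0.0, 1.3)
        subs = draw_cohort_parameters(spec)
        assert subs.loc[subs.group == "patient", "pwv_arch"].nunique() == 1

    def test_uncorrelated_parameters_near_zero_rho(self):
        subs = draw_cohort_parameters(
            default_cohort_spec(seed=3, n_patients=1000, n_controls=2)
        )
        pat = subs[subs["group"] == "patient"]
        rho = spearmanr(pat["pwv_arch"], pat["wall_area_right"]).statistic
        assert abs(rho) < 0.1

    def test_requested_rank_correlation_induced(self):
        subs = draw_cohort_parameters(
            default_cohort_spec(seed=4, n_patients=1000, n_controls=2)
        )
        pat = subs[subs["group"] == "patient"]
        rho = spearmanr(pat["age_at_repair"], pat["pwv_dao"]).statistic
        assert rho == pytest.approx(0.33, abs=0.1)

    def test_infeasible_correlation_rejected(self):
        corr = {
            ("pwv_arch", "pwv_dao"): 0.9,
            ("pwv_arch", "la_vol_max_i"): 0.9,
            ("pwv_dao", "la_vol_max_i"): -0.9,
        }
        with pytest.raises(ValueError, match="infeasible correlation"):
            draw_cohort_parameters(default_cohort_spec(spearman_correlations=corr))

    def test_volume_ordering_holds(self):
        subs = draw_cohort_parameters(default_cohort_spec(seed=6))
        assert (subs["la_vol_max_i"] >= subs["la_vol_ac_i"]).all()
        assert (subs["la_vol_ac_i"] >= subs["la_vol_min_i"]).all()
        assert (subs["lvedv_i"] > subs["lvesv_i"]).all()
        assert (subs["systolic"] > subs["diastolic"]).all()

    def test_materialized_subject_recovers_truth(self):
        """Noise-light raw data reproduce the latent biomarkers downstream."""
        from vesselpulse.chambers import la_landmarks, volume_curve
        from vesselpulse.pulsewave import pulse_wave_velocity, transit_time

        spec = default_cohort_spec(seed=11, n_patients=2, n_controls=2,
                                   n_carotid_patients=2, n_carotid_controls=2,
                                   waveform_noise_fraction=0.0)
        subs = draw_cohort_parameters(spec)
        row = subs.iloc[0]
        data = materialize_subject(row, spec)
        prox, dist = data.waveforms["arch"]
        est = transit_time(prox, dist)
        pwv = pulse_wave_velocity(est, row["delta_x_arch_m"], "aortic arch").pwv
        assert pwv == pytest.approx(row["pwv_arch"], rel=0.05)
        vc = volume_curve(data.contours, "LA")
        lm = la_landmarks(vc)
        assert vc.volumes[lm.phase_max] == pytest.approx(
            row["la_vol_max_i"] * row["bsa"], rel=0.02
        )

    def test_make_cohort_returns_data_for_every_subject(self):
        spec = default_cohort_spec(seed=12, n_patients=2, n_controls=2,
                                   n_carotid_patients=1, n_carotid_controls=1)
        subs, data = make_cohort(spec)
        assert set(data) == set(subs["subject_id"])
        assert "carotid_left" in data[subs.iloc[0]["subject_id"]].waveforms
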