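"""Kinematics: curvature fields, frequency, wave speed, speed, profiles."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nemaswim import (
    BodyShapeSeries,
    GaitParams,
    generate_gait,
    summarize_kinematics,
)
from nemaswim.errors import NoOscillation, NormalizationUndefined
from nemaswim.kinematics import (
    CurvatureField,
    beating_frequency,
    curvature_kymograph,
    curvature_profile,
    cycle_count_frequency,
    swimming_speed,
    time_averaged_curvature,
    wave_speed,
)


def _static_series(points: np.ndarray, n_frames: int = 10, fps: float = 30.0):
    return BodyShapeSeries(points=np.repeat(points[None], n_frames, axis=0), fps=fps)


class TestSwimmingSpeed:
    def test_constant_drift_exact(self):
        # 0.1 px/frame at 30 fps with 0.01 mm/px -> 0.03 mm/s
        pts = np.linspace([0, 0], [1, 0], 50)
        series = _static_series(pts, n_frames=30)
        shift = 0.1 * 0.01 * np.arange(30)
        series.points[..., 0] += shift[:, None]
        assert swimming_speed(series) == pytest.approx(0.03, rel=1e-9)

    def test_stationary_is_zero(self):
        series = _static_series(np.linspace([0, 0], [1, 0], 50))
        assert swimming_speed(series) == 0.0

    def test_round_trip_within_two_percent(self, clean_series):
        series, truth = clean_series
        assert swimming_speed(series) == pytest.approx(truth.u_true, rel=0.02)


class TestCurvatureKymograph:
    def test_straight_worm_zero_curvature(self):
        series = _static_series(np.linspace([0, 0], [1, 1], 60))
        field = curvature_kymograph(series)
        assert np.abs(field.kappa).max() < 1e-9

    def test_circular_arc_recovers_inverse_radius(self):
        # R = 0.2 mm -> kappa = 5 / mm at every interior position
        r = 0.2
        ang = np.linspace(0.0, 1.5 * np.pi, 100)
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        field = curvature_kymograph(_static_series(pts))
        assert np.allclose(np.abs(field.kappa), 5.0, rtol=0.01)

    def test_matches_analytic_wave_to_five_percent_of_peak(self, clean_series):
        series, truth = clean_series
        field = curvature_kymograph(series)
        rms = np.sqrt(np.mean((field.kappa - truth.kappa_true) ** 2))
        assert rms <= 0.05 * truth.params.kappa0

    def test_degenerate_points_name_the_frame(self):
        pts = np.linspace([0, 0], [1, 0], 20)
        pts[5] = pts[6]  # repeated point
        with pytest.raises(Exception, match="frame 0"):
            curvature_kymograph(_static_series(pts))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi), dx=st.floats(-5, 5), dy=st.floats(-5, 5))
    def test_rigid_transform_invariance(self, angle, dx, dy):
        params = GaitParams(duration=2.0, allow_short=True)
        series, _ = generate_gait(params)
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = BodyShapeSeries(points=series.points @ rot.T + [dx, dy], fps=series.fps)
        k1 = curvature_kymograph(series).kappa
        k2 = curvature_kymograph(moved).kappa
        assert np.allclose(k1, k2, rtol=1e-6, atol=1e-9 * np.abs(k1).max())


class TestBeatingFrequency:
    def test_round_trip_two_hertz(self):
        series, truth = generate_gait(GaitParams(frequency=2.0, duration=4.0))
        f, t_period = beating_frequency(curvature_kymograph(series))
        assert f == pytest.approx(2.0, rel=0.02)
        assert f * t_period == 1.0  # T = 1/f exactly

    def test_l2_like_preset_recovered(self):
        series, truth = generate_gait(
            GaitParams(body_length=0.39, kappa0=6.0 / 0.39, frequency=1.9, speed=0.16)
        )
        f, _ = beating_frequency(curvature_kymograph(series))
        assert f == pytest.approx(1.9, rel=0.02)

    def test_constant_field_raises_no_oscillation(self):
        field = CurvatureField(
            kappa=np.ones((50, 90)), sigma=np.linspace(0.01, 0.99, 50),
            fps=30.0, length_mm=0.6,
        )
        with pytest.raises(NoOscillation):
            beating_frequency(field)

    def test_cycle_count_cross_check_agrees(self, clean_series):
        series, truth = clean_series
        field = curvature_kymograph(series)
        f_spec, _ = beating_frequency(field)
        f_count, periods = cycle_count_frequency(field)
        assert f_count == pytest.approx(f_spec, rel=0.05)
        assert periods.std() / periods.mean() < 0.1  # regular beating


class TestWaveSpeed:
    def test_wave_speed_equals_wavelength_times_frequency(self):
        params = GaitParams(wavelength_frac=0.6, frequency=2.0, duration=4.0)
        series, truth = generate_gait(params)
        field = curvature_kymograph(series)
        f, _ = beating_frequency(field)
        v, lam = wave_speed(field, f)
        assert lam == pytest.approx(truth.lambda_true, rel=0.05)
        assert v == pytest.approx(truth.lambda_true * 2.0, rel=0.05)
        assert v == pytest.approx(lam * f, rel=0.01)  # internal consistency

    def test_doubling_frequency_doubles_wave_speed(self):
        fields = []
        for f_hz in (1.5, 3.0):
            series, _ = generate_gait(GaitParams(frequency=f_hz, duration=4.0))
            fields.append(curvature_kymograph(series))
        v1, lam1 = wave_speed(fields[0], 1.5)
        v2, lam2 = wave_speed(fields[1], 3.0)
        assert lam2 == pytest.approx(lam1, rel=0.02)
        assert v2 == pytest.approx(2 * v1, rel=0.02)

    def test_standing_wave_flagged_absent(self):
        # two halves of the body oscillating in antiphase, no travel
        sigma = np.linspace(0.01, 0.99, 60)
        t = np.arange(120) / 30.0
        spatial = np.where(sigma < 0.5, 1.0, -1.0)
        kappa = spatial[:, None] * np.sin(2 * np.pi * 2.0 * t)[None, :]
        field = CurvatureField(kappa=kappa, sigma=sigma, fps=30.0, length_mm=0.6)
        v, lam = wave_speed(field, 2.0)
        assert v is None and lam is None


class TestCurvatureProfile:
    def test_uniform_envelope_gives_flat_profile(self):
        params = GaitParams(envelope="uniform", duration=4.0)
        series, _ = generate_gait(params)
        profile = curvature_profile(curvature_kymograph(series))
        assert np.allclose(profile.values, 1.0, atol=0.05)

    def test_head_value_is_exactly_one_and_trimming_bounds(self, clean_series):
        series, _ = clean_series
        profile = curvature_profile(curvature_kymograph(series))
        assert profile.values[0] == 1.0
        assert profile.sigma[0] >= 0.05 and profile.sigma[-1] <= 0.95
        assert (profile.values >= 0).all()

    def test_time_first_order_nulls_a_zero_mean_wave(self, clean_series):
        # averaging curvature over integer periods before taking the magnitude
        # annihilates the oscillation; magnitude-first preserves it
        series, truth = clean_series
        field = curvature_kymograph(series)
        n_keep = int(round(4 * series.fps / truth.f_true))  # integer periods
        field_int = CurvatureField(kappa=field.kappa[:, :n_keep], sigma=field.sigma,
                                   fps=field.fps, length_mm=field.length_mm)
        _, abs_first = time_averaged_curvature(field_int, order="abs_first")
        _, time_first = time_averaged_curvature(field_int, order="time_first")
        assert time_first.max() < 0.05 * abs_first.max()

    def test_straight_worm_normalization_undefined(self):
        series = _static_series(np.linspace([0, 0], [1, 0], 60))
        with pytest.raises(NormalizationUndefined):
            curvature_profile(curvature_kymograph(series))

    def test_defective_gait_minimum_inside_suppression_window(self):
        from nemaswim.synthetic import preset

        series, _ = generate_gait(preset("defective").gait)
        profile = curvature_profile(curvature_kymograph(series))
        assert 0.5 <= profile.minimum_sigma <= 0.8


class TestSummarizeKinematics:
    def test_full_summary_on_clean_gait(self, clean_series):
        series, truth = clean_series
        kin = summarize_kinematics(series)
        assert kin.frequency == pytest.approx(truth.f_true, rel=0.02)
        assert kin.speed == pytest.approx(truth.u_true, rel=0.02)
        assert kin.wavelength == pytest.approx(truth.lambda_true, rel=0.05)
        assert kin.wave_speed == pytest.approx(kin.wavelength * kin.frequency, rel=0.01)
        assert kin.period * kin.frequency == 1.0
        assert kin.flags == []

    def test_non_undulating_mover_flagged(self):
        pts = np.linspace([0, 0], [0.6, 0], 60)
        series = _static_series(pts, n_frames=60)
        series.points[..., 0] += (0.005 * np.arange(60))[:, None]
        kin = summarize_kinematics(series)
        assert kin.frequency is None
        assert "no_oscillation" in kin.flags
        assert kin.speed > 0

    def test_rendered_round_trip_within_five_percent(self, rendered_movie, tracked_series):
        stack, truth, params = rendered_movie
        kin = summarize_kinematics(tracked_series)
        assert kin.frequency == pytest.approx(truth.f_true, rel=0.05)
        assert kin.speed == pytest.approx(truth.u_true, rel=0.05)
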