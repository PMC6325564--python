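"""Resistive-force-theory dynamics: coefficients, velocities, force, power."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nemaswim import (
    BodyShapeSeries,
    FluidParams,
    GaitParams,
    build_profile,
    drag_coefficients,
    generate_gait,
    mechanical_power,
    propulsive_force,
    segment_velocities,
)
from nemaswim.dynamics import rigid_drag_force, rigid_drag_power
from nemaswim.errors import DomainError
from nemaswim.kinematics import beating_frequency, curvature_kymograph
from nemaswim.synthetic import balanced_speed, preset


def _translating_rod(direction, speed=0.3, n_frames=60, fps=30.0, length=0.6):
    pts = np.linspace([0.0, 0.0], [length, 0.0], 80)
    series = BodyShapeSeries(points=np.repeat(pts[None], n_frames, axis=0), fps=fps)
    t = np.arange(n_frames) / fps
    series.points += (speed * t)[:, None, None] * np.asarray(direction)[None, None, :]
    return series


class TestDragCoefficients:
    # frozen from a hand evaluation of the closed forms at
    # mu = 1 mPa*s, lambda = 1 mm, a = 0.025 mm (ln(2 lambda / a) = ln 80)
    def test_regression_constants(self):
        coef = drag_coefficients(FluidParams(1.0), 1.0, 0.025, model="lighthill")
        assert coef.c_t == pytest.approx(1.6185322509275932, rel=1e-12)
        assert coef.c_n == pytest.approx(2.5740069759366655, rel=1e-12)
        gh = drag_coefficients(FluidParams(1.0), 1.0, 0.025, model="gray_hancock")
        assert gh.c_t == pytest.approx(1.6185322509275932, rel=1e-12)
        assert gh.c_n == pytest.approx(3.2370645018551865, rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        mu=st.floats(0.5, 5.0),
        lam=st.floats(0.2, 2.0),
        ratio=st.floats(8.0, 60.0),
        model=st.sampled_from(["lighthill", "gray_hancock"]),
    )
    def test_anisotropy_ratio_structural_bounds(self, mu, lam, ratio, model):
        coef = drag_coefficients(FluidParams(mu), lam, lam / ratio, model=model)
        assert 1.0 < coef.ratio <= 2.0

    def test_linear_in_viscosity(self):
        c1 = drag_coefficients(FluidParams(1.0), 0.9, 0.025)
        c2 = drag_coefficients(FluidParams(2.0), 0.9, 0.025)
        assert c2.c_n == pytest.approx(2 * c1.c_n, rel=1e-12)
        assert c2.c_t == pytest.approx(2 * c1.c_t, rel=1e-12)

    def test_wavelength_below_diameter_rejected(self):
        with pytest.raises(DomainError):
            drag_coefficients(FluidParams(1.0), 0.04, 0.025)


class TestSegmentVelocities:
    def test_axial_translation_is_purely_tangential(self):
        series = _translating_rod([1.0, 0.0], speed=0.3)
        vel = segment_velocities(series)
        assert np.abs(vel.u_n).max() < 1e-12
        assert np.allclose(vel.u_t, 0.3, atol=1e-12)

    def test_perpendicular_translation_is_purely_normal(self):
        series = _translating_rod([0.0, 1.0], speed=0.3)
        vel = segment_velocities(series)
        assert np.abs(vel.u_t).max() < 1e-12
        assert np.allclose(np.abs(vel.u_n), 0.3, atol=1e-12)

    def test_orthogonal_decomposition_preserves_speed(self, clean_series):
        series, _ = clean_series
        vel = segment_velocities(series)
        from nemaswim.dynamics import _time_derivative

        v = _time_derivative(vel.midpoints, series.fps)
        speed_sq = np.sum(v**2, axis=2)
        assert np.allclose(vel.u_n**2 + vel.u_t**2, speed_sq, rtol=1e-6)


class TestPropulsiveForce:
    def test_dragged_rod_zero_thrust_closed_form_drag(self):
        speed, length = 0.3, 0.6
        series = _translating_rod([1.0, 0.0], speed=speed, length=length)
        coef = drag_coefficients(FluidParams(1.0), length, length / 25.0)
        vel = segment_velocities(series)
        dyn = propulsive_force(vel, coef)
        assert dyn.mean_thrust == pytest.approx(0.0, abs=1e-12)
        assert dyn.mean_drag == pytest.approx(
            rigid_drag_force(coef, speed, length), rel=0.01
        )

    def test_force_linear_in_viscosity(self, clean_series):
        series, truth = clean_series
        vel = segment_velocities(series)
        lam = truth.lambda_true
        d1 = propulsive_force(vel, drag_coefficients(FluidParams(1.0), lam, 0.025),
                              frequency=truth.f_true)
        d3 = propulsive_force(vel, drag_coefficients(FluidParams(3.0), lam, 0.025),
                              frequency=truth.f_true)
        assert d3.mean_thrust == pytest.approx(3 * d1.mean_thrust, rel=1e-12)
        assert d3.mean_net_force == pytest.approx(3 * d1.mean_net_force, rel=1e-9)

    def test_force_free_closure_on_balanced_swimmer(self, n2_late_gait):
        # steady swimming = the RFT-balanced speed; there the period-averaged
        # net force must be a small fraction of the propulsive force
        params = replace(n2_late_gait, speed=balanced_speed(n2_late_gait))
        series, truth = generate_gait(params)
        field = curvature_kymograph(series)
        f, _ = beating_frequency(field)
        coef = drag_coefficients(FluidParams(1.0), truth.lambda_true,
                                 params.body_length / 25.0)
        vel = segment_velocities(series)
        dyn = propulsive_force(vel, coef, frequency=f)
        assert dyn.mean_net_force <= 0.10 * dyn.mean_thrust

    def test_magnitude_in_published_order(self, n2_late_gait):
        series, truth = generate_gait(n2_late_gait)
        prof = build_profile(series)
        assert 0.1 <= prof.force_nN <= 1.0  # published bending forces ~0.4-0.7 nN

    def test_quadrature_against_fine_grid_oracle(self, n2_late_gait):
        # independently coded fine-grid Riemann sum of the same integrand
        fine = replace(n2_late_gait, n_points=401)
        series, truth = generate_gait(fine)
        coef = drag_coefficients(FluidParams(1.0), truth.lambda_true,
                                 fine.body_length / 25.0)
        fps = series.fps
        p = series.points
        mids = 0.5 * (p[:, 1:] + p[:, :-1])
        v = np.empty_like(mids)
        v[1:-1] = (mids[2:] - mids[:-2]) * fps / 2
        v[0] = (mids[1] - mids[0]) * fps
        v[-1] = (mids[-1] - mids[-2]) * fps
        seg = np.diff(p, axis=1)
        ds = np.linalg.norm(seg, axis=2)
        tan = seg / ds[..., None]
        nor = np.stack([-tan[..., 1], tan[..., 0]], axis=-1)
        un = np.sum(v * nor, axis=2)
        ut = np.sum(v * tan, axis=2)
        oracle_power = ((coef.c_n * un**2 + coef.c_t * ut**2) * ds).sum(axis=1)

        vel = segment_velocities(series)
        dyn = mechanical_power(vel, coef, frequency=truth.f_true)
        assert np.allclose(dyn.power, oracle_power, rtol=0.01)

    def test_mesh_convergence(self, n2_late_gait):
        means = {}
        for n in (100, 400):
            series, truth = generate_gait(replace(n2_late_gait, n_points=n))
            prof = build_profile(series)
            means[n] = (prof.force_nN, prof.power_pW)
        assert means[400][0] == pytest.approx(means[100][0], rel=0.02)
        assert means[400][1] == pytest.approx(means[100][1], rel=0.02)


class TestMechanicalPower:
    def test_stationary_worm_zero_power(self):
        pts = np.linspace([0, 0], [0.6, 0], 80)
        series = BodyShapeSeries(points=np.repeat(pts[None], 30, axis=0), fps=30.0)
        coef = drag_coefficients(FluidParams(1.0), 0.6, 0.024)
        dyn = mechanical_power(segment_velocities(series), coef)
        assert np.allclose(dyn.power, 0.0)

    def test_power_nonnegative_and_linear_in_viscosity(self, clean_series):
        series, truth = clean_series
        vel = segment_velocities(series)
        lam = truth.lambda_true
        d1 = mechanical_power(vel, drag_coefficients(FluidParams(1.0), lam, 0.025))
        d2 = mechanical_power(vel, drag_coefficients(FluidParams(2.0), lam, 0.025))
        assert (d1.power >= 0).all()
        assert np.allclose(d2.power, 2 * d1.power, rtol=1e-12)

    def test_velocity_doubling_quadruples_power(self, clean_series):
        series, truth = clean_series
        vel = segment_velocities(series)
        coef = drag_coefficients(FluidParams(1.0), truth.lambda_true, 0.025)
        import copy

        base = mechanical_power(vel, coef)
        fast = copy.copy(vel)
        fast.u_n = 2 * vel.u_n
        fast.u_t = 2 * vel.u_t
        doubled = mechanical_power(fast, coef)
        assert np.allclose(doubled.power, 4 * base.power, rtol=1e-12)


class TestBuildProfile:
    def test_straight_mover_matches_rigid_drag_power(self):
        length, speed = 0.6, 0.2
        series = _translating_rod([1.0, 0.0], speed=speed, length=length, n_frames=90)
        prof = build_profile(series)
        assert prof.frequency_hz is None
        assert "no_oscillation" in prof.flags
        assert prof.speed_mm_s == pytest.approx(speed, rel=1e-6)
        # wavelength falls back to body length for the coefficient evaluation
        coef = drag_coefficients(FluidParams(1.0), length, length / 25.0)
        assert prof.power_pW == pytest.approx(
            rigid_drag_power(coef, speed, length), rel=0.05
        )

    def test_profile_is_deterministic(self, clean_series):
        series, _ = clean_series
        p1 = build_profile(series)
        p2 = build_profile(series)
        assert p1 == p2

    def test_group_mean_length_recovered_from_preset_cohort(self):
        from nemaswim.synthetic import make_cohort

        cohort = make_cohort(["n2_late"], n_per_group=20, seed=2, duration=2.5)
        lengths = [build_profile(w.series).length_mm for w in cohort.worms]
        assert np.mean(lengths) == pytest.approx(0.63, rel=0.03)
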