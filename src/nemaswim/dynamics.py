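"""Resistive force theory: drag coefficients, segment velocities, force, power.

At the low Reynolds numbers of a swimming nematode (Re ~ 0.1-1) the fluid force
on each slender body segment is approximated as linear drag on its normal and
tangential velocity components, dF = -(C_N u_N n + C_T u_T t) ds.  Because the
animal is self-propelled and force-free, the period-averaged thrust balances
the period-averaged drag, which lets the propulsive force be estimated from
the drag integral over the body.

Unit contract: with the dynamic viscosity mu in mPa*s, lengths in mm and
velocities in mm/s, the segment force C*u*ds comes out directly in nN and the
power C*u^2*ds directly in pW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import BodyShapeSeries
from .errors import DomainError, ValidationError

__all__ = [
    "FluidParams",
    "DragCoefficients",
    "SegmentVelocities",
    "DynamicsSummary",
    "BiomechanicalProfile",
    "drag_coefficients",
    "segment_velocities",
    "propulsive_force",
    "mechanical_power",
    "build_profile",
    "rigid_drag_force",
    "rigid_drag_power",
]


@dataclass(frozen=True)
class FluidParams:
    """Newtonian fluid: dynamic viscosity in mPa*s (1.0 = water-like buffer)."""

    mu: float = 1.0
    temperature_c: Optional[float] = None

    def __post_init__(self):
        if not self.mu > 0:
            raise ValidationError("mu", "viscosity must be positive")


@dataclass(frozen=True)
class DragCoefficients:
    """Per-unit-length normal/tangential drag coefficients, in mPa*s."""

    c_n: float
    c_t: float
    mu: float
    wavelength: float
    radius: float
    model: str

    @property
    def ratio(self) -> float:
        return self.c_n / self.c_t


def drag_coefficients(
    fluid: FluidParams, wavelength: float, radius: float, model: str = "lighthill"
) -> DragCoefficients:
    """Slender-body drag coefficients from viscosity, undulation wavelength
    and body radius.

    ``lighthill`` (default): C_T = 2*pi*mu / (ln(2*lambda/a) - 1/2),
                             C_N = 4*pi*mu / (ln(2*lambda/a) + 1/2).
    ``gray_hancock``: the original ratio-2 simplification, same C_T with
                             C_N = 2 * C_T.
    """
    if not radius > 0:
        raise DomainError("body radius must be positive")
    if not wavelength > 2 * radius:
        raise DomainError("wavelength must exceed the body diameter (log argument)")
    log = math.log(2.0 * wavelength / radius)
    if model == "lighthill":
        c_t = 2.0 * math.pi * fluid.mu / (log - 0.5)
        c_n = 4.0 * math.pi * fluid.mu / (log + 0.5)
    elif model == "gray_hancock":
        c_t = 2.0 * math.pi * fluid.mu / (log - 0.5)
        c_n = 2.0 * c_t
    else:
        raise ValidationError("model", f"unknown drag model {model!r}")
    if not c_n > c_t:
        raise DomainError("degenerate geometry: C_N <= C_T")
    return DragCoefficients(c_n=c_n, c_t=c_t, mu=fluid.mu, wavelength=wavelength,
                            radius=radius, model=model)


@dataclass
class SegmentVelocities:
    """Per-frame, per-segment kinematic decomposition.

    Arrays are (frames, segments[, 2]); velocities by central difference in
    time (one-sided at the ends), projected on each segment's unit tangent and
    normal.  ``swim_dir`` is the unit instantaneous swimming direction from
    the smoothed centroid velocity.
    """

    midpoints: np.ndarray
    tangents: np.ndarray
    normals: np.ndarray
    u_n: np.ndarray
    u_t: np.ndarray
    ds: np.ndarray
    fps: float
    swim_dir: np.ndarray
    centroid_speed: np.ndarray


def _time_derivative(x: np.ndarray, fps: float) -> np.ndarray:
    """Central differences along axis 0, one-sided at the first/last frame."""
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * (fps / 2.0)
    v[0] = (x[1] - x[0]) * fps
    v[-1] = (x[-1] - x[-2]) * fps
    return v


def smoothed_centroid_velocity(series: BodyShapeSeries, window: int = 5) -> np.ndarray:
    """Centroid velocity (mm/s) by central differences on a smoothed track."""
    track = series.centroid_track
    if window > 1:
        track = uniform_filter1d(track, size=window, axis=0, mode="nearest")
    return _time_derivative(track, series.fps)


def segment_velocities(series: BodyShapeSeries) -> SegmentVelocities:
    """Decompose each body segment's velocity into normal/tangential parts."""
    if series.n_frames < 2:
        raise ValidationError("series", "need at least 2 frames for velocities")
    p = series.points
    seg = np.diff(p, axis=1)  # (F, n-1, 2)
    ds = np.linalg.norm(seg, axis=2)
    if np.any(ds == 0):
        f = int(np.argwhere(ds == 0)[0][0])
        raise ValidationError("points", f"repeated points in frame {f}")
    tangents = seg / ds[..., None]
    normals = np.stack([-tangents[..., 1], tangents[..., 0]], axis=-1)
    mids = 0.5 * (p[:, 1:] + p[:, :-1])
    vel = _time_derivative(mids, series.fps)
    u_t = np.sum(vel * tangents, axis=2)
    u_n = np.sum(vel * normals, axis=2)
    cvel = smoothed_centroid_velocity(series)
    speed = np.linalg.norm(cvel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        swim_dir = np.where(speed[:, None] > 0, cvel / np.maximum(speed[:, None], 1e-300), 0.0)
    return SegmentVelocities(
        midpoints=mids, tangents=tangents, normals=normals,
        u_n=u_n, u_t=u_t, ds=ds, fps=series.fps,
        swim_dir=swim_dir, centroid_speed=speed,
    )


@dataclass
class DynamicsSummary:
    """Per-frame force/power traces and their period averages.

    ``thrust`` (the propulsive-force trace F_P(t), nN) is the magnitude of the
    summed segment forces whose projection on the instantaneous swimming
    direction is propulsive; ``drag`` the opposing sum; ``net_force`` the full
    RFT force vector (nN).  ``power`` is P(t) in pW.
    """

    thrust: np.ndarray = field(default_factory=lambda: np.empty(0))
    drag: np.ndarray = field(default_factory=lambda: np.empty(0))
    net_force: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    power: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_thrust: float = float("nan")
    mean_drag: float = float("nan")
    mean_net_force: float = float("nan")
    mean_power: float = float("nan")
    frequency: Optional[float] = None
    n_periods: int = 0
    flags: list = field(default_factory=list)

    @property
    def mean_propulsive_force(self) -> float:
        """Period-averaged propulsive force <F_P> in nN (thrust magnitude)."""
        return self.mean_thrust


def _period_slice(n_frames: int, fps: float, frequency: Optional[float]):
    """Largest integer number of beat periods; (slice, n_periods, flagged)."""
    if frequency is None or not np.isfinite(frequency) or frequency <= 0:
        return slice(0, n_frames), 0, True
    period_frames = fps / frequency
    n_per = int(n_frames / period_frames)
    if n_per < 1:
        return slice(0, n_frames), 0, True
    return slice(0, int(round(n_per * period_frames))), n_per, False


def _segment_forces(vel: SegmentVelocities, coef: DragCoefficients) -> np.ndarray:
    """Fluid drag force on each segment, (frames, segments, 2), in nN."""
    return -(
        coef.c_n * vel.u_n[..., None] * vel.normals
        + coef.c_t * vel.u_t[..., None] * vel.tangents
    ) * vel.ds[..., None]


def propulsive_force(
    vel: SegmentVelocities,
    coef: DragCoefficients,
    frequency: Optional[float] = None,
    out: Optional[DynamicsSummary] = None,
) -> DynamicsSummary:
    """Propulsive force trace and period average from the RFT drag integral.

    Per frame, segment forces are projected on the instantaneous swimming
    direction; F_P(t) is the summed propulsive (forward-pushing) part, the
    opposing part is the drag, and their vector sum the net force (near zero
    for a dynamically consistent swimmer: the force-free closure).
    """
    dF = _segment_forces(vel, coef)
    net = dF.sum(axis=1)
    proj = np.sum(dF * vel.swim_dir[:, None, :], axis=2)
    thrust = np.where(proj > 0, proj, 0.0).sum(axis=1)
    drag = -np.where(proj < 0, proj, 0.0).sum(axis=1)
    n_frames = len(thrust)
    sl, n_per, flagged = _period_slice(n_frames, vel.fps, frequency)
    res = out if out is not None else DynamicsSummary()
    res.thrust, res.drag, res.net_force = thrust, drag, net
    res.frequency = frequency
    res.n_periods = n_per
    res.mean_thrust = float(thrust[sl].mean())
    res.mean_drag = float(drag[sl].mean())
    res.mean_net_force = float(np.linalg.norm(net[sl].mean(axis=0)))
    if flagged and "no_period" not in res.flags:
        res.flags.append("no_period")
    return res


def mechanical_power(
    vel: SegmentVelocities,
    coef: DragCoefficients,
    frequency: Optional[float] = None,
    out: Optional[DynamicsSummary] = None,
) -> DynamicsSummary:
    """Mechanical power P(t) = sum (C_N u_N^2 + C_T u_T^2) ds, in pW."""
    power = ((coef.c_n * vel.u_n**2 + coef.c_t * vel.u_t**2) * vel.ds).sum(axis=1)
    sl, n_per, flagged = _period_slice(len(power), vel.fps, frequency)
    res = out if out is not None else DynamicsSummary()
    res.power = power
    res.frequency = frequency
    res.n_periods = max(res.n_periods, n_per)
    res.mean_power = float(power[sl].mean())
    if flagged and "no_period" not in res.flags:
        res.flags.append("no_period")
    return res


def rigid_drag_force(coef: DragCoefficients, speed: float, length: float) -> float:
    """Closed-form drag magnitude (nN) of a straight rod dragged axially."""
    return coef.c_t * speed * length


def rigid_drag_power(coef: DragCoefficients, speed: float, length: float) -> float:
    """Closed-form power (pW) dissipated dragging a straight rod axially."""
    return coef.c_t * speed**2 * length


@dataclass
class BiomechanicalProfile:
    """One per-worm record: the row structure of a biomechanical profile table."""

    worm_id: str = ""
    group: str = ""
    stage: str = ""
    length_mm: float = float("nan")
    speed_mm_s: float = float("nan")
    frequency_hz: Optional[float] = None
    force_nN: float = float("nan")
    power_pW: float = float("nan")
    wavelength_mm: Optional[float] = None
    wave_speed_mm_s: Optional[float] = None
    net_force_nN: float = float("nan")
    drag_model: str = "lighthill"
    mu_mPa_s: float = 1.0
    radius_mm: float = float("nan")
    flags: list = field(default_factory=list)


def characteristic_radius(series: BodyShapeSeries) -> float:
    """Median tracked half-width over the mid-body (sigma in [0.2, 0.8]);
    falls back to length/25 when no widths were tracked."""
    if series.half_widths is not None and np.isfinite(series.half_widths).any():
        sig = series.sigma
        mid = (sig >= 0.2) & (sig <= 0.8)
        val = float(np.nanmedian(series.half_widths[:, mid]))
        if val > 0:
            return val
    return series.length / 25.0


def build_profile(
    series: BodyShapeSeries,
    fluid: FluidParams = FluidParams(),
    model: str = "lighthill",
    worm_id: str = "",
    group: str = "",
    stage: str = "",
) -> BiomechanicalProfile:
    """Full per-worm biomechanical profile: L, U, f, <F_P>, <P>.

    The drag-coefficient wavelength is the measured undulation wavelength,
    with the body length as fallback when no traveling wave is detected.
    """
    from .kinematics import curvature_kymograph, summarize_kinematics

    field_ = curvature_kymograph(series)
    kin = summarize_kinematics(series, field_)
    flags = list(kin.flags)
    lam = kin.wavelength
    if lam is None or not np.isfinite(lam):
        lam = series.length
        flags.append("wavelength_fallback_body_length")
    a = characteristic_radius(series)
    coef = drag_coefficients(fluid, lam, a, model=model)
    vel = segment_velocities(series)
    dyn = propulsive_force(vel, coef, frequency=kin.frequency)
    dyn = mechanical_power(vel, coef, frequency=kin.frequency, out=dyn)
    flags += [f for f in dyn.flags if f not in flags]
    return BiomechanicalProfile(
        worm_id=worm_id, group=group, stage=stage,
        length_mm=series.length,
        speed_mm_s=kin.speed,
        frequency_hz=kin.frequency,
        force_nN=dyn.mean_thrust,
        power_pW=dyn.mean_power,
        wavelength_mm=kin.wavelength,
        wave_speed_mm_s=kin.wave_speed,
        net_force_nN=dyn.mean_net_force,
        drag_model=model, mu_mPa_s=fluid.mu, radius_mm=a,
        flags=flags,
    )
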