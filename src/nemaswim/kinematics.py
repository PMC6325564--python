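"""Gait kinematics: curvature kymographs, frequency, wave speed, speed, profiles.

Bending curvature kappa is the change of local tangent orientation per unit
arclength along the body, with positive = counterclockwise bending.  Plotted
as kappa(sigma, t) it forms a kymograph whose diagonal stripes are the
traveling curvature wave; the stripe slope is the wave speed and the temporal
repetition rate the beating frequency f = 1/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter
from scipy.signal.windows import hann

from .core import BodyShapeSeries
from .errors import NoOscillation, NormalizationUndefined, ValidationError

__all__ = [
    "CurvatureField",
    "KinematicsSummary",
    "CurvatureProfile",
    "swimming_speed",
    "curvature_kymograph",
    "beating_frequency",
    "cycle_count_frequency",
    "wave_speed",
    "time_averaged_curvature",
    "curvature_profile",
    "group_mean_profile",
    "summarize_kinematics",
    "plot_kymograph",
]


@dataclass
class CurvatureField:
    """kappa(sigma, t) in 1/mm; rows = body coordinate, columns = frame."""

    kappa: np.ndarray  # (n_points - 2, n_frames)
    sigma: np.ndarray  # (n_points - 2,)
    fps: float
    length_mm: float  # time-mean body length (converts sigma to arclength)

    @property
    def n_frames(self) -> int:
        return self.kappa.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


@dataclass
class KinematicsSummary:
    """Scalar gait kinematics for one worm."""

    speed: float  # U, mm/s
    frequency: Optional[float]  # f, Hz (None if no oscillation)
    period: Optional[float]  # T = 1/f, s
    wave_speed: Optional[float]  # mm/s (None for standing/no wave)
    wavelength: Optional[float]  # mm, = wave_speed / f
    flags: list = field(default_factory=list)


@dataclass
class CurvatureProfile:
    """Head-normalized time-averaged |curvature| vs body coordinate."""

    sigma: np.ndarray
    values: np.ndarray
    order: str  # "abs_first" or "time_first"

    @property
    def minimum_sigma(self) -> float:
        return float(self.sigma[int(np.argmin(self.values))])


def swimming_speed(series: BodyShapeSeries, window: int = 5) -> float:
    """Forward swimming speed U: mean magnitude of the smoothed centroid
    velocity (central differences on a ``window``-frame smoothed track)."""
    from .dynamics import smoothed_centroid_velocity

    if series.n_frames < 2:
        raise ValidationError("series", "need at least 2 frames")
    vel = smoothed_centroid_velocity(series, window=window)
    speed = np.linalg.norm(vel, axis=1)
    # drop frames biased by the smoothing window's edge padding
    trim = window // 2 + 1
    if len(speed) > 2 * trim + 2:
        speed = speed[trim:-trim]
    return float(speed.mean())


def _tangent_angles(points: np.ndarray) -> np.ndarray:
    """Unwrapped segment tangent angles, (frames, n-1)."""
    seg = np.diff(points, axis=1)
    ds = np.linalg.norm(seg, axis=2)
    if np.any(ds == 0):
        f = int(np.argwhere(ds == 0)[0][0])
        raise ValidationError("points", f"repeated (degenerate) points in frame {f}")
    theta = np.arctan2(seg[..., 1], seg[..., 0])
    return np.unwrap(theta, axis=1)


def curvature_kymograph(
    series: BodyShapeSeries, smooth_frac: float = 0.05
) -> CurvatureField:
    """Curvature field kappa(sigma, t) = d(theta)/ds of the tangent angle.

    Tangent angles are smoothed along the body with a Savitzky-Golay filter of
    window ``smooth_frac`` of the body length (polynomial order 2, which
    preserves constant curvature exactly) before differencing.  The field is
    defined at the n-2 interior points.
    """
    theta = _tangent_angles(series.points)  # (F, n-1)
    n_seg = theta.shape[1]
    win = max(5, int(round(smooth_frac * (n_seg + 1))))
    win = min(win + (win % 2 == 0), n_seg)  # odd, no larger than the data
    if win >= 5:
        theta = savgol_filter(theta, window_length=win, polyorder=2, axis=1, mode="interp")
    ds = series.ds  # (F,)
    kappa = np.diff(theta, axis=1) / ds[:, None]  # (F, n-2)
    if not np.all(np.isfinite(kappa)):
        raise ValidationError("points", "non-finite curvature (degenerate geometry)")
    sigma = series.sigma[1:-1]
    return CurvatureField(kappa=kappa.T, sigma=sigma, fps=series.fps,
                          length_mm=series.length)


def _midbody_signal(field: CurvatureField, lo: float = 0.3, hi: float = 0.5) -> np.ndarray:
    rows = (field.sigma >= lo) & (field.sigma <= hi)
    if not rows.any():
        rows = slice(None)
    return field.kappa[rows].mean(axis=0)


def _spectrum(signal: np.ndarray, fps: float):
    sig = signal - signal.mean()
    w = hann(len(sig), sym=False)
    spec = np.fft.rfft(sig * w)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(len(sig), d=1.0 / fps)
    return freqs, power, spec


def beating_frequency(
    field: CurvatureField, peak_snr: float = 10.0
) -> tuple[float, float]:
    """Beating frequency f (and period T = 1/f) from the dominant spectral
    peak of the mid-body curvature signal, refined by parabolic interpolation
    on the log power spectrum."""
    sig = _midbody_signal(field)
    if len(sig) < 8 or sig.std() < 1e-12:
        raise NoOscillation("curvature signal is constant in time")
    freqs, power, _ = _spectrum(sig, field.fps)
    if len(power) < 4:
        raise NoOscillation("record too short for spectral estimation")
    k = int(np.argmax(power[1:])) + 1  # exclude DC
    floor = np.median(power[1:])
    if floor > 0 and power[k] < peak_snr * floor:
        raise NoOscillation("no spectral peak above the noise floor")
    if floor == 0 and power[k] == 0:
        raise NoOscillation("zero spectrum")
    # parabolic refinement on log power
    delta = 0.0
    if 1 <= k < len(power) - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        la, lb, lc = np.log(power[k - 1]), np.log(power[k]), np.log(power[k + 1])
        denom = la - 2 * lb + lc
        if denom != 0:
            delta = float(np.clip(0.5 * (la - lc) / denom, -0.5, 0.5))
    f = (k + delta) * field.fps / len(sig)
    if f <= 0:
        raise NoOscillation("non-positive refined frequency")
    return float(f), float(1.0 / f)


def cycle_count_frequency(field: CurvatureField) -> tuple[float, np.ndarray]:
    """Cross-check estimator: frequency from upward zero crossings of the
    mid-body curvature signal; also returns the successive cycle periods."""
    sig = _midbody_signal(field)
    sig = sig - sig.mean()
    idx = np.nonzero((sig[:-1] < 0) & (sig[1:] >= 0))[0]
    if len(idx) < 2:
        raise NoOscillation("fewer than two zero crossings")
    # linear interpolation of the crossing times
    frac = -sig[idx] / (sig[idx + 1] - sig[idx])
    times = (idx + frac) / field.fps
    periods = np.diff(times)
    return float(1.0 / periods.mean()), periods


def wave_speed(
    field: CurvatureField,
    frequency: Optional[float] = None,
    sigma_range: tuple = (0.1, 0.9),
    max_residual_rad: float = 0.6,
) -> tuple[Optional[float], Optional[float]]:
    """Wave speed and wavelength from the stripe slope of the kymograph.

    The phase of the dominant frequency component is extracted per body
    position; a traveling wave has phase varying linearly with arclength, and
    the (amplitude-weighted) phase gradient gives the wavelength,
    lambda = 2*pi/|d(phase)/ds|, with wave speed = lambda * f.  Returns
    (None, None) when the phase is not coherently monotone along the body
    (standing wave / no travel).
    """
    if frequency is None:
        frequency, _ = beating_frequency(field)
    n_t = field.n_frames
    k_bin = int(round(frequency * n_t / field.fps))
    k_bin = max(1, min(k_bin, n_t // 2))
    w = hann(n_t, sym=False)
    demod = np.exp(-2j * np.pi * k_bin * np.arange(n_t) / n_t)
    rows = (field.sigma >= sigma_range[0]) & (field.sigma <= sigma_range[1])
    comp = ((field.kappa[rows] - field.kappa[rows].mean(axis=1, keepdims=True)) * w * demod).sum(axis=1)
    amp = np.abs(comp)
    if amp.max() <= 0:
        return None, None
    phase = np.unwrap(np.angle(comp))
    s_mm = field.sigma[rows] * field.length_mm
    wgt = amp / amp.sum()
    # weighted least-squares line phase = b*s + c
    sw = (wgt * s_mm).sum()
    pw = (wgt * phase).sum()
    cov = (wgt * (s_mm - sw) * (phase - pw)).sum()
    var = (wgt * (s_mm - sw) ** 2).sum()
    if var == 0:
        return None, None
    slope = cov / var
    resid = phase - pw - slope * (s_mm - sw)
    rms = float(np.sqrt((wgt * resid**2).sum()))
    min_slope = 2.0 * np.pi / (10.0 * field.length_mm)  # wavelength cap: 10 L
    if rms > max_residual_rad or abs(slope) < min_slope:
        return None, None
    lam = 2.0 * np.pi / abs(slope)
    return float(lam * frequency), float(lam)


def time_averaged_curvature(
    field: CurvatureField, order: str = "abs_first", trim: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized time-averaged curvature magnitude vs sigma, end-trimmed.

    ``abs_first`` (default) averages |kappa| over time; ``time_first`` takes
    |mean over time of kappa| (which tends to zero for a zero-mean wave).
    """
    if order == "abs_first":
        prof = np.abs(field.kappa).mean(axis=1)
    elif order == "time_first":
        prof = np.abs(field.kappa.mean(axis=1))
    else:
        raise ValidationError("order", "must be 'abs_first' or 'time_first'")
    keep = (field.sigma >= trim) & (field.sigma <= 1.0 - trim)
    return field.sigma[keep], prof[keep]


def curvature_profile(
    field: CurvatureField,
    order: str = "abs_first",
    trim: float = 0.05,
    eps: float = 1e-9,
) -> CurvatureProfile:
    """Head-normalized curvature profile: trim 5% per end, divide by the
    head-most retained value (which is therefore exactly 1)."""
    sigma, prof = time_averaged_curvature(field, order=order, trim=trim)
    head = prof[0]
    if not head > eps:
        raise NormalizationUndefined("head curvature is (numerically) zero")
    return CurvatureProfile(sigma=sigma, values=prof / head, order=order)


def group_mean_profile(profiles: list) -> CurvatureProfile:
    """Average per-worm normalized profiles on a common grid, renormalized to
    1 at the head-most position."""
    if not profiles:
        raise ValidationError("profiles", "empty group")
    sigma = profiles[0].sigma
    for p in profiles[1:]:
        if len(p.sigma) != len(sigma) or not np.allclose(p.sigma, sigma):
            raise ValidationError("profiles", "profiles are not on a common grid")
    mean = np.mean([p.values for p in profiles], axis=0)
    return CurvatureProfile(sigma=sigma, values=mean / mean[0], order=profiles[0].order)


def summarize_kinematics(
    series: BodyShapeSeries, field: Optional[CurvatureField] = None
) -> KinematicsSummary:
    """U, f, T, wave speed and wavelength for one series; oscillation and
    standing-wave failures are flagged rather than raised."""
    if field is None:
        field = curvature_kymograph(series)
    flags = []
    u = swimming_speed(series)
    try:
        f, t_per = beating_frequency(field)
    except NoOscillation:
        f, t_per = None, None
        flags.append("no_oscillation")
    v, lam = (None, None)
    if f is not None:
        v, lam = wave_speed(field, frequency=f)
        if v is None:
            flags.append("no_traveling_wave")
    return KinematicsSummary(speed=u, frequency=f, period=t_per,
                             wave_speed=v, wavelength=lam, flags=flags)


def plot_kymograph(field: CurvatureField, path=None, ax=None):
    """Render the kymograph (body coordinate vs time, diverging colors;
    positive = counterclockwise bending).  Returns the matplotlib Axes."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    vmax = float(np.abs(field.kappa).max()) or 1.0
    im = ax.imshow(
        field.kappa, aspect="auto", origin="upper", cmap="RdBu_r",
        vmin=-vmax, vmax=vmax,
        extent=[0, field.duration, field.sigma[-1], field.sigma[0]],
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("body coordinate s/L (head = 0)")
    ax.figure.colorbar(im, ax=ax, label=r"curvature $\kappa$ (mm$^{-1}$)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
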