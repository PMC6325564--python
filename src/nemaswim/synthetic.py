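"""Synthetic swimming-worm generator: analytic gaits, rendered movies, cohorts.

The generator is curvature-first: a prescribed traveling curvature wave
kappa(sigma, t) = kappa0 * A(sigma) * S(sigma) * sin(2*pi*(sigma*L0/lambda - f*t))
is integrated to tangent angles and then to coordinates at fixed arclength, so
the ground-truth curvature field is known exactly and the body is inextensible
by construction.  A(sigma) is the head-to-tail amplitude envelope (default
linear decay 1 -> 0.5) and S(sigma) an optional suppression window emulating a
regional loss of neuromuscular function in the mid-tail.

Group presets are parameterized to published biomechanical profile means
(length, swimming speed, beating frequency per genotype and stage), with a
fixed realistic dimensionless wave amplitude kappa0 * L = 6.  Because the
drag-coefficient model ignores the nearby chamber walls it under-predicts
free swimming speed, so a gait prescribing the published speed is only
approximately force-free; ``balanced_speed`` computes the translation speed
at which the resistive-force-theory net force vanishes exactly, and
``calibrate_kappa0`` solves the inverse problem when the target speed is
within reach of the model.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from shapely.geometry import LineString

from .core import BodyShapeSeries, FrameStack
from .errors import CalibrationError, OutOfFieldOfView, ValidationError

__all__ = [
    "SuppressionWindow",
    "GaitParams",
    "RenderConfig",
    "GroundTruth",
    "GroupPreset",
    "WormRecord",
    "Cohort",
    "REFERENCE_GROUP_MEANS",
    "generate_gait",
    "render_movie",
    "make_cohort",
    "preset",
    "preset_names",
    "balanced_speed",
    "calibrate_kappa0",
    "half_width_profile",
    "analytic_curvature",
]

# Published per-group biomechanical profile means and SDs used to parameterize
# the synthetic cohorts (length mm, speed mm/s, frequency Hz, force nN,
# power pW; mean, sd, and group size n).  Force and power are emergent in the
# generator and listed here as reference inputs for worked examples and
# percent-change arithmetic.
REFERENCE_GROUP_MEANS = {
    "n2_l2":         {"n": 22, "length": (0.39, 0.01), "speed": (0.16, 0.06), "frequency": (1.90, 0.39), "force": (0.50, 0.21), "power": (0.50, 0.24)},
    "daf2_l2":       {"n": 24, "length": (0.43, 0.03), "speed": (0.17, 0.04), "frequency": (2.20, 0.42), "force": (0.36, 0.09), "power": (0.57, 0.16)},
    "smn1_l2":       {"n": 28, "length": (0.48, 0.07), "speed": (0.19, 0.06), "frequency": (2.50, 0.52), "force": (0.50, 0.18), "power": (0.88, 0.40)},
    "smn1_daf2_l2":  {"n": 25, "length": (0.45, 0.03), "speed": (0.19, 0.05), "frequency": (2.60, 0.39), "force": (0.42, 0.19), "power": (0.60, 0.30)},
    "n2_late":       {"n": 13, "length": (0.63, 0.08), "speed": (0.26, 0.07), "frequency": (2.30, 0.25), "force": (0.69, 0.27), "power": (1.80, 0.45)},
    "daf2_late":     {"n": 15, "length": (0.70, 0.03), "speed": (0.28, 0.07), "frequency": (2.30, 0.46), "force": (0.66, 0.19), "power": (1.70, 0.57)},
    "smn1_late":     {"n": 20, "length": (0.70, 0.03), "speed": (0.16, 0.04), "frequency": (1.70, 0.36), "force": (0.50, 0.18), "power": (0.97, 0.39)},
    "smn1_daf2_late": {"n": 25, "length": (0.61, 0.07), "speed": (0.18, 0.04), "frequency": (2.30, 0.39), "force": (0.52, 0.11), "power": (1.21, 0.37)},
}

# groups carrying the regional curvature-suppression phenotype, and the factor
# applied inside the window (qualitative emulation; the "defective" preset uses
# the stronger 0.15 factor)
_SUPPRESSED_GROUPS = {"smn1_l2": 0.35, "smn1_late": 0.35}
_SUPPRESSION_WINDOW = (0.5, 0.8)


@dataclass(frozen=True)
class SuppressionWindow:
    """Multiplicative curvature suppression over body coordinates [lo, hi]."""

    lo: float
    hi: float
    factor: float

    def validate(self):
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValidationError("suppression_window", "need 0 <= lo < hi <= 1")
        if not (0.0 <= self.factor <= 1.0):
            raise ValidationError("suppression_factor", "must be in [0, 1]")


EnvelopeLike = Union[str, Callable[[np.ndarray], np.ndarray]]


@dataclass
class GaitParams:
    """Parameters of the prescribed undulatory gait.

    body_length : mm;  frequency : Hz;  speed : mm/s (translation speed along
    ``heading``);  kappa0 : 1/mm peak curvature at the head;  wavelength_frac :
    undulation wavelength as a fraction of body length.
    """

    body_length: float = 0.63
    n_points: int = 100
    frequency: float = 2.3
    wavelength_frac: float = 1.5
    kappa0: float = 6.0
    envelope: EnvelopeLike = "linear"
    envelope_tail: float = 0.5
    suppression: Optional[SuppressionWindow] = None
    speed: float = 0.26
    heading: float = 0.0
    duration: float = 4.0
    fps: float = 30.0
    seed: int = 0
    allow_short: bool = False  # permit <4 cycles (deliberate QC-reject cases)
    check_self_intersection: bool = True

    @property
    def wavelength(self) -> float:
        return self.wavelength_frac * self.body_length

    def validate(self):
        if not self.body_length > 0:
            raise ValidationError("body_length", "must be positive")
        if self.n_points < 5:
            raise ValidationError("n_points", "need at least 5 points")
        if not self.frequency > 0:
            raise ValidationError("frequency", "must be positive")
        if not self.wavelength_frac > 0:
            raise ValidationError("wavelength_frac", "must be positive")
        if self.kappa0 < 0:
            raise ValidationError("kappa0", "must be non-negative")
        if not self.fps >= 8 * self.frequency:
            raise ValidationError("fps", "must be >= 8 * frequency to resolve the wave")
        if self.duration * self.frequency < 4 and not self.allow_short:
            raise ValidationError(
                "duration", "fewer than 4 beat cycles (set allow_short to permit)"
            )
        if not self.speed >= 0:
            raise ValidationError("speed", "must be non-negative")
        if self.suppression is not None:
            self.suppression.validate()

    def envelope_values(self, sigma: np.ndarray) -> np.ndarray:
        if callable(self.envelope):
            return np.asarray(self.envelope(sigma), dtype=float)
        if self.envelope == "linear":
            return 1.0 + (self.envelope_tail - 1.0) * sigma
        if self.envelope == "uniform":
            return np.ones_like(sigma)
        raise ValidationError("envelope", f"unknown envelope tag {self.envelope!r}")


@dataclass
class RenderConfig:
    """How to rasterize a body-shape series into a bright-field-like movie."""

    mm_per_px: float = 0.005
    shape: Optional[tuple] = None  # (height, width); None -> auto-fit
    half_width_mm: float = 0.025  # mid-body half-width a
    taper_frac: float = 0.1  # terminal fraction over which the body tapers
    tip_frac: float = 0.25  # half-width at the very tip, as a fraction of mid
    background: float = 200.0
    worm_depth: float = 120.0  # intensity drop of the worm below background
    noise_sd: float = 8.0
    blur_sd_px: float = 1.0
    margin_px: int = 12
    origin_mm: Optional[tuple] = None  # mm coordinates of pixel (row 0, col 0)
    chamber_center_px: Optional[tuple] = None
    chamber_radius_px: Optional[float] = None
    seed: int = 0

    def validate(self):
        if not self.mm_per_px > 0:
            raise ValidationError("mm_per_px", "must be positive")
        if not self.half_width_mm > 0:
            raise ValidationError("half_width_mm", "must be positive")
        if self.noise_sd > 0 and self.worm_depth < 5 * self.noise_sd:
            raise ValidationError(
                "worm_depth", "worm must be darker than background by >= 5x noise sd"
            )


@dataclass
class GroundTruth:
    """Everything the generator knows; the oracle for round-trip tests."""

    centerlines: np.ndarray  # (frames, n_points, 2) mm
    centroid: np.ndarray  # (frames, 2) mm
    f_true: float
    u_true: float
    lambda_true: float
    kappa_true: np.ndarray  # (n_points - 2, frames), 1/mm on interior grid
    sigma: np.ndarray  # interior body-coordinate grid of kappa_true
    params: Optional[GaitParams] = None
    masks: Optional[np.ndarray] = None  # (frames, h, w) bool, when rendered
    half_widths: Optional[np.ndarray] = None  # (n_points,) mm, when rendered
    mm_per_px: Optional[float] = None
    origin_mm: Optional[tuple] = None


def half_width_profile(
    sigma: np.ndarray, a_mid: float, taper_frac: float = 0.1, tip_frac: float = 0.25
) -> np.ndarray:
    """Body half-width a(sigma): constant mid-body, linear taper at both ends."""
    sigma = np.asarray(sigma, dtype=float)
    a = np.full_like(sigma, a_mid)
    tip = tip_frac * a_mid
    if taper_frac > 0:
        head = sigma < taper_frac
        tail = sigma > 1.0 - taper_frac
        a[head] = tip + (a_mid - tip) * (sigma[head] / taper_frac)
        a[tail] = tip + (a_mid - tip) * ((1.0 - sigma[tail]) / taper_frac)
    return a


def analytic_curvature(params: GaitParams, sigma: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Ground-truth curvature kappa(sigma, t) in 1/mm; shape (len(sigma), len(t))."""
    sigma = np.asarray(sigma, dtype=float)
    t = np.asarray(t, dtype=float)
    amp = params.kappa0 * params.envelope_values(sigma)
    if params.suppression is not None:
        w = params.suppression
        amp = np.where((sigma >= w.lo) & (sigma <= w.hi), amp * w.factor, amp)
    phase = 2.0 * np.pi * (
        sigma[:, None] * params.body_length / params.wavelength - params.frequency * t[None, :]
    )
    return amp[:, None] * np.sin(phase)


def generate_gait(params: GaitParams) -> tuple[BodyShapeSeries, GroundTruth]:
    """Generate an analytic body-shape series with exact ground truth.

    The curvature wave is integrated to tangent angles (cumulative trapezoid),
    the mean tangent is pinned to ``heading``, and coordinates are stepped at
    exactly ds per segment using midpoint angles, so every frame's arclength
    equals body_length to machine precision.  The centroid is then pinned to a
    straight track advancing at ``speed`` along ``heading``.
    """
    params.validate()
    L, n = params.body_length, params.n_points
    n_frames = max(2, int(round(params.duration * params.fps)))
    t = np.arange(n_frames) / params.fps
    sigma = np.linspace(0.0, 1.0, n)
    ds = L / (n - 1)

    kappa = analytic_curvature(params, sigma, t)  # (n, F)
    # theta(sigma) = integral of kappa ds' ; cumulative trapezoid along body
    dtheta = 0.5 * (kappa[1:, :] + kappa[:-1, :]) * ds
    theta = np.vstack([np.zeros((1, n_frames)), np.cumsum(dtheta, axis=0)])
    # the body extends opposite the travel direction so the head leads: the
    # curvature wave runs head->tail and pushes the animal head-first
    theta = theta - theta.mean(axis=0, keepdims=True) + params.heading + math.pi

    theta_mid = 0.5 * (theta[1:, :] + theta[:-1, :])  # segment angles
    steps = np.stack([np.cos(theta_mid), np.sin(theta_mid)], axis=-1) * ds
    pts = np.concatenate(
        [np.zeros((1, n_frames, 2)), np.cumsum(steps, axis=0)], axis=0
    )  # (n, F, 2)
    pts = np.transpose(pts, (1, 0, 2))  # (F, n, 2)

    # pin the centroid to a straight constant-speed track
    e = np.array([math.cos(params.heading), math.sin(params.heading)])
    target = params.speed * t[:, None] * e[None, :]
    pts = pts - pts.mean(axis=1, keepdims=True) + target[:, None, :]

    if params.check_self_intersection and params.kappa0 > 0:
        for i in range(n_frames):
            if not LineString(pts[i]).is_simple:
                raise ValidationError(
                    "kappa0", f"generated centerline self-intersects at frame {i}"
                )

    series = BodyShapeSeries(
        points=pts,
        fps=params.fps,
        meta={"source": "synthetic", "params": params},
    )
    truth = GroundTruth(
        centerlines=pts.copy(),
        centroid=target.copy(),
        f_true=params.frequency,
        u_true=params.speed,
        lambda_true=params.wavelength,
        kappa_true=analytic_curvature(params, sigma[1:-1], t),
        sigma=sigma[1:-1].copy(),
        params=params,
    )
    return series, truth


def _auto_origin_shape(series: BodyShapeSeries, cfg: RenderConfig):
    pad_mm = (cfg.margin_px + 4 * cfg.blur_sd_px) * cfg.mm_per_px + cfg.half_width_mm
    xy = series.points.reshape(-1, 2)
    lo = xy.min(axis=0) - pad_mm
    hi = xy.max(axis=0) + pad_mm
    origin = cfg.origin_mm
    if origin is None:
        origin = (lo[0], lo[1])
    shape = cfg.shape
    if shape is None:
        w = int(np.ceil((hi[0] - origin[0]) / cfg.mm_per_px)) + 1
        h = int(np.ceil((hi[1] - origin[1]) / cfg.mm_per_px)) + 1
        shape = (h, w)
    return origin, shape


def render_movie(
    series: BodyShapeSeries,
    cfg: RenderConfig,
    truth: Optional[GroundTruth] = None,
) -> tuple[FrameStack, GroundTruth]:
    """Rasterize a body-shape series into a noisy bright-field-like movie.

    The worm is drawn as a dark band of local half-width a(sigma) around the
    centerline (a union of disks along a finely resampled midline), then
    blurred and corrupted with additive Gaussian noise.  Ground-truth binary
    masks (pre-blur, pre-noise) are stored on the returned GroundTruth.
    """
    cfg.validate()
    origin, (h, w) = _auto_origin_shape(series, cfg)
    rng = np.random.default_rng(cfg.seed)
    n_frames, n = series.n_frames, series.n_points
    sigma = series.sigma
    a_mm = half_width_profile(sigma, cfg.half_width_mm, cfg.taper_frac, cfg.tip_frac)

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    masks = np.zeros((n_frames, h, w), dtype=bool)
    # fine sampling along the midline (step ~0.4 px)
    s_par = np.linspace(0.0, 1.0, n)
    for i in range(n_frames):
        pts_px = (series.points[i] - np.asarray(origin)) / cfg.mm_per_px  # (n,2) x=col,y=row
        r_px = a_mm / cfg.mm_per_px
        lo = pts_px.min(axis=0) - r_px.max()
        hi = pts_px.max(axis=0) + r_px.max()
        if lo[0] < 0 or lo[1] < 0 or hi[0] > w - 1 or hi[1] > h - 1:
            raise OutOfFieldOfView(i)
        seg_len = np.linalg.norm(np.diff(pts_px, axis=0), axis=1).sum()
        n_fine = max(2 * n, int(seg_len / 0.4))
        s_fine = np.linspace(0.0, 1.0, n_fine)
        cx = np.interp(s_fine, s_par, pts_px[:, 0])
        cy = np.interp(s_fine, s_par, pts_px[:, 1])
        cr = np.interp(s_fine, s_par, r_px)
        mask = masks[i]
        for x, y, r in zip(cx, cy, cr):
            r = max(r, 0.5)
            x0, x1 = int(np.floor(x - r)), int(np.ceil(x + r)) + 1
            y0, y1 = int(np.floor(y - r)), int(np.ceil(y + r)) + 1
            yy, xx = np.mgrid[y0:y1, x0:x1]
            mask[y0:y1, x0:x1] |= (xx - x) ** 2 + (yy - y) ** 2 <= r**2
        img = np.full((h, w), cfg.background, dtype=float)
        img[mask] -= cfg.worm_depth
        if cfg.blur_sd_px > 0:
            img = gaussian_filter(img, cfg.blur_sd_px)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    stack = FrameStack(frames=frames, fps=series.fps, mm_per_px=cfg.mm_per_px)
    if truth is None:
        truth = GroundTruth(
            centerlines=series.points.copy(),
            centroid=series.centroid_track.copy(),
            f_true=float("nan"),
            u_true=float("nan"),
            lambda_true=float("nan"),
            kappa_true=np.empty((0, 0)),
            sigma=np.empty(0),
        )
    else:
        truth = copy.copy(truth)
    truth.masks = masks
    truth.half_widths = a_mm
    truth.mm_per_px = cfg.mm_per_px
    truth.origin_mm = tuple(origin)
    return stack, truth


# ---------------------------------------------------------------------------
# Resistive-force-theory force balance (calibration of the wave amplitude)
# ---------------------------------------------------------------------------

def balanced_speed(
    params: GaitParams,
    mu: float = 1.0,
    model: str = "lighthill",
    n_periods: int = 2,
) -> float:
    """Translation speed at which the period-mean RFT force along the heading
    vanishes, for the deformation wave prescribed by ``params``.

    RFT force is linear in segment velocity, and a rigid translation adds
    linearly to the deformation velocity field, so the balance speed is solved
    in closed form: U* = F0 / d, where F0 is the mean force of the pure
    deformation and d the mean translational drag per unit speed.
    """
    from .dynamics import FluidParams, drag_coefficients, segment_velocities

    p = replace(
        params,
        speed=0.0,
        duration=n_periods / params.frequency,
        allow_short=True,
        check_self_intersection=False,
    )
    series, _ = generate_gait(p)
    fluid = FluidParams(mu=mu)
    a = params.body_length / 25.0
    coef = drag_coefficients(fluid, params.wavelength, a, model=model)
    vel = segment_velocities(series)
    e = np.array([math.cos(params.heading), math.sin(params.heading)])

    # interior frames only (central differences are exact there)
    sl = slice(1, series.n_frames - 1)
    tan, nor, ds = vel.tangents[sl], vel.normals[sl], vel.ds[sl]
    un, ut = vel.u_n[sl], vel.u_t[sl]
    # drag force of the deformation, projected on the heading
    f_seg = -(coef.c_n * un[..., None] * nor + coef.c_t * ut[..., None] * tan)
    f0 = float(np.mean(np.sum(f_seg * ds[..., None] * e, axis=(1, 2))))
    # translational drag per unit speed along the heading
    et = (tan @ e)
    en = (nor @ e)
    d = float(np.mean(np.sum((coef.c_n * en**2 + coef.c_t * et**2) * ds, axis=1)))
    return f0 / d


def calibrate_kappa0(
    params: GaitParams,
    u_target: Optional[float] = None,
    mu: float = 1.0,
    model: str = "lighthill",
    bracket: Optional[tuple] = None,
) -> float:
    """Solve for the head curvature amplitude kappa0 whose force-balanced
    swimming speed equals ``u_target`` (default: params.speed)."""
    if u_target is None:
        u_target = params.speed
    if bracket is None:
        bracket = (0.2 / params.body_length, 8.0 / params.body_length)

    def f(k0):
        return balanced_speed(replace(params, kappa0=k0), mu=mu, model=model) - u_target

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise CalibrationError(
            f"no force-balance root for U={u_target} mm/s in kappa0 bracket {bracket}"
        )
    return float(brentq(f, lo, hi, xtol=1e-4))


# ---------------------------------------------------------------------------
# Presets and cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupPreset:
    """A named group: gait parameters at the group means plus jitter SDs."""

    name: str
    gait: GaitParams
    length_sd: float
    speed_sd: float
    frequency_sd: float
    n_default: int


# fixed dimensionless head-curvature amplitude of the presets (kappa0 * L)
_PRESET_KAPPA0_L = 6.0


@lru_cache(maxsize=None)
def _make_preset(name: str) -> GroupPreset:
    if name == "defective":
        base = _make_preset("n2_late")
        gait = replace(
            base.gait,
            suppression=SuppressionWindow(*_SUPPRESSION_WINDOW, 0.15),
        )
        return GroupPreset(name, gait, base.length_sd, base.speed_sd, base.frequency_sd, base.n_default)
    if name not in REFERENCE_GROUP_MEANS:
        raise ValidationError("preset", f"unknown preset {name!r}")
    ref = REFERENCE_GROUP_MEANS[name]
    supp = None
    if name in _SUPPRESSED_GROUPS:
        supp = SuppressionWindow(*_SUPPRESSION_WINDOW, _SUPPRESSED_GROUPS[name])
    L = ref["length"][0]
    gait = GaitParams(
        body_length=L,
        frequency=ref["frequency"][0],
        speed=ref["speed"][0],
        kappa0=_PRESET_KAPPA0_L / L,
        suppression=supp,
    )
    return GroupPreset(
        name=name,
        gait=gait,
        length_sd=ref["length"][1],
        speed_sd=ref["speed"][1],
        frequency_sd=ref["frequency"][1],
        n_default=ref["n"],
    )


def preset(name: str) -> GroupPreset:
    """Return the named group preset (a fresh copy; cached internally)."""
    p = _make_preset(name)
    return GroupPreset(p.name, replace(p.gait), p.length_sd, p.speed_sd, p.frequency_sd, p.n_default)


def preset_names() -> list:
    return list(REFERENCE_GROUP_MEANS) + ["defective"]


@dataclass
class WormRecord:
    worm_id: str
    group: str
    params: GaitParams
    series: BodyShapeSeries
    truth: GroundTruth
    stack: Optional[FrameStack] = None


@dataclass
class Cohort:
    worms: list = field(default_factory=list)
    seed: Optional[int] = None

    def __len__(self):
        return len(self.worms)

    def by_group(self) -> dict:
        out: dict = {}
        for wrm in self.worms:
            out.setdefault(wrm.group, []).append(wrm)
        return out


def _truncated_normal(rng, mean, sd, lo=None, n_sd=2.5):
    """One draw from N(mean, sd) truncated at +-n_sd and (optionally) above lo."""
    for _ in range(100):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sd * sd and (lo is None or x > lo):
            return x
    return mean


def make_cohort(
    presets: Union[Sequence[str], dict],
    n_per_group: int = 20,
    seed: int = 0,
    render: bool = False,
    render_cfg: Optional[RenderConfig] = None,
    duration: float = 4.0,
) -> Cohort:
    """Generate a labeled cohort with per-worm jitter around group means.

    ``presets`` is a list of preset names, or a mapping {label: GaitParams}.
    Per-worm jitter: length/speed/frequency from the group SDs (or 5% relative
    for explicit GaitParams), mild shape jitter on the envelope tail and
    wavelength, and a random heading.  Fully reproducible from ``seed``.
    """
    if n_per_group < 0:
        raise ValidationError("n_per_group", "must be >= 0")
    rng = np.random.default_rng(seed)
    cohort = Cohort(seed=seed)
    if isinstance(presets, dict):
        items = [(k, None, v) for k, v in presets.items()]
    else:
        items = [(name, preset(name), None) for name in presets]

    for label, grp, gait_override in items:
        base = grp.gait if grp is not None else gait_override
        l_sd = grp.length_sd if grp is not None else 0.05 * base.body_length
        u_sd = grp.speed_sd if grp is not None else 0.05 * base.speed
        f_sd = grp.frequency_sd if grp is not None else 0.05 * base.frequency
        for j in range(n_per_group):
            L = _truncated_normal(rng, base.body_length, l_sd, lo=0.05)
            U = _truncated_normal(rng, base.speed, u_sd, lo=0.0)
            f = _truncated_normal(rng, base.frequency, f_sd, lo=0.2)
            # kappa0 ~ 1/L scaling plus mild lognormal amplitude variability
            k0 = base.kappa0 * (base.body_length / L) * math.exp(rng.normal(0.0, 0.08))
            tail = float(np.clip(rng.normal(base.envelope_tail, 0.05), 0.2, 0.9))
            wfrac = float(np.clip(rng.normal(base.wavelength_frac, 0.05), 0.8, 2.5))
            params = replace(
                base,
                body_length=L,
                speed=U,
                frequency=f,
                kappa0=k0,
                envelope_tail=tail,
                wavelength_frac=wfrac,
                heading=rng.uniform(0.0, 2.0 * np.pi),
                duration=duration,
                seed=int(rng.integers(0, 2**31 - 1)),
                # individual draws may dip below 4 cycles; QC, not the
                # generator, is the inclusion gate for cohort members
                allow_short=True,
            )
            series, truth = generate_gait(params)
            stack = None
            if render:
                cfg = render_cfg if render_cfg is not None else RenderConfig()
                cfg = replace(cfg, seed=params.seed)
                stack, truth = render_movie(series, cfg, truth)
            cohort.worms.append(
                WormRecord(f"{label}_{j:03d}", label, params, series, truth, stack)
            )
    return cohort
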