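"""Core geometric containers: frame stacks, centerlines, and body-shape series.

All physical coordinates are millimetres, time in seconds, with the image
convention x = column, y = row (y increases downward).  Frames are 0-indexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

__all__ = [
    "FrameStack",
    "Centerline",
    "BodyShapeSeries",
    "polyline_arclength",
    "resample_equal_arclength",
]


def polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative chord length of an (n, 2) polyline, starting at 0."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_equal_arclength(
    points: np.ndarray,
    n: int,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> np.ndarray:
    """Resample a polyline to ``n`` points with uniform consecutive spacing.

    Points are always interpolated on the *source* polyline, so repeated
    iterations do not erode curvature; the parameter positions are adjusted
    until consecutive chord lengths are equal to relative tolerance ``tol``.
    Endpoints are preserved exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValidationError("points", "need an (n>=2, 2) polyline")
    if n < 2:
        raise ValidationError("n", "need at least 2 output points")
    # drop exactly duplicated consecutive points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 0])
    pts = pts[keep]
    if len(pts) < 2:
        raise ValidationError("points", "polyline is degenerate (a single point)")
    s = polyline_arclength(pts)
    total = s[-1]
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 2))
    for _ in range(max_iter):
        out[:, 0] = np.interp(t, s, pts[:, 0])
        out[:, 1] = np.interp(t, s, pts[:, 1])
        c = np.linalg.norm(np.diff(out, axis=0), axis=1)
        mean_c = c.mean()
        if mean_c == 0:
            break
        if (c.max() - c.min()) / mean_c < tol:
            break
        # lengthen parameter steps where chords came out short (damped update
        # so strongly curved coarse resamplings still converge)
        dt = np.diff(t) * (mean_c / np.maximum(c, 1e-300)) ** 0.5
        t = np.concatenate([[0.0], np.cumsum(dt)])
        t *= total / t[-1]
    return out


@dataclass
class FrameStack:
    """A grayscale movie with pixel and time calibration."""

    frames: np.ndarray  # (n_frames, height, width)
    fps: float
    mm_per_px: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames", "expected a (frames, height, width) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    def validate(self):
        if self.n_frames < 2:
            raise ValidationError("frames", "need at least 2 frames")
        if not self.fps > 0:
            raise ValidationError("fps", "must be positive")
        if not self.mm_per_px > 0:
            raise ValidationError("mm_per_px", "must be positive")


@dataclass
class Centerline:
    """An ordered head-first body midline for a single frame."""

    points: np.ndarray  # (n, 2) in mm
    half_width: Optional[np.ndarray] = None  # (n,) local half-width in mm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return float(polyline_arclength(self.points)[-1])

    @property
    def sigma(self) -> np.ndarray:
        """Normalized body coordinate s/L in [0, 1], head = 0."""
        s = polyline_arclength(self.points)
        return s / s[-1]


@dataclass
class BodyShapeSeries:
    """The parameterized body shape s(x, y, t): one centerline per frame.

    ``points`` has shape (n_frames, n_points, 2) in mm, consistently oriented
    head-first.  ``half_widths`` (optional) gives the local body half-width
    a(sigma) in mm for each frame/point.
    """

    points: np.ndarray
    fps: float
    half_widths: Optional[np.ndarray] = None
    orientation_confidence: Optional[float] = None
    flags: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValidationError("points", "expected (frames, points, 2)")
        if self.half_widths is not None:
            self.half_widths = np.asarray(self.half_widths, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @property
    def lengths(self) -> np.ndarray:
        """Per-frame body length (polyline arclength) in mm."""
        seg = np.linalg.norm(np.diff(self.points, axis=1), axis=2)
        return seg.sum(axis=1)

    @property
    def length(self) -> float:
        """Time-mean body length in mm."""
        return float(self.lengths.mean())

    @property
    def ds(self) -> np.ndarray:
        """Per-frame segment length L/(n-1) in mm."""
        return self.lengths / (self.n_points - 1)

    @property
    def centroid_track(self) -> np.ndarray:
        """(n_frames, 2) centerline centroid in mm."""
        return self.points.mean(axis=1)

    @property
    def sigma(self) -> np.ndarray:
        """Common normalized body coordinate grid (uniform by construction)."""
        return np.linspace(0.0, 1.0, self.n_points)

    def frame(self, i: int) -> Centerline:
        hw = None if self.half_widths is None else self.half_widths[i]
        return Centerline(self.points[i], hw)
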