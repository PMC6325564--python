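"""Worm tracking: segmentation, centerline extraction, head/tail orientation.

From each bright-field frame the worm is separated from the background (the
largest dark connected component after Otsu thresholding), its topological
skeleton pruned to the longest end-to-end path, extended to the body tips,
smoothed, and resampled to n points equally spaced in arclength.  Orientation
is made temporally consistent frame-to-frame and the head is assigned to the
end with the larger time-averaged curvature magnitude (the head beats with
larger amplitude).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, skeletonize

from .core import BodyShapeSeries, Centerline, FrameStack, resample_equal_arclength
from .errors import NoWormFound, SelfOverlap, TrackFailure, ValidationError

__all__ = [
    "SegmentationConfig",
    "TrackConfig",
    "BodyMask",
    "segment_frame",
    "extract_centerline",
    "orient_head_tail",
    "track_movie",
]


@dataclass
class SegmentationConfig:
    """Body/background separation settings."""

    threshold: Optional[float] = None  # fixed intensity threshold; None -> Otsu
    min_area_px: int = 50
    closing_radius_px: int = 1
    min_contrast: float = 1e-6  # guard against uniform frames


@dataclass
class TrackConfig:
    """Whole-movie tracking settings."""

    n_points: int = 100
    seg: SegmentationConfig = field(default_factory=SegmentationConfig)
    smooth_sigma_px: float = 2.0
    max_bad_frame_fraction: float = 0.2
    max_consecutive_bad: int = 2  # isolated failures (< 3 consecutive) interpolated
    head_override: Optional[str] = None  # "first" or "last" end of the raw order


@dataclass
class BodyMask:
    """Binary worm mask for one frame (exactly one filled component)."""

    mask: np.ndarray  # (h, w) bool
    mm_per_px: float
    touches_border: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_px * self.mm_per_px**2

    @property
    def centroid_mm(self) -> np.ndarray:
        """Mask centroid as (x, y) in mm (intensity-independent)."""
        rows, cols = np.nonzero(self.mask)
        return np.array([cols.mean(), rows.mean()]) * self.mm_per_px


def segment_frame(
    frame: np.ndarray, mm_per_px: float, cfg: Optional[SegmentationConfig] = None
) -> BodyMask:
    """Largest dark connected component, morphologically cleaned, holes filled."""
    cfg = cfg or SegmentationConfig()
    img = np.asarray(frame, dtype=float)
    if img.max() - img.min() <= cfg.min_contrast:
        raise NoWormFound("frame has no contrast (uniform image)")
    thr = cfg.threshold if cfg.threshold is not None else threshold_otsu(img)
    mask = img < thr
    if cfg.closing_radius_px > 0:
        mask = ndimage.binary_closing(mask, structure=disk(cfg.closing_radius_px))
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        raise NoWormFound("no foreground component found")
    sizes = np.bincount(lab.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < cfg.min_area_px:
        raise NoWormFound(f"largest component has {sizes[best - 1]} px < min_area")
    mask = lab == best
    mask = ndimage.binary_fill_holes(mask)
    touches = bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    return BodyMask(mask=mask, mm_per_px=mm_per_px, touches_border=touches)


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray:
    """Longest end-to-end pixel path through a skeleton (double BFS)."""
    pix = np.argwhere(skel)
    if len(pix) < 2:
        raise SelfOverlap("skeleton too small for an end-to-end path")
    index = {tuple(p): i for i, p in enumerate(pix)}
    adj = [[] for _ in range(len(pix))]
    for i, (r, c) in enumerate(pix):
        for dr, dc in _NBRS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)

    def bfs(start):
        prev = np.full(len(pix), -1, dtype=int)
        seen = np.zeros(len(pix), dtype=bool)
        seen[start] = True
        q = deque([start])
        last = start
        while q:
            u = q.popleft()
            last = u
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    prev[v] = u
                    q.append(v)
        return last, prev, seen

    far1, _, seen = bfs(0)
    if not seen.all():
        # disconnected skeleton: keep the component of pixel 0
        pass
    far2, prev, _ = bfs(far1)
    path = [far2]
    while prev[path[-1]] != -1:
        path.append(prev[path[-1]])
    if len(path) < max(3, 0.2 * len(pix)):
        raise SelfOverlap("skeleton has no usable end-to-end path")
    return pix[path[::-1]]  # (m, 2) as (row, col)


def _extend_to_tip(path_xy: np.ndarray, mask: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Extend both path ends along their tangents until leaving the mask
    (the skeleton stops about one body radius short of each tip)."""
    h, w = mask.shape
    out = [path_xy]
    for end in (0, -1):
        k = min(6, len(path_xy) - 1)
        p = path_xy[end]
        d = p - (path_xy[k] if end == 0 else path_xy[-1 - k])
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d = d / norm
        q = p.copy()
        for _ in range(int(40 / step)):
            cand = q + d * step
            r, c = int(round(cand[1])), int(round(cand[0]))
            if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
                break
            q = cand
        if end == 0:
            out.insert(0, q[None, :])
        else:
            out.append(q[None, :])
    return np.vstack(out)


def extract_centerline(
    body: BodyMask, n_points: int = 100, smooth_sigma_px: float = 2.0
) -> Centerline:
    """Ordered centerline from a body mask.

    Skeletonize, prune to the longest end-to-end path, extend to the tips,
    Gaussian-smooth the pixel path, resample to ``n_points`` equally spaced in
    arclength, and read the local half-width from the distance transform.
    """
    mask = ndimage.binary_fill_holes(body.mask)
    skel = skeletonize(mask)
    path_rc = _skeleton_longest_path(skel)
    path_xy = path_rc[:, ::-1].astype(float)  # (m, 2) as (x=col, y=row)
    path_xy = _extend_to_tip(path_xy, mask)
    if smooth_sigma_px > 0 and len(path_xy) > 10:
        sm = ndimage.gaussian_filter1d(path_xy, smooth_sigma_px, axis=0, mode="nearest")
        sm[0], sm[-1] = path_xy[0], path_xy[-1]  # keep the tips
        path_xy = sm
    pts_px = resample_equal_arclength(path_xy, n_points)
    edt = ndimage.distance_transform_edt(mask)
    rows = np.clip(pts_px[:, 1], 0, mask.shape[0] - 1)
    cols = np.clip(pts_px[:, 0], 0, mask.shape[1] - 1)
    half = ndimage.map_coordinates(edt, [rows, cols], order=1)
    return Centerline(points=pts_px * body.mm_per_px,
                      half_width=half * body.mm_per_px)


def _terminal_curvature(points: np.ndarray, frac: float = 0.15) -> tuple[float, float]:
    """Mean |tangent-angle change| over the terminal ``frac`` at each end,
    time-averaged; returns (first_end, last_end)."""
    seg = np.diff(points, axis=1)
    theta = np.unwrap(np.arctan2(seg[..., 1], seg[..., 0]), axis=1)
    dth = np.abs(np.diff(theta, axis=1))
    k = max(2, int(round(frac * dth.shape[1])))
    return float(dth[:, :k].mean()), float(dth[:, -k:].mean())


def orient_head_tail(
    points: np.ndarray,
    fps: float,
    half_widths: Optional[np.ndarray] = None,
    head_override: Optional[str] = None,
    ambiguity_ratio: float = 1.1,
) -> BodyShapeSeries:
    """Make per-frame orientation temporally consistent, then assign the head.

    Per frame the orientation minimizing end-to-end displacement to the
    previous frame is kept; globally, the head is the end with the larger
    time-averaged terminal curvature magnitude.  If the two ends' curvature
    averages differ by less than ``ambiguity_ratio`` the assignment is flagged
    low-confidence (and may be overridden via ``head_override``).
    """
    pts = np.array(points, dtype=float)
    hw = None if half_widths is None else np.array(half_widths, dtype=float)
    flips = 0
    for i in range(1, len(pts)):
        keep = np.linalg.norm(pts[i] - pts[i - 1], axis=1).sum()
        swap = np.linalg.norm(pts[i][::-1] - pts[i - 1], axis=1).sum()
        if swap < keep:
            pts[i] = pts[i][::-1]
            if hw is not None:
                hw[i] = hw[i][::-1]
            flips += 1
    first, last = _terminal_curvature(pts)
    ratio = max(first, last) / max(min(first, last), 1e-300)
    confidence = float(min(1.0, (ratio - 1.0) / (ambiguity_ratio - 1.0)))
    flags = {}
    if ratio < ambiguity_ratio:
        flags["orientation_low_confidence"] = True
    head_first = first >= last
    if head_override is not None:
        head_first = head_override == "first"
    if not head_first:
        pts = pts[:, ::-1]
        if hw is not None:
            hw = hw[:, ::-1]
    flags["orientation_flips_repaired"] = flips
    return BodyShapeSeries(points=pts, fps=fps, half_widths=hw,
                           orientation_confidence=confidence, flags=flags)


def track_movie(stack: FrameStack, cfg: Optional[TrackConfig] = None) -> BodyShapeSeries:
    """Segment + extract + orient every frame of a movie.

    Frames failing extraction are linearly interpolated when isolated
    (< 3 consecutive); longer runs, or more than ``max_bad_frame_fraction`` of
    the movie, raise TrackFailure.
    """
    cfg = cfg or TrackConfig()
    stack.validate()
    n_frames = stack.n_frames
    raw = np.full((n_frames, cfg.n_points, 2), np.nan)
    widths = np.full((n_frames, cfg.n_points), np.nan)
    bad = []
    border_frames = []
    for i in range(n_frames):
        try:
            body = segment_frame(stack.frames[i], stack.mm_per_px, cfg.seg)
            if body.touches_border:
                border_frames.append(i)
            cl = extract_centerline(body, cfg.n_points, cfg.smooth_sigma_px)
            raw[i] = cl.points
            widths[i] = cl.half_width
        except (NoWormFound, SelfOverlap, ValidationError):
            bad.append(i)
    if bad:
        if len(bad) / n_frames > cfg.max_bad_frame_fraction:
            raise TrackFailure(
                f"{len(bad)}/{n_frames} frames unextractable (> max_bad_frame_fraction)"
            )
        runs = np.split(np.asarray(bad), np.nonzero(np.diff(bad) > 1)[0] + 1)
        if max(len(r) for r in runs) > cfg.max_consecutive_bad:
            raise TrackFailure("a run of >= 3 consecutive frames failed extraction")
        good = np.setdiff1d(np.arange(n_frames), bad)
        if len(good) < 2 or bad[0] < good[0] or bad[-1] > good[-1]:
            raise TrackFailure("cannot interpolate failures at the movie ends")
        # align neighbouring good frames before interpolating across a gap
        for i in range(1, n_frames):
            if np.isnan(raw[i, 0, 0]):
                continue
            prev = i - 1
            while prev >= 0 and np.isnan(raw[prev, 0, 0]):
                prev -= 1
            if prev < 0:
                continue
            keep = np.linalg.norm(raw[i] - raw[prev], axis=1).sum()
            swap = np.linalg.norm(raw[i][::-1] - raw[prev], axis=1).sum()
            if swap < keep:
                raw[i] = raw[i][::-1]
                widths[i] = widths[i][::-1]
        for arr in (raw, widths):
            flat = arr.reshape(n_frames, -1)
            for col in range(flat.shape[1]):
                flat[bad, col] = np.interp(bad, good, flat[good, col])
    series = orient_head_tail(raw, stack.fps, widths, cfg.head_override)
    series.flags["interpolated_frames"] = list(map(int, bad))
    series.flags["border_frames"] = list(map(int, border_frames))
    series.meta["mm_per_px"] = stack.mm_per_px
    return series
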