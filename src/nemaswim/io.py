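"""Reading and writing movies, centerline series, and cohort manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import BodyShapeSeries, FrameStack
from .errors import ValidationError

__all__ = [
    "write_stack",
    "read_stack",
    "write_series_csv",
    "read_series_csv",
    "write_kymograph_csv",
    "read_kymograph_csv",
    "write_cohort_manifest",
    "write_qc_report",
]


def write_stack(stack: FrameStack, path, fmt: Optional[str] = None):
    """Write frames as a multi-page 8-bit TIFF, or a numbered PNG sequence
    when ``path`` is a directory (or fmt='png')."""
    path = Path(path)
    frames = stack.frames
    if frames.dtype != np.uint8:
        frames = np.clip(frames, 0, 255).astype(np.uint8)
    if fmt == "png" or (fmt is None and path.suffix == ""):
        path.mkdir(parents=True, exist_ok=True)
        for i, fr in enumerate(frames):
            iio.imwrite(path / f"frame_{i:05d}.png", fr)
        meta = {"fps": stack.fps, "mm_per_px": stack.mm_per_px}
        (path / "stack.json").write_text(json.dumps(meta, indent=1))
    else:
        tifffile.imwrite(path, frames, photometric="minisblack",
                         metadata={"fps": stack.fps, "mm_per_px": stack.mm_per_px})


def read_stack(path, fps: Optional[float] = None, mm_per_px: Optional[float] = None) -> FrameStack:
    """Read a multi-page TIFF or a directory of numbered PNGs."""
    path = Path(path)
    if path.is_dir():
        meta_path = path / "stack.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            fps = fps if fps is not None else meta.get("fps")
            mm_per_px = mm_per_px if mm_per_px is not None else meta.get("mm_per_px")
        files = sorted(path.glob("frame_*.png")) or sorted(path.glob("*.png"))
        if not files:
            raise ValidationError("path", f"no PNG frames found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    if fps is None or mm_per_px is None:
        raise ValidationError("fps/mm_per_px", "calibration required but not supplied")
    return FrameStack(frames=frames, fps=float(fps), mm_per_px=float(mm_per_px))


def write_series_csv(series: BodyShapeSeries, path, sidecar: bool = True):
    """Long-format centerline CSV (frame, point_index, x_mm, y_mm, sigma,
    half_width_mm) plus a JSON sidecar with calibration and flags."""
    path = Path(path)
    n_f, n_p = series.n_frames, series.n_points
    frame_idx = np.repeat(np.arange(n_f), n_p)
    point_idx = np.tile(np.arange(n_p), n_f)
    sigma = np.tile(series.sigma, n_f)
    df = pd.DataFrame({
        "frame": frame_idx,
        "point_index": point_idx,
        "x_mm": series.points[..., 0].ravel(),
        "y_mm": series.points[..., 1].ravel(),
        "sigma": sigma,
        "half_width_mm": (series.half_widths.ravel() if series.half_widths is not None
                          else np.full(n_f * n_p, np.nan)),
    })
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")
    if sidecar:
        meta = {
            "fps": series.fps,
            "n_frames": n_f,
            "n_points": n_p,
            "orientation_confidence": series.orientation_confidence,
            "flags": series.flags,
            "mm_per_px": series.meta.get("mm_per_px"),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, default=str))


def read_series_csv(path, fps: Optional[float] = None) -> BodyShapeSeries:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    fps = fps if fps is not None else meta.get("fps")
    if fps is None:
        raise ValidationError("fps", "fps required (no sidecar found)")
    n_f = int(df["frame"].max()) + 1
    n_p = int(df["point_index"].max()) + 1
    pts = np.column_stack([df["x_mm"], df["y_mm"]]).reshape(n_f, n_p, 2)
    hw = df["half_width_mm"].to_numpy().reshape(n_f, n_p)
    if np.isnan(hw).all():
        hw = None
    return BodyShapeSeries(points=pts, fps=float(fps), half_widths=hw,
                           flags=meta.get("flags", {}), meta=meta)


def write_kymograph_csv(field, path, sidecar: bool = True):
    """Curvature field as a CSV matrix (rows = body coordinate, columns =
    frames) plus a JSON sidecar with fps, body length and the sigma grid."""
    path = Path(path)
    df = pd.DataFrame(field.kappa, index=field.sigma)
    df.index.name = "sigma"
    df.to_csv(path, float_format="%.9g", lineterminator="\n")
    if sidecar:
        meta = {"fps": field.fps, "length_mm": field.length_mm,
                "n_frames": field.n_frames, "sigma": list(map(float, field.sigma))}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_kymograph_csv(path, fps: Optional[float] = None, length_mm: Optional[float] = None):
    from .kinematics import CurvatureField

    path = Path(path)
    df = pd.read_csv(path, index_col="sigma")
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    fps = fps if fps is not None else meta.get("fps")
    length_mm = length_mm if length_mm is not None else meta.get("length_mm")
    if fps is None or length_mm is None:
        raise ValidationError("fps/length_mm", "calibration required (no sidecar found)")
    return CurvatureField(kappa=df.to_numpy(), sigma=df.index.to_numpy(float),
                          fps=float(fps), length_mm=float(length_mm))


def write_cohort_manifest(cohort, path):
    """JSON manifest of a synthetic cohort (worm ids, groups, true parameters)."""
    records = []
    for w in cohort.worms:
        records.append({
            "worm_id": w.worm_id,
            "group": w.group,
            "body_length_mm": w.params.body_length,
            "frequency_hz": w.params.frequency,
            "speed_mm_s": w.params.speed,
            "kappa0_per_mm": w.params.kappa0,
            "wavelength_mm": w.params.wavelength,
            "seed": w.params.seed,
            "rendered": w.stack is not None,
        })
    Path(path).write_text(json.dumps({"seed": cohort.seed, "worms": records}, indent=1))


def write_qc_report(results: dict, path):
    """Per-movie QC report CSV: movie id, accepted, reasons, metrics."""
    rows = []
    for movie_id, res in results.items():
        row = {"movie_id": movie_id, "accepted": res.accepted,
               "reasons": ";".join(res.reasons)}
        row.update(res.metrics)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g",
                              lineterminator="\n")
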