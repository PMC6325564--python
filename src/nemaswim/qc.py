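"""Movie inclusion criteria applied before any statistic is computed.

A movie is discarded when it shows worm-wall interactions, interrupted or
irregular beating, or fewer than four beating cycles.  "Irregular beating" is
operationalized as a coefficient of variation of successive cycle periods
above a configurable threshold (default 0.3), and the wall margin defaults to
one body radius; both are declared surrogates for judgements the original
criteria leave unspecified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np

from .core import BodyShapeSeries
from .errors import NoOscillation
from .kinematics import CurvatureField, KinematicsSummary, curvature_kymograph, cycle_count_frequency

__all__ = ["ChamberGeometry", "QCConfig", "QCResult", "qc_movie"]


@dataclass(frozen=True)
class ChamberGeometry:
    """Circular swim chamber: center (x, y) and radius, in mm."""

    center_mm: tuple
    radius_mm: float


@dataclass
class QCConfig:
    min_cycles: float = 4.0
    cycle_tolerance: float = 0.05  # exactly-4-cycles passes despite estimator jitter
    irregular_cv: float = 0.3
    wall_margin_mm: Optional[float] = None  # None -> one body radius


@dataclass
class QCResult:
    accepted: bool
    reasons: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)


def _body_radius(series: BodyShapeSeries) -> float:
    if series.half_widths is not None and np.isfinite(series.half_widths).any():
        return float(np.nanmedian(series.half_widths))
    return series.length / 25.0


def qc_movie(
    series: BodyShapeSeries,
    kin: KinematicsSummary,
    chamber: Optional[ChamberGeometry] = None,
    cfg: Optional[QCConfig] = None,
    field_: Optional[CurvatureField] = None,
) -> QCResult:
    """Accept/reject one tracked movie against the inclusion criteria.

    Missing chamber geometry skips the wall check with a warning (not a
    failure).  ``accepted`` is True iff ``reasons`` is empty.
    """
    cfg = cfg or QCConfig()
    reasons = []
    metrics: dict = {}

    f = kin.frequency
    if f is None:
        reasons.append("irregular_beating")
        metrics["cycles"] = float("nan")
    else:
        cycles = series.duration * f
        metrics["cycles"] = float(cycles)
        if cycles < cfg.min_cycles - cfg.cycle_tolerance:
            reasons.append("too_few_cycles")
        try:
            if field_ is None:
                field_ = curvature_kymograph(series)
            _, periods = cycle_count_frequency(field_)
            if len(periods) >= 3:
                cv = float(periods.std() / periods.mean())
                metrics["cycle_period_cv"] = cv
                if cv > cfg.irregular_cv:
                    reasons.append("irregular_beating")
        except NoOscillation:
            if "irregular_beating" not in reasons:
                reasons.append("irregular_beating")

    if "track_failure" in series.flags.get("reasons", []):
        reasons.append("track_failure")

    if chamber is None:
        warnings.warn("no chamber geometry supplied; wall-interaction check skipped")
    else:
        center = np.asarray(chamber.center_mm, dtype=float)
        dist_center = np.linalg.norm(series.points - center, axis=2)
        wall_dist = chamber.radius_mm - dist_center
        metrics["min_wall_distance_mm"] = float(wall_dist.min())
        margin = cfg.wall_margin_mm if cfg.wall_margin_mm is not None else _body_radius(series)
        if wall_dist.min() < margin:
            reasons.append("wall_interaction")

    return QCResult(accepted=not reasons, reasons=reasons, metrics=metrics)
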