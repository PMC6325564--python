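"""Shared fixtures: analytic gaits and one rendered/tracked movie per session."""

from dataclasses import replace

import numpy as np
import pytest

from nemaswim import GaitParams, RenderConfig, generate_gait, render_movie, track_movie
from nemaswim.synthetic import preset


@pytest.fixture(scope="session")
def n2_late_gait() -> GaitParams:
    """N2-late-like preset: L = 0.63 mm, f = 2.3 Hz, U = 0.26 mm/s."""
    return preset("n2_late").gait


@pytest.fixture(scope="session")
def clean_series(n2_late_gait):
    """4-second analytic gait at the N2-late preset."""
    return generate_gait(n2_late_gait)


@pytest.fixture(scope="session")
def rendered_movie(n2_late_gait):
    """A rendered 3-second movie of the N2-late preset, with ground truth."""
    params = replace(n2_late_gait, duration=3.0)
    series, truth = generate_gait(params)
    stack, truth = render_movie(series, RenderConfig(seed=7), truth)
    return stack, truth, params


@pytest.fixture(scope="session")
def tracked_series(rendered_movie):
    stack, truth, params = rendered_movie
    return track_movie(stack)


def dense_polyline(points: np.ndarray, n: int = 1000) -> np.ndarray:
    """Linearly upsampled polyline for point-to-curve distance checks."""
    s = np.linspace(0.0, 1.0, len(points))
    f = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(f, s, points[:, 0]), np.interp(f, s, points[:, 1])])


def mean_distance_to_truth_px(tracked, truth, frame: int) -> float:
    """Mean distance (px) from tracked points to the true centerline."""
    from scipy.spatial import cKDTree

    origin = np.asarray(truth.origin_mm)
    dense = dense_polyline(truth.centerlines[frame] - origin)
    d, _ = cKDTree(dense).query(tracked.points[frame])
    return float(d.mean() / truth.mm_per_px)
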