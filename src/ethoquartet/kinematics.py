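"""Per-animal kinematics: speed, body length, wall proximity."""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .model import AnimalTrack, TrajectorySet

__all__ = ["speed_cm_s", "body_length_cm", "mean_body_length_cm", "near_wall"]


def speed_cm_s(track: AnimalTrack, fps: float) -> np.ndarray:
    """Mass-centre speed by centred difference, forward/backward at the ends.

    speed[t] = |p[t+1] - p[t-1]| / 2 * fps; undetected frames get NaN
    (they are ineligible for both the move and the idle predicate).
    """
    p = track.center
    n = len(p)
    if n < 2:
        raise ValueError("speed needs at least 2 frames")
    speed = np.empty(n)
    speed[1:-1] = np.hypot(*(p[2:] - p[:-2]).T) / 2.0 * fps
    speed[0] = np.hypot(*(p[1] - p[0])) * fps
    speed[-1] = np.hypot(*(p[-1] - p[-2])) * fps
    speed[~track.detected] = np.nan
    return speed


def body_length_cm(track: AnimalTrack) -> np.ndarray:
    """Nose to tail-base distance per frame."""
    return np.hypot(*(track.nose - track.tail).T)


def mean_body_length_cm(traj: TrajectorySet) -> float:
    """Mean body length over all animals' detected frames."""
    vals = []
    for aid in traj.animals:
        t = traj.track(aid)
        bl = body_length_cm(t)[t.detected]
        if bl.size:
            vals.append(bl)
    if not vals:
        raise ValueError("no detected frames in trajectory set")
    return float(np.concatenate(vals).mean())


def near_wall(track: AnimalTrack, traj: TrajectorySet, config: AnalysisConfig) -> np.ndarray:
    """True where the mass centre is within wall_distance_cm of the boundary."""
    w, h = traj.arena_size_cm
    x, y = track.center[:, 0], track.center[:, 1]
    d = config.wall_distance_cm
    return (x < d) | (y < d) | (x > w - d) | (y > h - d)
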