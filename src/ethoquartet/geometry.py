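"""Vectorised pair geometry: body-body distances and heading angles.

A body is modelled as a two-segment polyline (nose-centre, centre-tail);
"touching" means the minimum inter-polyline distance is below the contact
threshold.  Heading is the direction of the tail-to-nose vector; heading
differences live on [0, 180] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .model import AnimalTrack, TrajectorySet

__all__ = ["PairMasks", "compute_pair_masks", "segments_min_distance", "heading_deg"]


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points ``p`` to segments ``a``-``b`` (all (N, 2))."""
    ab = b - a
    ap = p - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.divide(
        np.einsum("ij,ij->i", ap, ab), denom,
        out=np.zeros_like(denom), where=denom > 0,
    )
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.hypot(*(p - closest).T)


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, 0] - o[:, 0]) * (b[:, 1] - o[:, 1]) - (
        a[:, 1] - o[:, 1]
    ) * (b[:, 0] - o[:, 0])


def _segments_intersect(
    p1: np.ndarray, p2: np.ndarray, q1: np.ndarray, q2: np.ndarray
) -> np.ndarray:
    """Proper intersection test for segment batches (collinear overlaps are
    caught by the endpoint-distance terms, which are then 0)."""
    d1 = _cross(q1, q2, p1)
    d2 = _cross(q1, q2, p2)
    d3 = _cross(p1, p2, q1)
    d4 = _cross(p1, p2, q2)
    return ((d1 * d2) < 0) & ((d3 * d4) < 0)


def segments_min_distance(
    p1: np.ndarray, p2: np.ndarray, q1: np.ndarray, q2: np.ndarray
) -> np.ndarray:
    """Minimum distance between segment batches p1-p2 and q1-q2."""
    d = np.minimum.reduce(
        [
            _point_segment_distance(p1, q1, q2),
            _point_segment_distance(p2, q1, q2),
            _point_segment_distance(q1, p1, p2),
            _point_segment_distance(q2, p1, p2),
        ]
    )
    d[_segments_intersect(p1, p2, q1, q2)] = 0.0
    return d


def body_min_distance(a: AnimalTrack, b: AnimalTrack) -> np.ndarray:
    """Min distance between the two-segment body polylines, per frame."""
    segs_a = ((a.nose, a.center), (a.center, a.tail))
    segs_b = ((b.nose, b.center), (b.center, b.tail))
    return np.minimum.reduce(
        [
            segments_min_distance(p1, p2, q1, q2)
            for p1, p2 in segs_a
            for q1, q2 in segs_b
        ]
    )


def heading_deg(track: AnimalTrack) -> np.ndarray:
    """Heading of the tail-to-nose vector in degrees, per frame."""
    v = track.nose - track.tail
    return np.degrees(np.arctan2(v[:, 1], v[:, 0]))


def heading_difference_deg(ha: np.ndarray, hb: np.ndarray) -> np.ndarray:
    """Absolute heading difference wrapped to [0, 180]."""
    d = np.abs(ha - hb) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


@dataclass
class PairMasks:
    """Per-frame contact predicates for one unordered pair (a, b), a < b.

    ``nose_ano_ab`` is directed: a's nose at whisker distance from b's tail
    base.  All masks are False on frames where either animal is undetected.
    """

    a: str
    b: str
    distance: np.ndarray       # min body-body distance, cm
    nose_nose_cm: np.ndarray
    angle_diff: np.ndarray     # deg in [0, 180]
    contact: np.ndarray        # bool
    nose_nose: np.ndarray
    nose_ano_ab: np.ndarray
    nose_ano_ba: np.ndarray
    side_side: np.ndarray
    side_side_htt: np.ndarray


def compute_pair_masks(
    traj: TrajectorySet, config: AnalysisConfig
) -> dict[tuple[str, str], PairMasks]:
    """Geometry predicates for every unordered pair in the trajectory set."""
    out: dict[tuple[str, str], PairMasks] = {}
    headings = {aid: heading_deg(traj.track(aid)) for aid in traj.animals}
    for a, b in traj.pairs():
        ta, tb = traj.track(a), traj.track(b)
        both = ta.detected & tb.detected
        dist = body_min_distance(ta, tb)
        nn_cm = np.hypot(*(ta.nose - tb.nose).T)
        ang = heading_difference_deg(headings[a], headings[b])
        contact = both & (dist < config.contact_distance_cm)
        nn = both & (nn_cm < config.whisker_distance_cm)
        ng_ab = both & (
            np.hypot(*(ta.nose - tb.tail).T) < config.whisker_distance_cm
        )
        ng_ba = both & (
            np.hypot(*(tb.nose - ta.tail).T) < config.whisker_distance_cm
        )
        ss = contact & (ang <= config.side_side_angle_deg)
        ss_htt = contact & (ang >= 180.0 - config.side_side_angle_deg)
        out[(a, b)] = PairMasks(
            a=a, b=b, distance=dist, nose_nose_cm=nn_cm, angle_diff=ang,
            contact=contact, nose_nose=nn, nose_ano_ab=ng_ab,
            nose_ano_ba=ng_ba, side_side=ss, side_side_htt=ss_htt,
        )
    return out
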