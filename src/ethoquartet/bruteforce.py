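"""Naive per-frame reference labeller.

A deliberately simple, loop-based re-implementation of every per-frame
event predicate, kept free of the vectorised code in
:mod:`ethoquartet.detection` / :mod:`ethoquartet.geometry` so the two
routes can be checked against each other (interval output must equal the
brute-force labels after run-length encoding).  Orders of magnitude slower
than the detector; use on short recordings only.
"""

from __future__ import annotations

import math

import numpy as np

from .config import AnalysisConfig
from .model import TrajectorySet

__all__ = [
    "brute_force_masks",
    "brute_force_exclusive_labels",
    "compare_detector_to_bruteforce",
]


def _pt_seg(px, py, ax, ay, bx, by):
    """Scalar point-to-segment distance."""
    dx, dy = bx - ax, by - ay
    dd = dx * dx + dy * dy
    if dd == 0.0:
        return math.hypot(px - ax, py - ay)
    t = ((px - ax) * dx + (py - ay) * dy) / dd
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    return math.hypot(px - (ax + t * dx), py - (ay + t * dy))


def _seg_seg(p1, p2, q1, q2):
    """Scalar segment-to-segment distance."""
    def orient(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    if d1 * d2 < 0 and d3 * d4 < 0:
        return 0.0
    return min(
        _pt_seg(p1[0], p1[1], q1[0], q1[1], q2[0], q2[1]),
        _pt_seg(p2[0], p2[1], q1[0], q1[1], q2[0], q2[1]),
        _pt_seg(q1[0], q1[1], p1[0], p1[1], p2[0], p2[1]),
        _pt_seg(q2[0], q2[1], p1[0], p1[1], p2[0], p2[1]),
    )


def _body_dist(ta, tb, t):
    segs_a = [(ta.nose[t], ta.center[t]), (ta.center[t], ta.tail[t])]
    segs_b = [(tb.nose[t], tb.center[t]), (tb.center[t], tb.tail[t])]
    return min(_seg_seg(p1, p2, q1, q2) for p1, p2 in segs_a for q1, q2 in segs_b)


def _heading(track, t):
    v = track.nose[t] - track.tail[t]
    return math.degrees(math.atan2(v[1], v[0]))


def _ang_diff(a, b):
    d = abs(a - b) % 360.0
    return 360.0 - d if d > 180.0 else d


def _speed(track, t, n, fps):
    if not track.detected[t]:
        return float("nan")
    if t == 0:
        p, q = track.center[1], track.center[0]
        return math.hypot(p[0] - q[0], p[1] - q[1]) * fps
    if t == n - 1:
        p, q = track.center[n - 1], track.center[n - 2]
        return math.hypot(p[0] - q[0], p[1] - q[1]) * fps
    p, q = track.center[t + 1], track.center[t - 1]
    return math.hypot(p[0] - q[0], p[1] - q[1]) / 2.0 * fps


def brute_force_masks(traj: TrajectorySet, config: AnalysisConfig) -> dict:
    """Per-frame labels for every per-frame-defined event type.

    Returns a dict with:

    - ``pair``: (a, b) -> {"contact", "nose-nose", "side-side",
      "side-side head-to-tail"} -> bool array
    - ``directed``: (a, b) -> {"nose-anogenital", "follow", "train2"} ->
      bool array (a is the actor/follower)
    - ``single``: animal -> {"single move", "move in contact",
      "single idle", "rearing", "rearing in contact", "jump",
      "group of 2", "group of 3"} -> bool array
    """
    n = traj.n_frames
    fps = traj.fps
    animals = traj.animals
    w, h = traj.arena_size_cm

    # mean body length over detected frames, by straightforward loops
    total, count = 0.0, 0
    for aid in animals:
        tr = traj.track(aid)
        for t in range(n):
            if tr.detected[t]:
                total += math.hypot(
                    tr.nose[t][0] - tr.tail[t][0], tr.nose[t][1] - tr.tail[t][1]
                )
                count += 1
    mean_bl = total / count

    speeds = {
        aid: [_speed(traj.track(aid), t, n, fps) for t in range(n)]
        for aid in animals
    }

    pair: dict = {}
    directed: dict = {}
    pairs = traj.pairs()
    for a, b in pairs:
        pair[(a, b)] = {
            k: np.zeros(n, bool)
            for k in ("contact", "nose-nose", "side-side",
                      "side-side head-to-tail")
        }
        for x, y in ((a, b), (b, a)):
            directed[(x, y)] = {
                k: np.zeros(n, bool) for k in ("nose-anogenital", "follow",
                                               "train2")
            }
    for a, b in pairs:
        ta, tb = traj.track(a), traj.track(b)
        for t in range(n):
            if not (ta.detected[t] and tb.detected[t]):
                continue
            dist = _body_dist(ta, tb, t)
            contact = dist < config.contact_distance_cm
            nn = (
                math.hypot(*(ta.nose[t] - tb.nose[t]))
                < config.whisker_distance_cm
            )
            ng_ab = (
                math.hypot(*(ta.nose[t] - tb.tail[t]))
                < config.whisker_distance_cm
            )
            ng_ba = (
                math.hypot(*(tb.nose[t] - ta.tail[t]))
                < config.whisker_distance_cm
            )
            ang = _ang_diff(_heading(ta, t), _heading(tb, t))
            pair[(a, b)]["contact"][t] = contact
            pair[(a, b)]["nose-nose"][t] = nn
            pair[(a, b)]["side-side"][t] = (
                contact and ang <= config.side_side_angle_deg
            )
            pair[(a, b)]["side-side head-to-tail"][t] = (
                contact and ang >= 180.0 - config.side_side_angle_deg
            )
            directed[(a, b)]["nose-anogenital"][t] = ng_ab
            directed[(b, a)]["nose-anogenital"][t] = ng_ba
            # follow / train2, both directions
            for follower, leader, ng in ((a, b, ng_ab), (b, a, ng_ba)):
                sf = speeds[follower][t]
                sl = speeds[leader][t]
                if not (
                    sf == sf and sl == sl  # NaN checks
                    and sf > config.speed_threshold_cm_s
                    and sl > config.speed_threshold_cm_s
                    and ang < config.side_side_angle_deg
                ):
                    continue
                tl = traj.track(leader)
                tf = traj.track(follower)
                hl = math.radians(_heading(tl, t))
                ux, uy = math.cos(hl), math.sin(hl)
                rx = tf.center[t][0] - tl.center[t][0]
                ry = tf.center[t][1] - tl.center[t][1]
                behind = -(rx * ux + ry * uy)
                lateral = rx * uy - ry * ux
                in_zone = (
                    0.0 <= behind <= config.follow_zone_length_bl * mean_bl
                    and abs(lateral) <= 0.5 * config.follow_zone_width_bl * mean_bl
                )
                if in_zone:
                    directed[(follower, leader)]["follow"][t] = True
                    if ng:
                        directed[(follower, leader)]["train2"][t] = True

    single: dict = {
        aid: {
            k: np.zeros(n, bool)
            for k in ("single move", "move in contact", "single idle",
                      "rearing", "rearing in contact", "jump",
                      "group of 2", "group of 3")
        }
        for aid in animals
    }
    for aid in animals:
        tr = traj.track(aid)
        others = [x for x in animals if x != aid]
        for t in range(n):
            if not tr.detected[t]:
                continue
            n_partners = 0
            for other in others:
                key = (aid, other) if aid < other else (other, aid)
                if pair[key]["contact"][t]:
                    n_partners += 1
            in_contact = n_partners > 0
            sp = speeds[aid][t]
            moving = sp == sp and sp > config.speed_threshold_cm_s
            resting = sp == sp and sp <= config.speed_threshold_cm_s
            single[aid]["single move"][t] = moving and not in_contact
            single[aid]["move in contact"][t] = moving and in_contact
            single[aid]["single idle"][t] = resting and not in_contact
            rearing = tr.body_slope[t] > config.slope_threshold
            single[aid]["rearing"][t] = rearing and not in_contact
            single[aid]["rearing in contact"][t] = rearing and in_contact
            x, y = tr.center[t]
            wall = (
                x < config.wall_distance_cm or y < config.wall_distance_cm
                or x > w - config.wall_distance_cm
                or y > h - config.wall_distance_cm
            )
            single[aid]["jump"][t] = (
                wall and sp == sp and sp > config.jump_speed_cm_s
            )
            single[aid]["group of 2"][t] = n_partners == 1
            single[aid]["group of 3"][t] = n_partners == 2
    return {"pair": pair, "directed": directed, "single": single}


def brute_force_exclusive_labels(
    traj: TrajectorySet, config: AnalysisConfig
) -> dict[str, list[str]]:
    """Exclusive per-frame labels by an explicit per-frame precedence scan."""
    masks = brute_force_masks(traj, config)
    n = traj.n_frames
    out: dict[str, list[str]] = {}
    for aid in traj.animals:
        tr = traj.track(aid)
        others = [x for x in traj.animals if x != aid]
        labels = []
        for t in range(n):
            if not tr.detected[t]:
                labels.append("undetected")
                continue
            nn = ng = ng_pass = ss = ss_htt = contact = False
            nn_ss = ng_htt = ng_pass_htt = False
            for other in others:
                key = (aid, other) if aid < other else (other, aid)
                pm = masks["pair"][key]
                c_t = pm["contact"][t]
                nn_t = pm["nose-nose"][t]
                ss_t = pm["side-side"][t]
                htt_t = pm["side-side head-to-tail"][t]
                ng_t = masks["directed"][(aid, other)]["nose-anogenital"][t]
                ngp_t = masks["directed"][(other, aid)]["nose-anogenital"][t]
                contact |= c_t
                nn |= nn_t
                ng |= ng_t
                ng_pass |= ngp_t
                ss |= ss_t
                ss_htt |= htt_t
                nn_ss |= nn_t and ss_t
                ng_htt |= ng_t and htt_t
                ng_pass_htt |= ngp_t and htt_t
            if nn_ss:
                labels.append("nose-nose & side-side")
            elif ng_htt:
                labels.append("nose-anogenital & side-side head-to-tail")
            elif ng_pass_htt:
                labels.append("passive nose-anogenital & side-side head-to-tail")
            elif nn:
                labels.append("nose-nose")
            elif ng:
                labels.append("nose-anogenital")
            elif ng_pass:
                labels.append("passive nose-anogenital")
            elif ss:
                labels.append("side-side")
            elif ss_htt:
                labels.append("side-side head-to-tail")
            elif contact:
                labels.append("other contact")
            else:
                sp = _speed(tr, t, n, traj.fps)
                if sp == sp and sp > config.speed_threshold_cm_s:
                    labels.append("move")
                else:
                    labels.append("idle")
        out[aid] = labels
    return out


def compare_detector_to_bruteforce(
    traj: TrajectorySet, config: AnalysisConfig, ethogram=None
) -> dict[str, int]:
    """Mismatching frame counts, detector vs brute force, per event type.

    Runs the vectorised detector and the naive labeller on the same
    trajectory and counts, for every per-frame-defined event type, frames
    where the rasterised detector intervals disagree with the brute-force
    labels.  An all-zero result means the two routes are equivalent (the
    intervals equal the run-length encoding of the brute-force labels).
    """
    from .detection import detect_all

    eth = ethogram if ethogram is not None else detect_all(traj, config)
    bf = brute_force_masks(traj, config)
    n = traj.n_frames
    mism: dict[str, int] = {}
    for (a, b), masks in bf["pair"].items():
        for name, mask in masks.items():
            det = eth.mask(n, name, actor=a, partner=b)
            mism[name] = mism.get(name, 0) + int(np.count_nonzero(mask != det))
    for (a, b), masks in bf["directed"].items():
        for name, mask in masks.items():
            det = eth.mask(n, name, actor=a, partner=b)
            mism[name] = mism.get(name, 0) + int(np.count_nonzero(mask != det))
    for aid, masks in bf["single"].items():
        for name, mask in masks.items():
            det = eth.mask(n, name, actor=aid)
            mism[name] = mism.get(name, 0) + int(np.count_nonzero(mask != det))
    return mism
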