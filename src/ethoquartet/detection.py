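"""Behavioural event detection from pose trajectories.

Implements the event catalogue of long-term group monitoring: dyadic
contacts (contact, nose-nose, nose-anogenital, side-side, side-side
head-to-tail), locomotor events (single move, move in contact, single idle,
rearing, rearing in contact, jump), group events (group of 2/3, make/break
group 3/4, break contact) and dynamic events (follow, train2, approach
contact), plus nightly distance travelled.

The speed threshold splitting moving from resting is 5 cm/s throughout
(the conventional walking threshold for mice; it also bounds the follow
definition).  Event intervals are maximal runs of per-frame predicates;
interruptions up to ``max_gap_frames`` (default 0) can be bridged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import model as M
from .config import AnalysisConfig
from .geometry import PairMasks, compute_pair_masks, heading_deg, heading_difference_deg
from .kinematics import mean_body_length_cm, near_wall, speed_cm_s
from .model import Ethogram, EventInterval, TrajectorySet, runs_to_intervals

__all__ = [
    "detect_dyadic_contacts",
    "detect_locomotor_events",
    "detect_group_events",
    "detect_dynamic_events",
    "detect_all",
    "compute_activity",
]


def _bridge_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    if max_gap <= 0:
        return mask
    out = mask.copy()
    runs = runs_to_intervals(~mask)
    n = len(mask)
    for s, e in runs:
        if s > 0 and e < n - 1 and (e - s + 1) <= max_gap:
            out[s : e + 1] = True
    return out


def _intervals(
    mask: np.ndarray, event_type: str, actor: str, partners: frozenset[str],
    config: AnalysisConfig,
) -> list[EventInterval]:
    mask = _bridge_gaps(mask, config.max_gap_frames)
    return [
        EventInterval(event_type, actor, partners, s, e)
        for s, e in runs_to_intervals(mask)
    ]


# ---------------------------------------------------------------------------
# Dyadic contacts
# ---------------------------------------------------------------------------

def detect_dyadic_contacts(
    traj: TrajectorySet,
    config: AnalysisConfig,
    pair_masks: dict[tuple[str, str], PairMasks] | None = None,
) -> Ethogram:
    """Contact, nose-nose, nose-anogenital and side-side(+/-) intervals.

    Symmetric events (contact, nose-nose, side-side variants) are emitted
    once per member of the pair with the other as partner; nose-anogenital
    keeps its direction (actor sniffing partner's tail base).
    """
    pm = pair_masks if pair_masks is not None else compute_pair_masks(traj, config)
    eth = Ethogram()
    for (a, b), m in pm.items():
        for mask, etype in (
            (m.contact, M.CONTACT),
            (m.nose_nose, M.NOSE_NOSE),
            (m.side_side, M.SIDE_SIDE),
            (m.side_side_htt, M.SIDE_SIDE_HTT),
        ):
            eth.add(_intervals(mask, etype, a, frozenset({b}), config))
            eth.add(_intervals(mask, etype, b, frozenset({a}), config))
        eth.add(_intervals(m.nose_ano_ab, M.NOSE_ANOGENITAL, a, frozenset({b}), config))
        eth.add(_intervals(m.nose_ano_ba, M.NOSE_ANOGENITAL, b, frozenset({a}), config))
    return eth


def _any_contact_masks(
    traj: TrajectorySet, pm: dict[tuple[str, str], PairMasks]
) -> dict[str, np.ndarray]:
    n = traj.n_frames
    masks = {aid: np.zeros(n, dtype=bool) for aid in traj.animals}
    for (a, b), m in pm.items():
        masks[a] |= m.contact
        masks[b] |= m.contact
    return masks


# ---------------------------------------------------------------------------
# Locomotor events
# ---------------------------------------------------------------------------

def detect_locomotor_events(
    traj: TrajectorySet,
    config: AnalysisConfig,
    pair_masks: dict[tuple[str, str], PairMasks] | None = None,
) -> Ethogram:
    """Single move / move in contact / single idle / rearing(+/- contact) / jump."""
    if traj.n_frames < 2:
        raise ValueError("locomotor detection needs at least 2 frames")
    pm = pair_masks if pair_masks is not None else compute_pair_masks(traj, config)
    in_contact = _any_contact_masks(traj, pm)
    eth = Ethogram()
    none = frozenset()
    for aid in traj.animals:
        t = traj.track(aid)
        speed = speed_cm_s(t, traj.fps)
        det = t.detected
        moving = det & (speed > config.speed_threshold_cm_s)
        resting = det & (speed <= config.speed_threshold_cm_s)
        contact = in_contact[aid]
        rearing = det & (t.body_slope > config.slope_threshold)
        jump = det & near_wall(t, traj, config) & (speed > config.jump_speed_cm_s)
        eth.add(_intervals(moving & ~contact, M.SINGLE_MOVE, aid, none, config))
        eth.add(_intervals(moving & contact, M.MOVE_IN_CONTACT, aid, none, config))
        eth.add(_intervals(resting & ~contact, M.SINGLE_IDLE, aid, none, config))
        eth.add(_intervals(rearing & ~contact, M.REARING, aid, none, config))
        eth.add(_intervals(rearing & contact, M.REARING_IN_CONTACT, aid, none, config))
        eth.add(_intervals(jump, M.JUMP, aid, none, config))
    return eth


# ---------------------------------------------------------------------------
# Group events
# ---------------------------------------------------------------------------

def _components(animals: list[str], edges: set[tuple[str, str]]) -> dict[str, frozenset[str]]:
    """Connected components of the contact graph; singletons included."""
    parent = {a: a for a in animals}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for a in animals:
        groups.setdefault(find(a), set()).add(a)
    return {a: frozenset(groups[find(a)]) for a in animals}


def detect_group_events(
    traj: TrajectorySet,
    config: AnalysisConfig,
    pair_masks: dict[tuple[str, str], PairMasks] | None = None,
) -> Ethogram:
    """Group-of-2/3 states and counted make/break group events.

    group of 2: touching exactly one other animal; group of 3: touching
    exactly two.  Make group3/group4 fires when an animal joins a connected
    contact component, growing it to size 3 resp. 4; break contact /
    group3 / group4 fires when a component of size 2/3/4 loses a member,
    attributed to the fastest of the former members at the transition frame
    (ties broken by animal id).
    """
    if traj.n_animals < 2:
        raise ValueError("group events need at least 2 animals")
    pm = pair_masks if pair_masks is not None else compute_pair_masks(traj, config)
    n = traj.n_frames
    animals = traj.animals
    quartet = traj.n_animals >= 3

    # partner counts -> group2/group3 states
    partner_count = {a: np.zeros(n, dtype=np.int8) for a in animals}
    for (a, b), m in pm.items():
        partner_count[a] += m.contact
        partner_count[b] += m.contact
    eth = Ethogram()
    for a in animals:
        eth.add(_intervals(partner_count[a] == 1, M.GROUP2, a, frozenset(), config))
        if quartet:
            eth.add(_intervals(partner_count[a] == 2, M.GROUP3, a, frozenset(), config))

    # component evolution at contact-graph change points
    pair_keys = list(pm)
    contact_stack = np.array([pm[k].contact for k in pair_keys])  # (P, N)
    change = np.zeros(n, dtype=bool)
    change[0] = True
    if n > 1:
        change[1:] = (contact_stack[:, 1:] != contact_stack[:, :-1]).any(axis=0)
    change_frames = np.flatnonzero(change)

    speeds = {a: speed_cm_s(traj.track(a), traj.fps) for a in animals}

    def comps_at(t: int) -> dict[str, frozenset[str]]:
        edges = {
            pair_keys[i] for i in range(len(pair_keys)) if contact_stack[i, t]
        }
        return _components(animals, edges)

    prev = comps_at(0)
    counted: list[EventInterval] = []
    for t in change_frames[1:]:
        cur = comps_at(int(t))
        # make events: animal alone before, in a component of size 3/4 now
        for a in animals:
            s0, s1 = len(prev[a]), len(cur[a])
            if s0 == 1 and s1 == 3:
                counted.append(EventInterval(M.MAKE_GROUP3, a, cur[a] - {a}, t, t))
            elif s0 == 1 and s1 == 4:
                counted.append(EventInterval(M.MAKE_GROUP4, a, cur[a] - {a}, t, t))
        # break events: a component of size s loses a member
        seen: set[frozenset[str]] = set()
        for a in animals:
            comp = prev[a]
            if len(comp) < 2 or comp in seen:
                continue
            seen.add(comp)
            members = sorted(comp)
            if len({cur[m] for m in members}) == 1:
                continue  # members still connected (possibly grown)
            sp = [
                speeds[m][t] if np.isfinite(speeds[m][t]) else -1.0
                for m in members
            ]
            fastest = members[int(np.argmax(sp))]
            etype = {2: M.BREAK_CONTACT, 3: M.BREAK_GROUP3, 4: M.BREAK_GROUP4}[
                len(comp)
            ]
            counted.append(
                EventInterval(etype, fastest, comp - {fastest}, t, t)
            )
        prev = cur
    eth.add(counted)
    return eth


# ---------------------------------------------------------------------------
# Dynamic events
# ---------------------------------------------------------------------------

def detect_dynamic_events(
    traj: TrajectorySet,
    config: AnalysisConfig,
    pair_masks: dict[tuple[str, str], PairMasks] | None = None,
) -> Ethogram:
    """Follow, train2 and approach-contact events (all directed).

    Follow: both animals above the speed threshold, headings within the
    side-side angle, and the follower's mass centre inside a rectangular
    zone trailing the leader (1 mean body length wide, 2 long).  Train2 is
    a follow during which the follower's nose is at whisker distance from
    the leader's tail base.  An approach contact is a maximal run of
    closing-distance frames with the approacher faster than the approached,
    ending at the onset frame of a contact between the two.
    """
    pm = pair_masks if pair_masks is not None else compute_pair_masks(traj, config)
    bl = mean_body_length_cm(traj)
    half_w = 0.5 * config.follow_zone_width_bl * bl
    zone_len = config.follow_zone_length_bl * bl
    speeds = {a: speed_cm_s(traj.track(a), traj.fps) for a in traj.animals}
    headings = {a: heading_deg(traj.track(a)) for a in traj.animals}
    eth = Ethogram()
    for (a, b), m in pm.items():
        ang = heading_difference_deg(headings[a], headings[b])
        for follower, leader, ng_mask in (
            (a, b, m.nose_ano_ab),
            (b, a, m.nose_ano_ba),
        ):
            tf, tl = traj.track(follower), traj.track(leader)
            both_det = tf.detected & tl.detected
            with np.errstate(invalid="ignore"):
                both_moving = (
                    (speeds[follower] > config.speed_threshold_cm_s)
                    & (speeds[leader] > config.speed_threshold_cm_s)
                )
            both_moving &= both_det
            hl = np.radians(headings[leader])
            u = np.column_stack([np.cos(hl), np.sin(hl)])
            rel = tf.center - tl.center
            behind = -np.einsum("ij,ij->i", rel, u)      # along -heading
            lateral = rel[:, 0] * u[:, 1] - rel[:, 1] * u[:, 0]
            in_zone = (behind >= 0) & (behind <= zone_len) & (np.abs(lateral) <= half_w)
            follow = (
                both_moving
                & (ang < config.side_side_angle_deg)
                & in_zone
            )
            eth.add(
                _intervals(follow, M.FOLLOW, follower, frozenset({leader}), config)
            )
            train2 = follow & ng_mask
            eth.add(
                _intervals(train2, M.TRAIN2, follower, frozenset({leader}), config)
            )
        # approach contact: scan backwards from each contact onset
        dist = m.distance
        contact = m.contact
        onsets = [s for s, _ in runs_to_intervals(contact) if s > 0]
        for actor, partner in ((a, b), (b, a)):
            sp_a, sp_p = speeds[actor], speeds[partner]
            for s in onsets:
                t = s - 1
                while (
                    t >= 0
                    and not contact[t]
                    and dist[t] > dist[t + 1]
                    and np.isfinite(sp_a[t])
                    and np.isfinite(sp_p[t])
                    and sp_a[t] > sp_p[t]
                ):
                    t -= 1
                if t < s - 1:
                    eth.add(
                        [
                            EventInterval(
                                M.APPROACH_CONTACT, actor,
                                frozenset({partner}), t + 1, s,
                            )
                        ]
                    )
    return eth


# ---------------------------------------------------------------------------
# Orchestration and activity
# ---------------------------------------------------------------------------

def detect_all(traj: TrajectorySet, config: AnalysisConfig) -> Ethogram:
    """Run every detector and return the combined ethogram."""
    pm = compute_pair_masks(traj, config)
    eth = detect_dyadic_contacts(traj, config, pm)
    eth.add(detect_locomotor_events(traj, config, pm))
    eth.add(detect_group_events(traj, config, pm))
    eth.add(detect_dynamic_events(traj, config, pm))
    return eth


def compute_activity(
    traj: TrajectorySet, night_windows: list[tuple[int, int]]
) -> pd.DataFrame:
    """Distance travelled (cm) per animal per dark phase.

    Sums frame-to-frame mass-centre displacements over each inclusive
    (start, end) frame window; steps touching an undetected frame
    contribute 0.
    """
    if not night_windows:
        raise ValueError("no night windows given")
    for s, e in night_windows:
        if e < s:
            raise ValueError(f"empty night window ({s}, {e})")
    rows = []
    for aid in traj.animals:
        t = traj.track(aid)
        steps = np.hypot(*(t.center[1:] - t.center[:-1]).T)
        valid = t.detected[1:] & t.detected[:-1]
        steps = np.where(valid, steps, 0.0)
        for i, (s, e) in enumerate(night_windows):
            rows.append(
                {
                    "animal_id": aid,
                    "night_index": i,
                    "distance_cm": float(steps[s:e].sum()),
                }
            )
    return pd.DataFrame(rows)
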