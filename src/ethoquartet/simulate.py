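"""Agent-based synthetic generator for trajectories, designs and USV tables.

The generator scripts behavioural events rather than letting them emerge:
contact bouts place the two animals in exact poses whose geometry sits a
safe margin inside (or outside) the detector's thresholds, so the ground
truth is unambiguous at every frame except the single boundary frames
created by block transitions.  Outside contacts, each animal alternates
idle blocks and move blocks (constant-speed orbit around a home point in
its own arena quadrant, so non-interacting animals can never come within
contact range).  Ultrasonic vocalisations are emitted as an inhomogeneous
Poisson process whose rate depends on the current pair state (highest in
contact, lowest in idle).

The generator targets the statistical structure of long-term group
recordings (a 50 x 50 cm arena, 2 or 4 animals, 2 wt + 2 Del/+ quartets,
genotype-dependent speed and contact-leaving parameters), not
biomechanical realism; default durations are minutes rather than nights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AnimalTrack, GroupDesign, TrajectorySet, runs_to_intervals

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_quartet",
    "simulate_pair_with_usv",
    "simulate_colony",
    "simulate_null_phenotype",
    "uniform_partner_null",
    "make_contour",
    "frame_agreement",
    "scripted_follow_pair",
    "scripted_approach_pair",
    "scripted_huddle",
    "PAIR_POSES",
]

BODY_L = 4.0          # nose to tail-base, cm
HALF_L = BODY_L / 2.0
SLOPE_FLAT = 0.1
SLOPE_REAR = 0.9


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    Genotype effects are multipliers applied to Del/+ animals:
    ``del_speed_mult`` scales the moving speed, ``del_leave_mult`` scales
    the contact-leaving rate (a value of 2 halves the expected contact
    duration of bouts involving a Del/+ animal, once per Del/+ member).
    """

    n_animals: int = 4
    arena_cm: float = 50.0
    fps: float = 30.0
    duration_s: float = 300.0
    speed_scale_cm_s: float = 9.0
    move_mean_s: float = 10.0
    idle_mean_s: float = 15.0
    contact_rate_per_min: float = 2.0   # pooled over all pairs
    contact_mean_s: float = 8.0
    contact_cooldown_s: float = 1.0
    rearing_rate_per_min: float = 1.0
    rearing_mean_s: float = 1.5
    del_speed_mult: float = 1.0
    del_leave_mult: float = 1.0
    pose_weights: dict[str, float] | None = None
    detection_dropout: float = 0.0
    jitter_cm: float = 0.02
    orbit_radius_cm: float = 6.0
    usv_rate_contact_per_min: float = 20.0
    usv_rate_move_per_min: float = 4.0
    usv_rate_idle_per_min: float = 0.5
    usv_duration_mean_ms: float = 80.0
    usv_contour_points: int = 20
    usv_inflexion_mean: float = 1.5
    sex: str = "F"

    def __post_init__(self) -> None:
        if self.n_animals not in (2, 4):
            raise ValueError("n_animals must be 2 or 4")
        if not 0.0 <= self.detection_dropout < 1.0:
            raise ValueError("detection_dropout must be in [0, 1)")
        for name in (
            "contact_rate_per_min", "rearing_rate_per_min",
            "usv_rate_contact_per_min", "usv_rate_move_per_min",
            "usv_rate_idle_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        margin = 8.0 + self.orbit_radius_cm + BODY_L
        if self.arena_cm < 2 * margin / 1.6:
            raise ValueError("arena too small for the scripted geometry")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


# ---------------------------------------------------------------------------
# Pose library: exact dyadic contact poses with threshold margins
# ---------------------------------------------------------------------------

def _pose_from_center(center: tuple[float, float], theta_deg: float):
    th = math.radians(theta_deg)
    u = np.array([math.cos(th), math.sin(th)])
    c = np.array(center, float)
    return c, theta_deg


def _pose_from_nose(nose: tuple[float, float], theta_deg: float):
    th = math.radians(theta_deg)
    u = np.array([math.cos(th), math.sin(th)])
    c = np.array(nose, float) - HALF_L * u
    return c, theta_deg


#: kind -> ((center_a, theta_a), (center_b, theta_b), truth event set).
#: Truth names: "contact", "nose-nose", "nose-anogenital" (directed a->b),
#: "side-side", "side-side head-to-tail".  Geometry designed for the default
#: thresholds (contact 1.5 cm, whisker 2.0 cm, angle 45 deg) with >=0.15 cm
#: / >=10 deg margins on every predicate, on both sides.
PAIR_POSES: dict[str, tuple] = {
    "nose-nose": (
        _pose_from_nose((-0.5, 0.0), 40.0),
        _pose_from_nose((0.5, 0.0), 140.0),
        frozenset({"contact", "nose-nose"}),
    ),
    "nose-anogenital": (
        _pose_from_nose((-0.77, -0.64), 80.0),
        _pose_from_nose((4.0, 0.0), 0.0),       # tail at origin
        frozenset({"contact", "nose-anogenital"}),
    ),
    "side-side": (
        _pose_from_center((0.0, 0.0), 0.0),
        _pose_from_center((2.0, 1.2), 0.0),
        frozenset({"contact", "side-side"}),
    ),
    "side-side head-to-tail": (
        _pose_from_center((0.0, 0.0), 0.0),
        _pose_from_center((2.1, 1.2), 180.0),
        frozenset({"contact", "side-side head-to-tail"}),
    ),
    "nose-nose & side-side": (
        _pose_from_center((0.0, 0.0), 0.0),
        _pose_from_center((0.0, 1.2), 0.0),
        frozenset({"contact", "nose-nose", "side-side"}),
    ),
    "nose-anogenital & side-side head-to-tail": (
        _pose_from_center((0.0, 0.0), 0.0),
        # tail near a's nose, heading 170 deg: a sniffs b's tail base while
        # flank-to-flank antiparallel; b's nose stays clear of a's tail.
        (np.array([2.8, 1.3]) + HALF_L * np.array(
            [math.cos(math.radians(170.0)), math.sin(math.radians(170.0))]
        ), 170.0),
        frozenset({"contact", "nose-anogenital", "side-side head-to-tail"}),
    ),
    "other contact": (
        _pose_from_center((0.0, 0.0), 0.0),
        _pose_from_center((3.2, 0.0), 90.0),
        frozenset({"contact"}),
    ),
}


def _place_pose(center: np.ndarray, theta_deg: float, rot_deg: float,
                origin: np.ndarray):
    """Rotate a local pose by rot_deg about (0,0) and translate to origin."""
    rot = math.radians(rot_deg)
    c, s = math.cos(rot), math.sin(rot)
    R = np.array([[c, -s], [s, c]])
    new_center = origin + R @ np.asarray(center, float)
    return new_center, theta_deg + rot_deg


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Scripted per-frame truth of a simulation.

    ``single``: per animal, masks for "move", "idle", "rearing".
    ``pair``: per unordered pair, masks for "contact", "nose-nose",
    "side-side", "side-side head-to-tail".  ``directed``: per ordered pair,
    "nose-anogenital".  Counted with the same conventions as the detector
    (inclusive frames); :func:`intervals` run-length encodes a mask.
    """

    single: dict[str, dict[str, np.ndarray]]
    pair: dict[tuple[str, str], dict[str, np.ndarray]]
    directed: dict[tuple[str, str], dict[str, np.ndarray]]
    bouts: list[tuple[tuple[str, str], str, int, int]]
    multipliers: dict[str, float]
    usv_states: np.ndarray | None = None
    usv_rates_per_min: dict[str, float] | None = None
    usv_inflexions: list[int] | None = None

    @staticmethod
    def intervals(mask: np.ndarray) -> list[tuple[int, int]]:
        return runs_to_intervals(mask)


def frame_agreement(
    truth: np.ndarray, detected: np.ndarray, boundary_tolerance: int = 1
) -> dict[str, float]:
    """Frame-level agreement between a truth mask and a detector mask.

    Frames within ``boundary_tolerance`` of a state change in either mask
    are excluded (scripted transitions blur detector output by at most one
    frame); recall/precision are reported over all frames regardless.
    """
    truth = np.asarray(truth, bool)
    detected = np.asarray(detected, bool)
    n = truth.size
    near_boundary = np.zeros(n, dtype=bool)
    for m in (truth, detected):
        change = np.flatnonzero(m[1:] != m[:-1]) + 1
        for c in change:
            lo = max(0, c - boundary_tolerance)
            hi = min(n, c + boundary_tolerance)
            near_boundary[lo:hi] = True
    core = ~near_boundary
    exact_core = bool(np.array_equal(truth[core], detected[core]))
    tp = float(np.count_nonzero(truth & detected))
    fn = float(np.count_nonzero(truth & ~detected))
    fp = float(np.count_nonzero(~truth & detected))
    return {
        "exact_outside_boundaries": exact_core,
        "recall": tp / (tp + fn) if (tp + fn) > 0 else 1.0,
        "precision": tp / (tp + fp) if (tp + fp) > 0 else 1.0,
    }


# ---------------------------------------------------------------------------
# Core scripted simulation
# ---------------------------------------------------------------------------

def _exp_blocks(rng, n_frames: int, mean_a: float, mean_b: float,
                fps: float, start_state: int):
    """Alternating (state, start, end) blocks with Exp-distributed lengths.

    state 0 uses mean_a (idle), state 1 uses mean_b (move); a zero mean
    suppresses that state entirely.
    """
    if mean_a <= 0:
        return [(1, 0, n_frames - 1)]
    if mean_b <= 0:
        return [(0, 0, n_frames - 1)]
    blocks = []
    t = 0
    state = start_state
    while t < n_frames:
        mean = mean_a if state == 0 else mean_b
        length = max(2, int(round(rng.exponential(mean * fps))))
        blocks.append((state, t, min(n_frames - 1, t + length - 1)))
        t += length
        state = 1 - state
    return blocks


def _simulate_core(config: SimulationConfig, seed: int, cage_id: str = "c0"):
    rng = np.random.default_rng(seed)
    n = config.n_frames
    fps = config.fps
    na = config.n_animals
    animals = [f"{cage_id}-m{i + 1}" for i in range(na)]
    # 2 wt + 2 del quartets; pairs are same-genotype (as in unfamiliar-pair
    # encounters), alternating wt/del across cages is the caller's job.
    genotypes = (
        ["wt", "wt", "del", "del"] if na == 4 else ["wt", "wt"]
    )
    design = GroupDesign(
        genotype=dict(zip(animals, genotypes)),
        sex={a: config.sex for a in animals},
        cage={a: cage_id for a in animals},
    )
    A = config.arena_cm
    q = A / 4.0
    homes = {
        2: [np.array([q, 2 * q]), np.array([3 * q, 2 * q])],
        4: [
            np.array([q, q]), np.array([3 * q, q]),
            np.array([q, 3 * q]), np.array([3 * q, 3 * q]),
        ],
    }[na]

    # ---- pair contact bouts (globally exclusive) -------------------------
    pairs = [
        (animals[i], animals[j]) for i in range(na) for j in range(i + 1, na)
    ]
    pose_kinds = list(PAIR_POSES)
    weights = np.array(
        [
            (config.pose_weights or {}).get(k, 1.0) for k in pose_kinds
        ],
        float,
    )
    weights = weights / weights.sum()
    bouts: list[tuple[tuple[str, str], str, int, int, bool]] = []
    if config.contact_rate_per_min > 0:
        rate_frames = config.contact_rate_per_min / 60.0 / fps
        cooldown = int(round(config.contact_cooldown_s * fps))
        t = int(rng.exponential(1.0 / rate_frames))
        while t < n - 3:
            pair = pairs[rng.integers(len(pairs))]
            n_del = sum(1 for a in pair if design.genotype[a] == "del")
            mean_frames = (
                config.contact_mean_s * fps / (config.del_leave_mult ** n_del)
            )
            length = max(3, int(round(rng.exponential(mean_frames))))
            end = min(n - 2, t + length - 1)
            kind = pose_kinds[rng.choice(len(pose_kinds), p=weights)]
            flip = bool(rng.integers(2))  # which member plays role A
            bouts.append((pair, kind, t, end, flip))
            t = end + 1 + cooldown + int(rng.exponential(1.0 / rate_frames))

    # ---- per-animal block schedules --------------------------------------
    centers = np.zeros((na, n, 2))
    thetas = np.zeros((na, n))
    move_mask = np.zeros((na, n), bool)
    in_bout = np.zeros((na, n), bool)
    idx = {a: i for i, a in enumerate(animals)}
    for i, aid in enumerate(animals):
        mult = (
            config.del_speed_mult if design.genotype[aid] == "del" else 1.0
        )
        v = config.speed_scale_cm_s * mult
        r = config.orbit_radius_cm
        dphi = v / r / fps
        blocks = _exp_blocks(
            rng, n, config.idle_mean_s, config.move_mean_s, fps,
            int(rng.integers(2)),
        )
        phi = rng.uniform(0, 2 * np.pi)
        direction = 1.0 if rng.random() < 0.5 else -1.0
        for state, s, e in blocks:
            length = e - s + 1
            if state == 1:  # move: constant-speed orbit
                phis = phi + direction * dphi * np.arange(1, length + 1)
                centers[i, s : e + 1] = homes[i] + r * np.column_stack(
                    [np.cos(phis), np.sin(phis)]
                )
                thetas[i, s : e + 1] = np.degrees(phis) + direction * 90.0
                phi = phis[-1]
                move_mask[i, s : e + 1] = True
            else:           # idle: hold the current orbit position
                centers[i, s : e + 1] = homes[i] + r * np.array(
                    [np.cos(phi), np.sin(phi)]
                )
                thetas[i, s : e + 1] = np.degrees(phi) + direction * 90.0

    # ---- apply contact bouts ---------------------------------------------
    pair_truth = {
        p: {
            k: np.zeros(n, bool)
            for k in ("contact", "nose-nose", "side-side",
                      "side-side head-to-tail")
        }
        for p in pairs
    }
    directed_truth = {}
    for a, b in pairs:
        directed_truth[(a, b)] = {"nose-anogenital": np.zeros(n, bool)}
        directed_truth[(b, a)] = {"nose-anogenital": np.zeros(n, bool)}
    lo, hi = 8.0, A - 8.0
    for (pa, pb), kind, s, e, flip in bouts:
        ia, ib = idx[pa], idx[pb]
        role_a, role_b = (pb, pa) if flip else (pa, pb)
        ra, rb = idx[role_a], idx[role_b]
        mid = (homes[ia] + homes[ib]) / 2.0 + rng.uniform(-3, 3, size=2)
        mid = np.clip(mid, lo, hi)
        rot = rng.uniform(0, 360)
        (ca, tha), (cb, thb), truth_set = PAIR_POSES[kind]
        ca_w, tha_w = _place_pose(ca, tha, rot, mid)
        cb_w, thb_w = _place_pose(cb, thb, rot, mid)
        centers[ra, s : e + 1] = ca_w
        thetas[ra, s : e + 1] = tha_w
        centers[rb, s : e + 1] = cb_w
        thetas[rb, s : e + 1] = thb_w
        in_bout[ia, s : e + 1] = True
        in_bout[ib, s : e + 1] = True
        key = (pa, pb)
        for name in truth_set:
            if name == "nose-anogenital":
                directed_truth[(role_a, role_b)][name][s : e + 1] = True
            else:
                pair_truth[key][name][s : e + 1] = True

    # ---- rearing bouts during idle ---------------------------------------
    slopes = np.full((na, n), SLOPE_FLAT)
    rearing = np.zeros((na, n), bool)
    if config.rearing_rate_per_min > 0:
        rr = config.rearing_rate_per_min / 60.0 / fps
        for i in range(na):
            idle = ~move_mask[i] & ~in_bout[i]
            for s, e in runs_to_intervals(idle):
                t = s + int(rng.exponential(1.0 / rr))
                while t < e - 1:
                    length = max(2, int(round(rng.exponential(
                        config.rearing_mean_s * fps))))
                    re_end = min(e, t + length - 1)
                    rearing[i, t : re_end + 1] = True
                    slopes[i, t : re_end + 1] = SLOPE_REAR
                    t = re_end + 2 + int(rng.exponential(1.0 / rr))

    # ---- assemble tracks ---------------------------------------------------
    detected = np.ones((na, n), bool)
    if config.detection_dropout > 0:
        detected = rng.random((na, n)) >= config.detection_dropout
        detected[:, 0] = True  # anchor last-known coordinates
    th = np.radians(thetas)
    u = np.stack([np.cos(th), np.sin(th)], axis=-1)
    noses = centers + HALF_L * u
    tails = centers - HALF_L * u
    if config.jitter_cm > 0:
        for arr in (noses, centers, tails):
            arr += rng.uniform(
                -config.jitter_cm, config.jitter_cm, size=arr.shape
            )
    np.clip(noses, 0.0, A, out=noses)
    np.clip(centers, 0.0, A, out=centers)
    np.clip(tails, 0.0, A, out=tails)
    tracks = {}
    for i, aid in enumerate(animals):
        det = detected[i]
        no, ce, ta = noses[i].copy(), centers[i].copy(), tails[i].copy()
        if not det.all():
            last = 0
            for t in range(n):
                if det[t]:
                    last = t
                else:
                    no[t], ce[t], ta[t] = no[last], ce[last], ta[last]
        tracks[aid] = AnimalTrack(
            nose=no, center=ce, tail=ta,
            body_slope=slopes[i].copy(), detected=det,
        )
    traj = TrajectorySet(tracks, fps=fps, arena_size_cm=(A, A))

    # truth masks respect detection: events require the animals detected
    single = {}
    for i, aid in enumerate(animals):
        det = detected[i]
        single[aid] = {
            "move": move_mask[i] & ~in_bout[i] & det,
            "idle": ~move_mask[i] & ~in_bout[i] & det,
            "rearing": rearing[i] & det,
        }
    for (a, b), masks in pair_truth.items():
        both = detected[idx[a]] & detected[idx[b]]
        for k in masks:
            masks[k] &= both
    for (a, b), masks in directed_truth.items():
        both = detected[idx[a]] & detected[idx[b]]
        masks["nose-anogenital"] &= both
    truth = GroundTruth(
        single=single,
        pair=pair_truth,
        directed=directed_truth,
        bouts=[(p, k, s, e) for p, k, s, e, _ in bouts],
        multipliers={
            "del_speed_mult": config.del_speed_mult,
            "del_leave_mult": config.del_leave_mult,
        },
    )
    return traj, design, truth, rng, in_bout, move_mask, animals


def simulate_quartet(
    config: SimulationConfig | None = None, seed: int = 0, cage_id: str = "c0"
):
    """Simulate a 2 wt + 2 Del/+ quartet.

    Returns (TrajectorySet, GroupDesign, GroundTruth); bit-identical for a
    fixed seed.
    """
    config = config or SimulationConfig(n_animals=4)
    if config.n_animals != 4:
        raise ValueError("simulate_quartet needs n_animals=4")
    traj, design, truth, *_ = _simulate_core(config, seed, cage_id)
    return traj, design, truth


def simulate_pair_with_usv(
    config: SimulationConfig | None = None, seed: int = 0, cage_id: str = "p0"
):
    """Simulate a same-genotype pair plus its USV table.

    USVs follow an inhomogeneous Poisson process with per-state rates
    (contact > move > idle, mirroring context-specific call rates); each
    call carries a peak-frequency contour with a known inflexion count.
    Returns (TrajectorySet, GroupDesign, usv_records, GroundTruth).
    """
    config = config or SimulationConfig(n_animals=2)
    if config.n_animals != 2:
        raise ValueError("simulate_pair_with_usv needs n_animals=2")
    from .usv import USVRecord

    traj, design, truth, rng, in_bout, move_mask, animals = _simulate_core(
        config, seed, cage_id
    )
    n, fps = config.n_frames, config.fps
    contact_state = in_bout.any(axis=0)
    moving_state = ~contact_state & move_mask.any(axis=0)
    states = np.where(contact_state, 2, np.where(moving_state, 1, 0))
    rates = {
        0: config.usv_rate_idle_per_min,
        1: config.usv_rate_move_per_min,
        2: config.usv_rate_contact_per_min,
    }
    p_frame = np.array([rates[s] for s in (0, 1, 2)]) / 60.0 / fps
    emit = rng.random(n) < p_frame[states]
    records: list[USVRecord] = []
    inflexions: list[int] = []
    prev_offset = -1.0
    for t in np.flatnonzero(emit):
        onset = t / fps + rng.uniform(0, 1.0 / fps)
        if onset <= prev_offset + 0.001:
            continue
        duration_ms = float(
            np.clip(
                rng.lognormal(
                    math.log(config.usv_duration_mean_ms), 0.3
                ),
                20.0, 400.0,
            )
        )
        k = int(rng.poisson(config.usv_inflexion_mean))
        k = min(k, config.usv_contour_points - 2)
        contour = make_contour(
            k, config.usv_contour_points, rng,
            f_start=float(rng.uniform(55.0, 75.0)),
        )
        records.append(
            USVRecord(onset_s=onset, duration_ms=duration_ms, contour=contour)
        )
        inflexions.append(k)
        prev_offset = onset + duration_ms / 1000.0
    truth.usv_states = states
    truth.usv_rates_per_min = {
        "idle": rates[0], "move": rates[1], "contact": rates[2],
    }
    truth.usv_inflexions = inflexions
    return traj, design, records, truth


def make_contour(
    n_inflexions: int,
    n_points: int,
    rng,
    f_start: float = 60.0,
    step_range: tuple[float, float] = (0.5, 2.0),
) -> np.ndarray:
    """A peak-frequency contour with exactly ``n_inflexions`` inflexions.

    Built from ``n_inflexions + 1`` strictly monotone segments with
    alternating direction; every consecutive difference is non-zero and
    below the jump threshold, so the feature extractor counts exactly
    ``n_inflexions`` modulations and no jumps.
    """
    if n_points < n_inflexions + 2:
        raise ValueError("contour too short for the requested inflexions")
    n_steps = n_points - 1
    n_segments = n_inflexions + 1
    # split steps into n_segments parts, each >= 1
    cuts = np.sort(
        rng.choice(np.arange(1, n_steps), size=n_segments - 1, replace=False)
    ) if n_segments > 1 else np.array([], int)
    seg_lengths = np.diff(np.concatenate(([0], cuts, [n_steps])))
    direction = 1.0 if rng.random() < 0.5 else -1.0
    steps = []
    for length in seg_lengths:
        steps.append(direction * rng.uniform(*step_range, size=int(length)))
        direction = -direction
    contour = f_start + np.concatenate([[0.0], np.cumsum(np.concatenate(steps))])
    return contour


# ---------------------------------------------------------------------------
# Colony-scale helpers and null generators
# ---------------------------------------------------------------------------

def simulate_colony(
    n_cages: int, config: SimulationConfig | None = None, seed: int = 0
):
    """Independent quartet simulations with distinct cage ids.

    Returns a list of (traj, design, truth) and the merged GroupDesign.
    """
    config = config or SimulationConfig(n_animals=4)
    rng = np.random.default_rng(seed)
    sims = []
    merged = GroupDesign()
    for c in range(n_cages):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        traj, design, truth = simulate_quartet(config, sub_seed, cage_id=f"c{c}")
        sims.append((traj, design, truth))
        merged.genotype.update(design.genotype)
        merged.sex.update(design.sex)
        merged.cage.update(design.cage)
    return sims, merged


def simulate_null_phenotype(
    n_cages: int = 8,
    n_per_cage: int = 4,
    cage_sd: float = 1.0,
    noise_sd: float = 1.0,
    effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal phenotype values with a cage random effect.

    value = cage_effect + effect * [del] + noise, with 2 wt + 2 del per
    cage (or an even split).  ``effect=0`` is the null used for type-I
    calibration of the mixed model.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cages):
        u = rng.normal(0, cage_sd)
        for i in range(n_per_cage):
            g = "del" if i >= n_per_cage // 2 else "wt"
            rows.append(
                {
                    "value": u + (effect if g == "del" else 0.0)
                    + rng.normal(0, noise_sd),
                    "genotype": g,
                    "cage": f"c{c}",
                }
            )
    return pd.DataFrame(rows)


def uniform_partner_null(
    n_choices: int, seed: int = 0, n_replicates: int = 1
) -> np.ndarray:
    """Same-genotype interaction proportions under uniform partner choice.

    Each replicate draws ``n_choices`` partners uniformly from the 3 cage
    mates of a 2 wt + 2 del quartet (1 same-genotype) and returns the
    fraction of same-genotype picks; the grand mean converges to 1/3.
    """
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 3, size=(n_replicates, n_choices))
    return (draws == 0).mean(axis=1)


# ---------------------------------------------------------------------------
# Deterministic scripted scenarios (follow / approach / group dynamics)
# ---------------------------------------------------------------------------

def _straight_track(start, heading_deg, speed, n, fps, slope=SLOPE_FLAT):
    th = math.radians(heading_deg)
    u = np.array([math.cos(th), math.sin(th)])
    t = np.arange(n)[:, None] / fps
    center = np.asarray(start, float) + speed * t * u
    return AnimalTrack(
        nose=center + HALF_L * u,
        center=center,
        tail=center - HALF_L * u,
        body_slope=np.full(n, slope),
        detected=np.ones(n, bool),
    )


def scripted_follow_pair(
    n_frames: int = 120,
    fps: float = 30.0,
    speed: float = 10.0,
    gap_cm: float = 7.0,
    heading_offset_deg: float = 0.0,
) -> TrajectorySet:
    """Leader on a straight line with the follower trailing at ``gap_cm``.

    The default gap (7 cm) keeps the follower inside the 2-body-length
    follow zone but out of contact; a gap of 5 cm adds nose-to-tail-base
    contact (train2 geometry).  ``heading_offset_deg`` rotates the
    follower's body axis without moving its path.
    """
    leader = _straight_track((12.0 + gap_cm, 25.0), 0.0, speed, n_frames, fps)
    follower = _straight_track((12.0, 25.0), 0.0, speed, n_frames, fps)
    if heading_offset_deg:
        th = math.radians(heading_offset_deg)
        u = np.array([math.cos(th), math.sin(th)])
        follower = AnimalTrack(
            nose=follower.center + HALF_L * u,
            center=follower.center,
            tail=follower.center - HALF_L * u,
            body_slope=follower.body_slope,
            detected=follower.detected,
        )
    return TrajectorySet(
        {"follower": follower, "leader": leader}, fps=fps,
        arena_size_cm=(80.0, 50.0),
    )


def scripted_approach_pair(
    n_frames: int = 90, fps: float = 30.0, speed: float = 10.0
) -> tuple[TrajectorySet, int]:
    """One animal walks straight at a static partner until contact.

    Returns the trajectory set and the frame at which contact begins
    (minimum body-body distance first below the default 1.5 cm threshold).
    """
    target = AnimalTrack(
        nose=np.tile([30.0, 27.0], (n_frames, 1)).astype(float),
        center=np.tile([30.0, 25.0], (n_frames, 1)).astype(float),
        tail=np.tile([30.0, 23.0], (n_frames, 1)).astype(float),
        body_slope=np.full(n_frames, SLOPE_FLAT),
        detected=np.ones(n_frames, bool),
    )
    # approacher moves along y=25 towards x=30; stops once in contact
    xs = 10.0 + speed * np.arange(n_frames) / fps
    stop_x = 27.0    # nose at 29.0, 1.0 cm from target body -> in contact
    xs = np.minimum(xs, stop_x)
    center = np.column_stack([xs, np.full(n_frames, 25.0)])
    approacher = AnimalTrack(
        nose=center + [HALF_L, 0.0],
        center=center,
        tail=center - [HALF_L, 0.0],
        body_slope=np.full(n_frames, SLOPE_FLAT),
        detected=np.ones(n_frames, bool),
    )
    # first frame with nose within 1.5 cm of the target's body (x = 30)
    contact_start = int(np.flatnonzero(30.0 - (xs + HALF_L) < 1.5)[0])
    return (
        TrajectorySet(
            {"approacher": approacher, "target": target}, fps=fps,
            arena_size_cm=(50.0, 50.0),
        ),
        contact_start,
    )


def scripted_huddle(fps: float = 30.0) -> tuple[TrajectorySet, list[tuple[str, str, int]]]:
    """A scripted group scenario with known make/break group events.

    Four animals form a side-by-side chain one at a time (pair -> trio ->
    quartet) and then leave one at a time.  Returns the trajectory set and
    the expected counted events as (event_type, actor, frame) tuples.
    """
    n = 360
    phase = n // 6  # 6 phases of equal length
    homes = [
        np.array([10.0, 10.0]), np.array([40.0, 10.0]),
        np.array([10.0, 40.0]), np.array([40.0, 40.0]),
    ]
    base = np.array([23.0, 25.0])
    # chain slots: lateral spacing 1.2 cm, longitudinal stagger 0/2 cm
    slots = [
        base + np.array([0.0, 0.0]),
        base + np.array([2.0, 1.2]),
        base + np.array([0.0, 2.4]),
        base + np.array([2.0, 3.6]),
    ]
    animals = ["m1", "m2", "m3", "m4"]
    centers = np.zeros((4, n, 2))
    for i in range(4):
        centers[i, :] = homes[i]
    f1, f2, f3, f4, f5 = phase, 2 * phase, 3 * phase, 4 * phase, 5 * phase
    centers[1, f1:] = slots[1]   # m2 and m3 form the initial pair
    centers[2, f1:] = slots[2]
    centers[0, f2:] = slots[0]   # m1 joins -> trio
    centers[3, f3:] = slots[3]   # m4 joins -> quartet
    centers[3, f4:] = homes[3]   # m4 leaves -> trio
    centers[0, f5:] = homes[0]   # m1 leaves -> pair
    u = np.array([1.0, 0.0])
    tracks = {
        aid: AnimalTrack(
            nose=centers[i] + HALF_L * u,
            center=centers[i],
            tail=centers[i] - HALF_L * u,
            body_slope=np.full(n, SLOPE_FLAT),
            detected=np.ones(n, bool),
        )
        for i, aid in enumerate(animals)
    }
    traj = TrajectorySet(tracks, fps=fps, arena_size_cm=(50.0, 50.0))
    expected = [
        ("make group3", "m1", f2),
        ("make group4", "m4", f3),
        ("break group4", "m4", f4),
        ("break group3", "m1", f5),
    ]
    return traj, expected
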