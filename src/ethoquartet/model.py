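"""Core domain types: trajectories, group designs, behavioural events.

Coordinates are in centimetres in an arena whose origin is the lower-left
corner; frames are 0-based and intervals are inclusive on both ends, so a
one-frame event has duration 1 frame.  Undetected frames are materialised
(``detected=False`` with last-known coordinates) rather than dropped, because
the exclusive-event analysis needs an "undetected" state covering every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventInterval",
    "Ethogram",
    "TrajectorySet",
    "GroupDesign",
    "SchemaError",
    "EVENT_TYPES",
    "runs_to_intervals",
    "mask_from_intervals",
]


class SchemaError(ValueError):
    """A tabular input violates the interchange schema."""


# ---------------------------------------------------------------------------
# Event catalogue (non-exclusive events of the long-term monitoring pipeline)
# ---------------------------------------------------------------------------

CONTACT = "contact"
NOSE_NOSE = "nose-nose"
NOSE_ANOGENITAL = "nose-anogenital"
SIDE_SIDE = "side-side"
SIDE_SIDE_HTT = "side-side head-to-tail"
SINGLE_MOVE = "single move"
MOVE_IN_CONTACT = "move in contact"
SINGLE_IDLE = "single idle"
REARING = "rearing"
REARING_IN_CONTACT = "rearing in contact"
JUMP = "jump"
GROUP2 = "group of 2"
GROUP3 = "group of 3"
MAKE_GROUP3 = "make group3"
MAKE_GROUP4 = "make group4"
BREAK_CONTACT = "break contact"
BREAK_GROUP3 = "break group3"
BREAK_GROUP4 = "break group4"
FOLLOW = "follow"
TRAIN2 = "train2"
APPROACH_CONTACT = "approach contact"

#: Every event type the detector can emit.
EVENT_TYPES: tuple[str, ...] = (
    CONTACT, NOSE_NOSE, NOSE_ANOGENITAL, SIDE_SIDE, SIDE_SIDE_HTT,
    SINGLE_MOVE, MOVE_IN_CONTACT, SINGLE_IDLE, REARING, REARING_IN_CONTACT,
    JUMP, GROUP2, GROUP3, MAKE_GROUP3, MAKE_GROUP4, BREAK_CONTACT,
    BREAK_GROUP3, BREAK_GROUP4, FOLLOW, TRAIN2, APPROACH_CONTACT,
)

#: Events with an empty partner set.
NON_SOCIAL_EVENTS = frozenset({SINGLE_MOVE, SINGLE_IDLE, REARING, JUMP})


@dataclass(frozen=True, order=True)
class EventInterval:
    """A named behavioural event over an inclusive frame interval.

    ``partners`` is empty for non-social events (single move, single idle,
    rearing, jump) and carries the interacting animal ids otherwise.
    Directed events (nose-anogenital, follow, approach contact) keep the
    direction in (actor, partners).
    """

    event_type: str
    actor: str
    partners: frozenset[str]
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError(
                f"start_frame {self.start_frame} > end_frame {self.end_frame}"
            )
        if self.start_frame < 0:
            raise ValueError("negative start_frame")

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, fps: float) -> float:
        return self.duration_frames / fps


class Ethogram:
    """A collection of :class:`EventInterval` with query helpers."""

    def __init__(self, intervals: Iterable[EventInterval] = ()) -> None:
        self.intervals: list[EventInterval] = sorted(
            intervals, key=lambda e: (e.event_type, e.actor, e.start_frame)
        )

    def __iter__(self) -> Iterator[EventInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ethogram):
            return NotImplemented
        return sorted(self.intervals) == sorted(other.intervals)

    def add(self, intervals: Iterable[EventInterval]) -> None:
        self.intervals.extend(intervals)
        self.intervals.sort(key=lambda e: (e.event_type, e.actor, e.start_frame))

    def by_type(
        self,
        event_type: str,
        actor: str | None = None,
        partner: str | None = None,
    ) -> list[EventInterval]:
        out = [e for e in self.intervals if e.event_type == event_type]
        if actor is not None:
            out = [e for e in out if e.actor == actor]
        if partner is not None:
            out = [e for e in out if partner in e.partners]
        return out

    def mask(
        self,
        n_frames: int,
        event_type: str,
        actor: str | None = None,
        partner: str | None = None,
    ) -> np.ndarray:
        """Boolean per-frame mask of the selected intervals."""
        return mask_from_intervals(
            self.by_type(event_type, actor, partner), n_frames
        )

    def total_duration(
        self, event_type: str, actor: str | None = None, partner: str | None = None
    ) -> int:
        return sum(
            e.duration_frames for e in self.by_type(event_type, actor, partner)
        )

    def count(
        self, event_type: str, actor: str | None = None, partner: str | None = None
    ) -> int:
        return len(self.by_type(event_type, actor, partner))


def runs_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as inclusive (start, end) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def mask_from_intervals(
    intervals: Iterable[EventInterval | tuple[int, int]], n_frames: int
) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for item in intervals:
        if isinstance(item, EventInterval):
            s, e = item.start_frame, item.end_frame
        else:
            s, e = item
        mask[s : e + 1] = True
    return mask


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

TRAJECTORY_COLUMNS = (
    "frame", "time_s", "animal_id", "nose_x", "nose_y", "center_x",
    "center_y", "tail_x", "tail_y", "body_slope", "detected",
)


@dataclass
class AnimalTrack:
    """Per-frame pose arrays for one animal, contiguous in frame."""

    nose: np.ndarray      # (N, 2) cm
    center: np.ndarray    # (N, 2) cm
    tail: np.ndarray      # (N, 2) cm
    body_slope: np.ndarray  # (N,)
    detected: np.ndarray    # (N,) bool


class TrajectorySet:
    """Poses of 2-4 identified animals sharing a common frame axis.

    Every frame is present exactly once per animal; undetected frames are
    flagged rather than absent.
    """

    def __init__(
        self,
        tracks: Mapping[str, AnimalTrack],
        fps: float = 30.0,
        arena_size_cm: tuple[float, float] = (50.0, 50.0),
        lights_on: str = "07:00",
        lights_off: str = "19:00",
        start_clock: str = "15:30",
    ) -> None:
        if not tracks:
            raise ValueError("empty trajectory set")
        lengths = {len(t.detected) for t in tracks.values()}
        if len(lengths) != 1:
            raise SchemaError("animals do not share the same frame axis")
        self.tracks = dict(tracks)
        self.fps = float(fps)
        self.arena_size_cm = tuple(arena_size_cm)
        self.lights_on = lights_on
        self.lights_off = lights_off
        self.start_clock = start_clock

    @property
    def animals(self) -> list[str]:
        return sorted(self.tracks)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.tracks.values())).detected)

    @property
    def n_animals(self) -> int:
        return len(self.tracks)

    def track(self, animal_id: str) -> AnimalTrack:
        return self.tracks[animal_id]

    def pairs(self) -> list[tuple[str, str]]:
        """Unordered animal pairs, lexicographic."""
        ids = self.animals
        return [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]

    def to_dataframe(self) -> pd.DataFrame:
        frames = np.arange(self.n_frames)
        parts = []
        for aid in self.animals:
            t = self.tracks[aid]
            parts.append(
                pd.DataFrame(
                    {
                        "frame": frames,
                        "time_s": frames / self.fps,
                        "animal_id": aid,
                        "nose_x": t.nose[:, 0],
                        "nose_y": t.nose[:, 1],
                        "center_x": t.center[:, 0],
                        "center_y": t.center[:, 1],
                        "tail_x": t.tail[:, 0],
                        "tail_y": t.tail[:, 1],
                        "body_slope": t.body_slope,
                        "detected": t.detected,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        fps: float = 30.0,
        arena_size_cm: tuple[float, float] = (50.0, 50.0),
        **kwargs,
    ) -> "TrajectorySet":
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        tracks: dict[str, AnimalTrack] = {}
        expected = None
        for aid, sub in df.groupby("animal_id", sort=True):
            sub = sub.sort_values("frame")
            frames = sub["frame"].to_numpy()
            if len(np.unique(frames)) != len(frames):
                dup = int(frames[np.flatnonzero(np.diff(frames) == 0)[0]])
                raise SchemaError(
                    f"duplicate (frame, animal) row: frame {dup}, animal {aid}"
                )
            gaps = np.flatnonzero(np.diff(frames) > 1)
            if frames.size and frames[0] != 0:
                raise SchemaError(f"frames for {aid} do not start at 0")
            if gaps.size:
                missing_frame = int(frames[gaps[0]]) + 1
                raise SchemaError(
                    f"gap in frame sequence for {aid} at frame {missing_frame}"
                )
            if expected is None:
                expected = len(frames)
            elif len(frames) != expected:
                raise SchemaError("animals do not share the same frame axis")
            tracks[str(aid)] = AnimalTrack(
                nose=sub[["nose_x", "nose_y"]].to_numpy(float),
                center=sub[["center_x", "center_y"]].to_numpy(float),
                tail=sub[["tail_x", "tail_y"]].to_numpy(float),
                body_slope=sub["body_slope"].to_numpy(float),
                detected=sub["detected"].to_numpy(bool),
            )
        return cls(tracks, fps=fps, arena_size_cm=arena_size_cm, **kwargs)


# ---------------------------------------------------------------------------
# Group design
# ---------------------------------------------------------------------------

GENOTYPES = ("wt", "del")


@dataclass
class GroupDesign:
    """Genotype / sex / cage assignment of each animal.

    Quartet cages must contain exactly 2 wt + 2 del animals when the
    selective-interaction analysis is requested.
    """

    genotype: dict[str, str] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)
    cage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aid, g in self.genotype.items():
            if g not in GENOTYPES:
                raise SchemaError(f"unknown genotype {g!r} for animal {aid}")

    @property
    def animals(self) -> list[str]:
        return sorted(self.genotype)

    def cage_members(self, cage_id: str) -> list[str]:
        return sorted(a for a, c in self.cage.items() if c == cage_id)

    def cages(self) -> list[str]:
        return sorted(set(self.cage.values()))

    def same_genotype(self, a: str, b: str) -> bool:
        return self.genotype[a] == self.genotype[b]

    def validate_mixed_quartet(self, cage_id: str) -> None:
        members = self.cage_members(cage_id)
        counts = {g: 0 for g in GENOTYPES}
        for a in members:
            counts[self.genotype[a]] += 1
        if len(members) != 4 or counts["wt"] != 2 or counts["del"] != 2:
            raise ValueError(
                f"cage {cage_id} is not a 2 wt + 2 del quartet: {counts}"
            )

    def chance_level_same_genotype(self, cage_id: str, focal: str) -> float:
        """Analytic probability of drawing a same-genotype partner uniformly.

        For a 2 wt + 2 del quartet this is 1/3 (1 same-genotype partner out
        of 3); computed from the composition so other designs are supported.
        """
        members = self.cage_members(cage_id)
        partners = [a for a in members if a != focal]
        if not partners:
            raise ValueError(f"focal {focal} has no cage mates in {cage_id}")
        same = sum(1 for p in partners if self.same_genotype(focal, p))
        return same / len(partners)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animals,
                "genotype": [self.genotype[a] for a in self.animals],
                "sex": [self.sex.get(a, "F") for a in self.animals],
                "cage_id": [self.cage.get(a, "c0") for a in self.animals],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GroupDesign":
        required = {"animal_id", "genotype", "sex", "cage_id"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(sorted(missing))}")
        return cls(
            genotype=dict(zip(df["animal_id"].astype(str), df["genotype"])),
            sex=dict(zip(df["animal_id"].astype(str), df["sex"])),
            cage=dict(zip(df["animal_id"].astype(str), df["cage_id"].astype(str))),
        )
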