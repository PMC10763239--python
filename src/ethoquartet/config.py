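"""Analysis configuration.

All geometric thresholds of the contact detector live here because the
original tracking system's constants are not published: the defaults are
plausible for adult mice (whisker-length proximity ~2 cm, body-body contact
~1.5 cm) and every value is overridable from a single JSON document.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AnalysisConfig", "night_windows_from_schedule"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the detection and analysis pipeline.

    Parameters
    ----------
    fps
        Frame rate of the tracking system (frames/s).
    speed_threshold_cm_s
        Mass-centre speed above which an animal counts as moving.  5 cm/s,
        shared by the move/idle split and the follow definition.
    contact_distance_cm
        Body polyline to body polyline distance below which two animals are
        in contact.
    whisker_distance_cm
        Nose-to-point proximity standing in for sniffing contact.
    side_side_angle_deg
        Heading-difference bound: side-side if the headings are within this
        angle, head-to-tail if within this angle of 180 deg.
    slope_threshold
        Body-slope value above which a posture counts as rearing.
    follow_zone_width_bl, follow_zone_length_bl
        Follow zone trailing the leader, in units of mean body length.
    jump_speed_multiplier
        A jump requires wall proximity and speed above
        ``jump_speed_multiplier * speed_threshold_cm_s`` (approximate; 2-D
        poses carry no vertical cue).
    wall_distance_cm
        Distance from the arena boundary below which an animal is near-wall.
    max_gap_frames
        Interruptions up to this many frames are bridged when building event
        intervals (0 = no debouncing).
    usv_gap_ms
        Silent gap at or above which two consecutive USVs belong to
        different sequences (strictly-less-than rule: gaps < 750 ms chain).
    usv_jump_threshold_khz
        Frequency step between consecutive contour samples counted as a jump.
    """

    fps: float = 30.0
    speed_threshold_cm_s: float = 5.0
    contact_distance_cm: float = 1.5
    whisker_distance_cm: float = 2.0
    side_side_angle_deg: float = 45.0
    slope_threshold: float = 0.5
    follow_zone_width_bl: float = 1.0
    follow_zone_length_bl: float = 2.0
    jump_speed_multiplier: float = 3.0
    wall_distance_cm: float = 2.0
    max_gap_frames: int = 0
    usv_gap_ms: float = 750.0
    usv_jump_threshold_khz: float = 10.0
    night_windows: list[tuple[int, int]] | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "fps", "speed_threshold_cm_s", "contact_distance_cm",
            "whisker_distance_cm", "slope_threshold", "follow_zone_width_bl",
            "follow_zone_length_bl", "jump_speed_multiplier",
            "wall_distance_cm", "usv_gap_ms", "usv_jump_threshold_khz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.side_side_angle_deg < 90.0:
            raise ValueError("side_side_angle_deg must be in (0, 90)")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")

    @property
    def jump_speed_cm_s(self) -> float:
        return self.jump_speed_multiplier * self.speed_threshold_cm_s

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if data.get("night_windows") is not None:
            data["night_windows"] = [tuple(w) for w in data["night_windows"]]
        return cls(**data)


def _clock_to_s(clock: str) -> float:
    h, m = clock.split(":")
    return int(h) * 3600 + int(m) * 60


def night_windows_from_schedule(
    n_frames: int,
    fps: float,
    start_clock: str = "15:30",
    lights_off: str = "19:00",
    lights_on: str = "07:00",
) -> list[tuple[int, int]]:
    """Dark-phase frame windows of a recording started at ``start_clock``.

    Returns inclusive (start_frame, end_frame) pairs, one per night fully or
    partly covered by the recording, under a 12/12 h light/dark schedule.
    """
    if n_frames <= 0:
        raise ValueError("empty recording")
    t0 = _clock_to_s(start_clock)
    off = _clock_to_s(lights_off)
    on = _clock_to_s(lights_on)
    total_s = n_frames / fps
    windows: list[tuple[int, int]] = []
    # first lights-off at or after recording start
    first_off = off - t0 if off >= t0 else off - t0 + 86400.0
    night_start = first_off
    night_len = (on - off) % 86400.0
    while night_start < total_s:
        s = max(0.0, night_start)
        e = min(total_s, night_start + night_len)
        sf = int(np.ceil(s * fps)) if s > 0 else 0
        ef = min(n_frames - 1, int(np.floor(e * fps)) - 1)
        if ef >= sf:
            windows.append((sf, ef))
        night_start += 86400.0
    if not windows:
        raise ValueError("recording does not cover any dark phase")
    return windows
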