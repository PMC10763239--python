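"""Ultrasonic vocalisation analysis: sequences, acoustic features, synchrony.

USVs arrive as detected calls with an onset, a duration and a peak-frequency
contour (kHz samples at uniform spacing).  Sequences are maximal chains of
consecutive USVs whose silent gaps (previous offset to next onset) are
strictly below 750 ms.  Because the emitter cannot be identified when two
animals interact closely, all synchrony metrics are computed at the pair
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Ethogram

__all__ = [
    "USVRecord",
    "USVSequence",
    "segment_sequences",
    "compute_acoustic_features",
    "features_table",
    "compute_synchrony",
]


@dataclass
class USVRecord:
    """One ultrasonic vocalisation."""

    onset_s: float
    duration_ms: float
    contour: np.ndarray  # peak frequency, kHz

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=float)
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")
        if self.contour.size == 0:
            raise ValueError("empty contour")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_ms / 1000.0


@dataclass
class USVSequence:
    """Consecutive USVs separated by silent gaps under the threshold."""

    usvs: list[USVRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.usvs)

    @property
    def start_s(self) -> float:
        return self.usvs[0].onset_s

    @property
    def end_s(self) -> float:
        return self.usvs[-1].offset_s


def segment_sequences(
    usvs: list[USVRecord], gap_ms: float = 750.0, gap_from_onset: bool = False
) -> list[USVSequence]:
    """Greedy left-to-right chaining on the silent-gap rule.

    A USV joins the current sequence iff its gap to the previous USV is
    strictly less than ``gap_ms``.  The gap is measured offset-to-onset by
    default (``gap_from_onset=True`` switches to onset-to-onset).
    Overlapping USVs raise ``ValueError``.
    """
    if not usvs:
        return []
    ordered = sorted(usvs, key=lambda u: u.onset_s)
    sequences = [USVSequence([ordered[0]])]
    for prev, cur in zip(ordered, ordered[1:]):
        ref = prev.onset_s if gap_from_onset else prev.offset_s
        gap = (cur.onset_s - ref) * 1000.0
        if not gap_from_onset and gap < 0:
            raise ValueError(
                f"overlapping USVs at onset {cur.onset_s:.3f} s"
            )
        if gap < gap_ms:
            sequences[-1].usvs.append(cur)
        else:
            sequences.append(USVSequence([cur]))
    return sequences


def compute_acoustic_features(
    contour: np.ndarray, jump_threshold_khz: float = 10.0
) -> dict[str, float]:
    """Acoustic features of a peak-frequency contour.

    - frequency_range_khz: max - min
    - mean_peak_khz: arithmetic mean
    - n_modulations: inflexion points, i.e. sign changes of consecutive
      contour differences with plateaus (zero differences) skipped
    - n_jumps: consecutive differences whose magnitude exceeds the jump
      threshold
    """
    contour = np.asarray(contour, dtype=float)
    if contour.size == 0:
        raise ValueError("empty contour")
    diffs = np.diff(contour)
    signs = np.sign(diffs)
    signs = signs[signs != 0]
    n_mod = int(np.count_nonzero(signs[1:] != signs[:-1])) if signs.size > 1 else 0
    n_jumps = int(np.count_nonzero(np.abs(diffs) > jump_threshold_khz))
    return {
        "frequency_range_khz": float(contour.max() - contour.min()),
        "mean_peak_khz": float(contour.mean()),
        "n_modulations": n_mod,
        "n_jumps": n_jumps,
    }


def features_table(
    usvs: list[USVRecord], jump_threshold_khz: float = 10.0
) -> pd.DataFrame:
    """Tidy per-USV feature table."""
    rows = []
    for u in usvs:
        feats = compute_acoustic_features(u.contour, jump_threshold_khz)
        rows.append({"onset_s": u.onset_s, "duration_ms": u.duration_ms, **feats})
    return pd.DataFrame(
        rows,
        columns=[
            "onset_s", "duration_ms", "frequency_range_khz",
            "mean_peak_khz", "n_modulations", "n_jumps",
        ],
    )


def compute_synchrony(
    usvs: list[USVRecord],
    ethogram: Ethogram,
    fps: float,
    n_frames: int,
    event_types: list[str] | None = None,
) -> pd.DataFrame:
    """USV-behaviour synchrony per event type (pair level).

    A USV is synchronous with an event iff their time intervals overlap.
    An event interval [s, e] in frames spans [s/fps, (e+1)/fps) seconds.
    For each event type, reports the proportion of all USVs overlapping at
    least one event of that type, the proportion of events of that type
    overlapped by at least one USV, and the call rate (USVs overlapping the
    context per minute of context time).  USVs outside the recording span
    are excluded with a warning.
    """
    span_s = n_frames / fps
    kept = [u for u in usvs if u.onset_s < span_s and u.offset_s > 0]
    if len(kept) < len(usvs):
        warnings.warn(
            f"{len(usvs) - len(kept)} USV(s) outside the recording span excluded",
            stacklevel=2,
        )
    if event_types is None:
        event_types = sorted({e.event_type for e in ethogram})
    onsets = np.array([u.onset_s for u in kept])
    offsets = np.array([u.offset_s for u in kept])
    rows = []
    for etype in event_types:
        events = [e for e in ethogram if e.event_type == etype]
        starts = np.array([e.start_frame / fps for e in events])
        ends = np.array([(e.end_frame + 1) / fps for e in events])
        if kept and events:
            # overlap matrix: usv i overlaps event j
            ov = (onsets[:, None] < ends[None, :]) & (offsets[:, None] > starts[None, :])
            usv_hit = ov.any(axis=1)
            event_hit = ov.any(axis=0)
        else:
            usv_hit = np.zeros(len(kept), dtype=bool)
            event_hit = np.zeros(len(events), dtype=bool)
        total_min = float((ends - starts).sum()) / 60.0 if events else 0.0
        rows.append(
            {
                "event_type": etype,
                "n_events": len(events),
                "n_usvs_overlapping": int(usv_hit.sum()),
                "prop_usvs_in_event": (
                    float(usv_hit.mean()) if kept else 0.0
                ),
                "prop_events_with_usv": (
                    float(event_hit.mean()) if events else 0.0
                ),
                "call_rate_per_min": (
                    float(usv_hit.sum()) / total_min if total_min > 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
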