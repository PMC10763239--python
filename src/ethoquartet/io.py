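"""Readers and writers for the tabular interchange formats.

The original tracking system's database formats are not consumed here; the
pipeline exchanges plain CSV files with the following schemas:

- trajectories.csv: frame,time_s,animal_id,nose_x,nose_y,center_x,center_y,
  tail_x,tail_y,body_slope,detected
- events.csv: event_type,actor,partners (``|``-joined),start_frame,end_frame
- usv.csv: onset_s,duration_ms,contour (``;``-joined kHz samples)
- design.csv: animal_id,genotype,sex,cage_id
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .model import (
    Ethogram,
    EventInterval,
    GroupDesign,
    SchemaError,
    TrajectorySet,
)
from .usv import USVRecord

__all__ = [
    "read_trajectories", "write_trajectories",
    "read_events", "write_events",
    "read_usv_table", "write_usv_table",
    "read_design", "write_design",
]


def read_trajectories(
    path: str | Path, config: AnalysisConfig | None = None, **kwargs
) -> TrajectorySet:
    """Read and validate a trajectories.csv file.

    Raises :class:`SchemaError` naming the offending field on missing
    columns, duplicate (frame, animal) rows, or gaps in the frame sequence.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path)
    traj = TrajectorySet.from_dataframe(df, fps=config.fps, **kwargs)
    # time consistency: time_s == frame / fps within float tolerance
    t = df["time_s"].to_numpy(float)
    expected = df["frame"].to_numpy(float) / config.fps
    if not np.allclose(t, expected, atol=1.0 / config.fps):
        raise SchemaError("time_s inconsistent with frame / fps")
    return traj


def write_trajectories(traj: TrajectorySet, path: str | Path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


EVENT_COLUMNS = ("event_type", "actor", "partners", "start_frame", "end_frame")


def write_events(ethogram: Ethogram, path: str | Path) -> None:
    """One CSV row per interval; partners joined with ``|``."""
    rows = [
        {
            "event_type": e.event_type,
            "actor": e.actor,
            "partners": "|".join(sorted(e.partners)),
            "start_frame": e.start_frame,
            "end_frame": e.end_frame,
        }
        for e in ethogram
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> Ethogram:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    intervals = [
        EventInterval(
            event_type=row.event_type,
            actor=str(row.actor),
            partners=frozenset(
                p for p in str(row.partners).split("|") if p
            ),
            start_frame=int(row.start_frame),
            end_frame=int(row.end_frame),
        )
        for row in df.itertuples()
    ]
    return Ethogram(intervals)


def read_usv_table(path: str | Path) -> list[USVRecord]:
    """Read usv.csv; contours parsed to kHz arrays, records sorted by onset."""
    df = pd.read_csv(path)
    required = {"onset_s", "duration_ms", "contour"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(sorted(missing))}")
    records = []
    for row in df.itertuples():
        if row.duration_ms <= 0:
            raise SchemaError(f"non-positive duration_ms: {row.duration_ms}")
        raw = "" if pd.isna(row.contour) else str(row.contour)
        contour = np.array([float(x) for x in raw.split(";") if x.strip()])
        if contour.size == 0 or not np.isfinite(contour).all():
            raise SchemaError(f"empty contour at onset {row.onset_s}")
        records.append(
            USVRecord(
                onset_s=float(row.onset_s),
                duration_ms=float(row.duration_ms),
                contour=contour,
            )
        )
    return sorted(records, key=lambda r: r.onset_s)


def write_usv_table(records: list[USVRecord], path: str | Path) -> None:
    rows = [
        {
            "onset_s": r.onset_s,
            "duration_ms": r.duration_ms,
            "contour": ";".join(f"{x:.3f}" for x in r.contour),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["onset_s", "duration_ms", "contour"]).to_csv(
        path, index=False
    )


def read_design(path: str | Path) -> GroupDesign:
    return GroupDesign.from_dataframe(pd.read_csv(path))


def write_design(design: GroupDesign, path: str | Path) -> None:
    design.to_dataframe().to_csv(path, index=False)
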