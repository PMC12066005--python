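"""Readers and writers for trajectory tables, fall-event lists, and timestamps.

All files are plain delimited text (CSV).  A trajectory table has columns
``frame, x, y, width, height, confidence`` where ``(x, y)`` is the top-left
corner of the bounding box; the fly position is taken as the box centroid.
Rows with blank coordinates mark frames where the detector produced no
output and are omitted from the trajectory (gaps are encoded by absence).
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import (
    Detection,
    FallEvent,
    ParseError,
    Trajectory,
    ValidationError,
    validate_events_sorted,
)

TRAJECTORY_COLUMNS = ["frame", "x", "y", "width", "height", "confidence"]
EVENT_COLUMNS = [
    "start_time_s",
    "end_time_s",
    "start_y",
    "end_y",
    "delta_y_px",
    "delta_y_cm",
]


def _is_blank(value: str) -> bool:
    return value is None or str(value).strip() == ""


def _fmt(value: float) -> str:
    """Shortest exact decimal form of a float (round-trips via repr)."""
    return repr(float(value))


def read_trajectory(path: str | Path, fps: float, source_id: str | None = None) -> Trajectory:
    """Read a per-frame detection table into a :class:`Trajectory`.

    Rows whose coordinate fields are blank are treated as frames with no
    detection and omitted.  Malformed rows raise :class:`ParseError`
    naming the offending line; duplicate or unsorted frames raise
    :class:`ValidationError`.
    """
    path = Path(path)
    detections: list[Detection] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise ParseError(f"{path}: empty file (header required)")
    header = [c.strip().lower() for c in rows[0]]
    missing = [c for c in TRAJECTORY_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    idx = {c: header.index(c) for c in TRAJECTORY_COLUMNS}
    for lineno, row in enumerate(rows[1:], start=2):
        try:
            frame_field = row[idx["frame"]]
        except IndexError:
            raise ParseError(f"{path}: line {lineno}: too few fields") from None
        coord_fields = [row[idx[c]] if idx[c] < len(row) else "" for c in ("x", "y", "width", "height")]
        if all(_is_blank(f) for f in coord_fields):
            continue  # frame with no detection
        try:
            frame = int(frame_field)
            x, y, w, h = (float(f) for f in coord_fields)
            conf_field = row[idx["confidence"]] if idx["confidence"] < len(row) else ""
            conf = 1.0 if _is_blank(conf_field) else float(conf_field)
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: line {lineno}: malformed row ({exc})") from None
        if not all(math.isfinite(v) for v in (x, y, w, h, conf)):
            raise ParseError(f"{path}: line {lineno}: non-finite value")
        try:
            detections.append(
                Detection(
                    frame_index=frame,
                    time_s=frame / fps,
                    bbox=(x, y, w, h),
                    centroid=(x + w / 2.0, y + h / 2.0),
                    confidence=conf,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return Trajectory(
        source_id=source_id or path.stem,
        fps=fps,
        detections=detections,
    )


def write_trajectory(traj: Trajectory, path: str | Path, header_comment: str | None = None) -> None:
    """Write a trajectory as a detection table (inverse of :func:`read_trajectory`)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(TRAJECTORY_COLUMNS)
        for d in traj.detections:
            x, y, w, h = d.bbox
            writer.writerow(
                [d.frame_index, _fmt(x), _fmt(y), _fmt(w), _fmt(h), _fmt(d.confidence)]
            )


def write_fall_events(
    events: Sequence[FallEvent], path: str | Path, header_comment: str | None = None
) -> None:
    """Write the scored fall list: timestamps and Y-direction displacement.

    Events must be sorted by start time.  The written table round-trips
    through :func:`read_fall_events` field-for-field.
    """
    validate_events_sorted(events)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow(
                [
                    _fmt(e.start_time_s),
                    _fmt(e.end_time_s),
                    _fmt(e.start_y),
                    _fmt(e.end_y),
                    _fmt(e.delta_y_px),
                    _fmt(e.delta_y_cm),
                ]
            )


def read_fall_events(path: str | Path) -> list[FallEvent]:
    """Read a fall-event table written by :func:`write_fall_events`."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            FallEvent(
                start_time_s=float(row.start_time_s),
                end_time_s=float(row.end_time_s),
                start_y=float(row.start_y),
                end_y=float(row.end_y),
                delta_y_px=float(row.delta_y_px),
                delta_y_cm=float(row.delta_y_cm),
            )
        )
    return events


def read_timestamps(path: str | Path) -> list[float]:
    """Read ground-truth fall timestamps: one value in seconds per row.

    A header line is optional; an extra hour column, if present, is
    ignored.  Returns timestamps sorted ascending.
    """
    path = Path(path)
    times: list[float] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#") or _is_blank(row[0]):
                continue
            try:
                times.append(float(row[0]))
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError(f"{path}: line {lineno}: not a timestamp: {row[0]!r}")
    return sorted(times)


def write_timestamps(times: Sequence[float], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("time_s\n")
        for t in times:
            fh.write(f"{_fmt(t)}\n")
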