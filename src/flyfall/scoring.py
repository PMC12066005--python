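"""Fall scoring from a trajectory: the core computation.

A fall is a rapid downward movement of the fly from the vial wall to
the bottom surface.  Because the descent is too fast for per-frame
detection, a fall manifests as a *gap* in the trajectory that starts
high and ends low.  Scoring therefore scans consecutive detection
pairs ``(d_i, d_{i+1})`` and scores a fall when all of:

a. the elapsed time between them is at most ``max_fall_duration_s``;
b. the downward displacement ``cy_{i+1} - cy_i`` is at least
   ``y_threshold_px`` (60 px default; 160 px is the strict setting that
   excludes short drops starting below the half-height line);
c. the end position lies within the bottom region of the vial;
d. (optional) the start position lies in the upper 50% of the available
   area — the definition used for manual ground-truth annotation.

Each qualifying pair yields exactly one event, so events never overlap.
The fall timestamp is the time of the last detection before the gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    FallEvent,
    FlyfallError,
    HourlySummary,
    Trajectory,
    ValidationError,
    VialGeometry,
    make_fall_event,
)


@dataclass(frozen=True)
class FallParams:
    """Scoring thresholds.

    y_threshold_px: minimum downward displacement between successive
        detections (default 60 px on a ~325 px vial; 160 px strict).
    max_fall_duration_s: maximum elapsed time across the gap for the
        displacement to count as "rapid" (default 1.0 s).
    require_upper_start: when True, additionally require the start
        position in the upper half of the vial (the manual ground-truth
        definition); when False, score any qualifying drop, as the
        automated pipeline does.
    bottom_fraction: depth of the "bottom surface" region as a fraction
        of the vial height; the fall must end inside it.
    """

    y_threshold_px: float = 60.0
    max_fall_duration_s: float = 1.0
    require_upper_start: bool = False
    bottom_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.y_threshold_px <= 0:
            raise ValidationError(f"y_threshold_px must be > 0, got {self.y_threshold_px}")
        if self.max_fall_duration_s <= 0:
            raise ValidationError(
                f"max_fall_duration_s must be > 0, got {self.max_fall_duration_s}"
            )
        if not 0.0 < self.bottom_fraction <= 1.0:
            raise ValidationError(
                f"bottom_fraction must be in (0, 1], got {self.bottom_fraction}"
            )


# strict threshold used to separate genuine falls from short drops that
# begin below the half-height line
STRICT_Y_THRESHOLD_PX = 160.0


def detect_falls(
    traj: Trajectory,
    geometry: VialGeometry,
    params: FallParams | None = None,
) -> list[FallEvent]:
    """Score falls in a trajectory by the displacement/region criteria.

    Returns fall events sorted by start time; an empty trajectory
    yields an empty list.
    """
    params = params or FallParams()
    bottom_start = geometry.bottom_region_start(params.bottom_fraction)
    upper_boundary = geometry.upper_boundary_y
    events: list[FallEvent] = []
    dets = traj.detections
    for d0, d1 in zip(dets, dets[1:]):
        dt = d1.time_s - d0.time_s
        dy = d1.cy - d0.cy
        if dt > params.max_fall_duration_s:
            continue
        if dy < params.y_threshold_px:
            continue
        if d1.cy < bottom_start:
            continue
        if params.require_upper_start and not d0.cy < upper_boundary:
            continue
        events.append(
            make_fall_event(
                start_time_s=d0.time_s,
                end_time_s=d1.time_s,
                start_y=d0.cy,
                end_y=d1.cy,
                geometry=geometry,
            )
        )
    return events


def total_movement(traj: Trajectory) -> float:
    """Total path length in pixels: sum over successive detections of
    sqrt(dx^2 + dy^2).

    Pairs spanning gaps are included — the displacement across a fall
    gap is real movement.  Trajectories with fewer than two detections
    have zero movement.
    """
    if len(traj) < 2:
        return 0.0
    cx = np.array([d.cx for d in traj.detections])
    cy = np.array([d.cy for d in traj.detections])
    return float(np.hypot(np.diff(cx), np.diff(cy)).sum())


def hourly_summaries(
    traj: Trajectory,
    events: list[FallEvent],
    hours: set[int] | None = None,
) -> list[HourlySummary]:
    """Bin falls and movement into hours.

    Hour ``h`` covers ``[3600*h, 3600*(h+1))`` seconds.  An event
    belongs to the hour of its start time; a detection pair contributes
    its displacement to the hour of its earlier member.  When ``hours``
    is None the hours spanned by the trajectory (or, failing that, the
    events) are used.
    """
    if hours is None:
        hour_set: set[int] = set()
        for d in traj.detections:
            hour_set.add(int(d.time_s // 3600))
        for e in events:
            hour_set.add(int(e.start_time_s // 3600))
    else:
        hour_set = set(hours)
    movement: dict[int, float] = {h: 0.0 for h in hour_set}
    for d0, d1 in zip(traj.detections, traj.detections[1:]):
        h = int(d0.time_s // 3600)
        if h in movement:
            movement[h] += float(np.hypot(d1.cx - d0.cx, d1.cy - d0.cy))
    falls: dict[int, int] = {h: 0 for h in hour_set}
    for e in events:
        h = int(e.start_time_s // 3600)
        if h in falls:
            falls[h] += 1
    return [
        HourlySummary(hour_index=h, falls=falls[h], movement_px=movement[h])
        for h in sorted(hour_set)
    ]


def normalize_falls(summaries: list[HourlySummary]) -> list[HourlySummary]:
    """Normalize hourly fall counts to total movement per hour.

    Each hour's movement is expressed in *relative units* — that hour's
    movement divided by the mean hourly movement (over hours with any
    movement) — and the fall count is divided by the relative unit.
    An hour with average movement therefore keeps its raw fall count,
    while a sluggish hour with the same falls is scored higher.  An
    hour with falls but zero movement is inconsistent (a scored fall
    implies displacement) and raises an error.
    """
    if not summaries:
        raise ValidationError("normalize_falls requires at least one summary")
    moving = [s.movement_px for s in summaries if s.movement_px > 0]
    mean_movement = float(np.mean(moving)) if moving else 0.0
    out: list[HourlySummary] = []
    for s in summaries:
        if s.movement_px == 0:
            if s.falls > 0:
                raise FlyfallError(
                    f"hour {s.hour_index}: {s.falls} falls with zero movement — "
                    "a scored fall implies a displacement contributing to movement"
                )
            norm = 0.0
        else:
            relative_unit = s.movement_px / mean_movement
            norm = 0.0 if s.falls == 0 else s.falls / relative_unit
        out.append(
            HourlySummary(
                hour_index=s.hour_index,
                falls=s.falls,
                movement_px=s.movement_px,
                normalized_falls=norm,
            )
        )
    return out
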