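"""Domain types for single-fly vial tracking.

Coordinate convention: image coordinates, origin at the top-left corner,
y increases *downward*.  A fall therefore has positive vertical
displacement (``end_y - start_y > 0``), and "upper region" tests use
``y < boundary``.  Timestamps are ``frame_index / fps`` seconds from the
start of the recording; hour ``k`` covers the half-open interval
``[3600*k, 3600*(k+1))`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence


class FlyfallError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(FlyfallError, ValueError):
    """An object or argument violates a documented invariant."""


class ParseError(FlyfallError, ValueError):
    """A delimited input file could not be parsed."""


@dataclass(frozen=True)
class Detection:
    """One per-frame localization of the fly.

    ``bbox`` is ``(x, y, width, height)`` in pixels; ``centroid`` is
    ``(cx, cy)`` and must lie inside the box.  ``confidence`` is a
    unitless score in [0, 1].
    """

    frame_index: int
    time_s: float
    bbox: tuple[float, float, float, float]
    centroid: tuple[float, float]
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValidationError(f"bbox width/height must be > 0, got {(w, h)}")
        cx, cy = self.centroid
        if not (x <= cx <= x + w and y <= cy <= y + h):
            raise ValidationError(
                f"centroid {self.centroid} lies outside bbox {self.bbox}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence must be in [0,1], got {self.confidence}")

    @property
    def cx(self) -> float:
        return self.centroid[0]

    @property
    def cy(self) -> float:
        return self.centroid[1]


@dataclass
class Trajectory:
    """Time-ordered detections for one recording.

    Missing frames are encoded by absence: gaps carry meaning (the fly
    moves too fast to be detected during a fall, so falls appear as gaps
    that start high and end low).
    """

    source_id: str
    fps: float
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        frames = [d.frame_index for d in self.detections]
        for a, b in zip(frames, frames[1:]):
            if b <= a:
                raise ValidationError(
                    f"detections must be strictly sorted by frame_index; "
                    f"saw frame {b} after frame {a}"
                )

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self) -> Iterator[Detection]:
        return iter(self.detections)

    @property
    def duration_s(self) -> float:
        if not self.detections:
            return 0.0
        return self.detections[-1].time_s - self.detections[0].time_s


@dataclass(frozen=True)
class VialGeometry:
    """Pixel calibration of the vial region.

    ``top_y`` is the pixel row of the stopper's lower edge and
    ``bottom_y`` the row of the vial floor (y grows downward, so
    ``bottom_y > top_y``).  The physical span between them is
    ``height_cm`` (3 cm in the standard assay, corresponding to roughly
    325 pixels at the standard camera distance).
    """

    top_y: float = 50.0
    bottom_y: float = 375.0
    height_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.bottom_y <= self.top_y:
            raise ValidationError(
                f"bottom_y ({self.bottom_y}) must exceed top_y ({self.top_y}); "
                "image y grows downward"
            )
        if self.height_cm <= 0:
            raise ValidationError(f"height_cm must be > 0, got {self.height_cm}")

    @property
    def height_px(self) -> float:
        return self.bottom_y - self.top_y

    @property
    def upper_boundary_y(self) -> float:
        """Row separating the upper 50% of the available area (y < boundary)."""
        return self.top_y + 0.5 * self.height_px

    def bottom_region_start(self, bottom_fraction: float) -> float:
        """Row above the floor marking the bottom region of given fractional depth."""
        if not 0.0 < bottom_fraction <= 1.0:
            raise ValidationError(
                f"bottom_fraction must be in (0, 1], got {bottom_fraction}"
            )
        return self.bottom_y - bottom_fraction * self.height_px


def px_to_cm(dy_px: float, geometry: VialGeometry) -> float:
    """Convert a vertical pixel displacement to centimeters.

    Uses the vial calibration: ``height_cm`` physical span over
    ``bottom_y - top_y`` pixel rows (3 cm over ~325 px by default).
    """
    return dy_px * geometry.height_cm / geometry.height_px


@dataclass(frozen=True)
class FallEvent:
    """One scored fall: a downward displacement across a trajectory gap."""

    start_time_s: float
    end_time_s: float
    start_y: float
    end_y: float
    delta_y_px: float
    delta_y_cm: float

    def __post_init__(self) -> None:
        if self.end_time_s < self.start_time_s:
            raise ValidationError(
                f"end_time_s ({self.end_time_s}) precedes start_time_s "
                f"({self.start_time_s})"
            )
        if self.delta_y_px <= 0:
            raise ValidationError(
                f"falls are downward: delta_y_px must be > 0, got {self.delta_y_px}"
            )


def make_fall_event(
    start_time_s: float,
    end_time_s: float,
    start_y: float,
    end_y: float,
    geometry: VialGeometry,
) -> FallEvent:
    """Build a :class:`FallEvent`, deriving displacements from positions."""
    dy = end_y - start_y
    return FallEvent(
        start_time_s=start_time_s,
        end_time_s=end_time_s,
        start_y=start_y,
        end_y=end_y,
        delta_y_px=dy,
        delta_y_cm=px_to_cm(dy, geometry),
    )


@dataclass(frozen=True)
class HourlySummary:
    """Fall count and movement for one hour of recording."""

    hour_index: int
    falls: int
    movement_px: float
    normalized_falls: float = 0.0

    def __post_init__(self) -> None:
        if self.falls < 0:
            raise ValidationError(f"falls must be >= 0, got {self.falls}")
        if self.movement_px < 0:
            raise ValidationError(f"movement_px must be >= 0, got {self.movement_px}")


def validate_events_sorted(events: Sequence[FallEvent]) -> None:
    for a, b in zip(events, events[1:]):
        if b.start_time_s < a.start_time_s:
            raise ValidationError(
                f"fall events must be sorted by start_time_s; "
                f"{b.start_time_s} follows {a.start_time_s}"
            )
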