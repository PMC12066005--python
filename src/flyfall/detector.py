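"""Per-frame fly localization by background subtraction.

Localizes the single fly in grayscale IR video: a static background
model (per-pixel median of sampled frames) is subtracted from each
frame, the absolute difference is thresholded, and the largest connected
foreground component becomes the detection.  Static features such as the
bright glare from the vial stopper cancel in the subtraction, while the
moving fly survives it.

A frame may legitimately yield no detection: during a rapid fall the fly
smears into a faint motion streak and drops below the foreground
threshold, so falls appear downstream as trajectory gaps.  Detection
tables produced by any other detector can be scored identically through
:func:`flyfall.io.read_trajectory`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.measure import label, regionprops

from .core import Detection, Trajectory, ValidationError, VialGeometry


@dataclass(frozen=True)
class DetectorParams:
    """Tunables for background subtraction.

    intensity_threshold: minimum |frame - background| (of 255) for a
        pixel to count as foreground.
    min_area: minimum component area in px^2 to accept as the fly.
    bg_frames: number of uniformly spaced frames sampled for the
        background model.
    """

    intensity_threshold: float = 25.0
    min_area: int = 9
    bg_frames: int = 25


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pixel median of sampled frames."""

    reference_image: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.reference_image.shape


def build_background(frames: Sequence[np.ndarray]) -> BackgroundModel:
    """Build the background as the per-pixel median of the given frames.

    The median suppresses the fly, which is a transient blob occupying
    any given pixel in only a minority of sampled frames.
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("build_background requires at least one frame")
    shape = np.asarray(frames[0]).shape
    for i, f in enumerate(frames):
        if np.asarray(f).shape != shape:
            raise ValidationError(
                f"frame {i} has shape {np.asarray(f).shape}, expected {shape}"
            )
    stack = np.stack([np.asarray(f, dtype=np.float64) for f in frames])
    return BackgroundModel(reference_image=np.median(stack, axis=0))


def detect_fly(
    frame: np.ndarray,
    bg: BackgroundModel,
    min_area: int = 9,
    intensity_threshold: float = 25.0,
    *,
    frame_index: int = 0,
    fps: float = 30.0,
) -> Detection | None:
    """Localize the fly in one frame, or return None if nothing qualifies.

    The absolute difference from the background is thresholded at
    ``intensity_threshold``; among connected foreground components the
    largest is taken, and accepted if its area is at least ``min_area``.
    Confidence is ``min(1, area / (4 * min_area))`` so a component at
    the bare minimum area scores 0.25 and a comfortably large one
    saturates at 1.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != bg.shape:
        raise ValidationError(
            f"frame shape {frame.shape} does not match background {bg.shape}"
        )
    mask = np.abs(frame - bg.reference_image) >= intensity_threshold
    if not mask.any():
        return None
    labels = label(mask, connectivity=2)
    regions = regionprops(labels)
    best = max(regions, key=lambda r: r.area)
    if best.area < min_area:
        return None
    r0, c0, r1, c1 = best.bbox  # skimage: (min_row, min_col, max_row, max_col)
    cy, cx = best.centroid
    return Detection(
        frame_index=frame_index,
        time_s=frame_index / fps,
        bbox=(float(c0), float(r0), float(c1 - c0), float(r1 - r0)),
        centroid=(float(cx), float(cy)),
        confidence=min(1.0, best.area / (4.0 * min_area)),
    )


def _open_frames(video) -> Sequence[np.ndarray]:
    """Accept a frame stack (array/sequence supporting len+getitem) or a path."""
    if isinstance(video, (str, Path)):
        import imageio.v3 as iio

        try:
            arr = iio.imread(video)
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise IOError(f"cannot read video {video}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 4:  # color -> grayscale
            arr = arr.mean(axis=-1)
        return arr
    return video


def track_video(
    video,
    fps: float,
    geometry: VialGeometry,
    params: DetectorParams | None = None,
    source_id: str = "video",
) -> Trajectory:
    """Track the fly through a whole recording.

    ``video`` is a file path readable as grayscale frames, or any
    in-memory frame stack supporting ``len`` and integer indexing.
    A background model is built from ``params.bg_frames`` uniformly
    spaced frames; every frame is then localized independently.  Frames
    with no accepted detection become trajectory gaps, and detections
    whose centroid falls outside the vial region ``[top_y, bottom_y]``
    are discarded.
    """
    params = params or DetectorParams()
    frames = _open_frames(video)
    n = len(frames)
    if n == 0:
        return Trajectory(source_id=source_id, fps=fps, detections=[])
    sample_idx = np.unique(np.linspace(0, n - 1, min(params.bg_frames, n)).astype(int))
    bg = build_background([frames[i] for i in sample_idx])
    detections = []
    for i in range(n):
        try:
            frame = frames[i]
        except Exception as exc:  # noqa: BLE001
            raise IOError(f"cannot read frame {i}: {exc}") from exc
        det = detect_fly(
            frame,
            bg,
            min_area=params.min_area,
            intensity_threshold=params.intensity_threshold,
            frame_index=i,
            fps=fps,
        )
        if det is None:
            continue
        if not geometry.top_y <= det.cy <= geometry.bottom_y:
            continue
        detections.append(det)
    return Trajectory(source_id=source_id, fps=fps, detections=detections)
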