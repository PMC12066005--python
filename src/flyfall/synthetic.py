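"""Seeded generator of vial-assay ground truth.

Emulates the standard single-fly assay: one fly in a glass vial with a
3 cm working height (~325 px), recorded from the side at 30 fps under
IR illumination.  The fly performs a bounded random walk on the vial
wall between programmed falls; each fall removes the fly from detection
for 0.1–0.5 s (the descent is too fast to track) and resumes near the
vial floor, reproducing the gap-starts-high-ends-low trajectory
signature that the fall scorer keys on.

The walking kinematics are deliberately simple — a reflected,
bridge-corrected random walk — because only the fall/gap/bottom
structure matters downstream.  Rendered videos show a bright fly on a
dark background with a static glare band near the stopper and a faint
sub-threshold motion streak during each descent.

Everything is driven by a single integer seed: the same spec and seed
reproduce trajectories, videos, and evaluation cases bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    Detection,
    FallEvent,
    FlyfallError,
    Trajectory,
    ValidationError,
    VialGeometry,
    make_fall_event,
)

# minimum spacing between programmed fall onsets; > 2x the 1 s maximum
# fall duration so events can never interact
MIN_FALL_SEPARATION_S = 3.0
_EDGE_MARGIN_S = 5.0

FLY_W, FLY_H = 9.0, 7.0  # emitted bounding-box size, px


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic recording.

    fall_displacement_px is a (low, high) range; with the default
    (200, 320) every programmed fall clears both the 60 px working
    threshold and the 160 px strict threshold, and starts in the upper
    half of the vial, so programmed counts are recoverable at either
    setting and under the manual upper-start definition.
    """

    seed: int
    duration_s: float = 600.0
    fps: float = 30.0
    geometry: VialGeometry = field(default_factory=VialGeometry)
    n_falls: int = 5
    fall_times_s: tuple[float, ...] | None = None
    fall_displacement_px: tuple[float, float] = (200.0, 320.0)
    walk_speed_px_s: float = 40.0
    dropout_rate: float = 0.01
    fall_dropout: bool = True
    noise_px: float = 0.5
    frame_width: int = 160

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValidationError("duration_s and fps must be > 0")
        if self.n_falls < 0:
            raise ValidationError(f"n_falls must be >= 0, got {self.n_falls}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")
        lo, hi = self.fall_displacement_px
        if not 0 < lo <= hi:
            raise ValidationError(f"bad fall_displacement_px range {self.fall_displacement_px}")
        if hi > self.geometry.height_px:
            raise ValidationError(
                "fall displacement range exceeds the vial height "
                f"({hi} > {self.geometry.height_px})"
            )
        if self.fall_times_s is not None:
            times = list(self.fall_times_s)
            if len(times) != self.n_falls:
                raise ValidationError(
                    f"fall_times_s has {len(times)} entries for n_falls={self.n_falls}"
                )
            if any(not 0 <= t < self.duration_s for t in times):
                raise ValidationError("fall_times_s must lie within [0, duration_s)")
            for a, b in zip(sorted(times), sorted(times)[1:]):
                if b - a < MIN_FALL_SEPARATION_S:
                    raise FlyfallError(
                        f"falls too dense: onsets {a} and {b} closer than "
                        f"{MIN_FALL_SEPARATION_S} s"
                    )


def _sample_fall_times(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.fall_times_s is not None:
        return np.sort(np.asarray(spec.fall_times_s, dtype=float))
    if spec.n_falls == 0:
        return np.empty(0)
    lo = _EDGE_MARGIN_S
    hi = spec.duration_s - _EDGE_MARGIN_S
    slack = (hi - lo) - (spec.n_falls - 1) * MIN_FALL_SEPARATION_S
    if slack <= 0:
        raise FlyfallError(
            f"falls too dense: cannot place {spec.n_falls} onsets at least "
            f"{MIN_FALL_SEPARATION_S} s apart within {spec.duration_s} s"
        )
    u = np.sort(rng.uniform(0.0, slack, spec.n_falls))
    return lo + u + np.arange(spec.n_falls) * MIN_FALL_SEPARATION_S


def _bridge_walk(
    rng: np.random.Generator, n: int, start: float, end: float, step_std: float
) -> np.ndarray:
    """Random walk of n+1 points pinned to start and end (Brownian bridge)."""
    if n == 0:
        return np.array([start])
    w = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, step_std, n))])
    t = np.arange(n + 1) / n
    return start + (end - start) * t + (w - t * w[-1])


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the boundaries."""
    span = hi - lo
    v = np.mod(values - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return lo + v


def generate_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, list[FallEvent]]:
    """Generate one recording: walking punctuated by programmed falls.

    Returns the detection trajectory and the ground-truth fall list
    (one event per programmed fall, onset at the last pre-gap
    detection).  Fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    geo = spec.geometry
    n_frames = int(round(spec.duration_s * spec.fps))
    fall_times = _sample_fall_times(spec, rng)

    # per-fall frame schedule: onset frame, dropout window, resume frame
    onsets, resumes, starts_y, ends_y = [], [], [], []
    for t in fall_times:
        f0 = int(round(t * spec.fps))
        gap = int(rng.integers(3, 16))  # 0.1-0.5 s unseen at 30 fps
        r0 = min(f0 + gap + 1, n_frames - 1)
        end_y = rng.uniform(geo.bottom_y - 15.0, geo.bottom_y - 3.0)
        d = rng.uniform(*spec.fall_displacement_px)
        start_y = max(end_y - d, geo.top_y + 2.0)
        onsets.append(f0)
        resumes.append(r0)
        starts_y.append(start_y)
        ends_y.append(end_y)

    step_std = spec.walk_speed_px_s / spec.fps
    cy = np.empty(n_frames)
    y_lo, y_hi = geo.top_y + 1.0, geo.bottom_y - 1.0

    # stitch walking segments between falls, pinning each segment to the
    # next programmed fall-start position so there are no spurious jumps
    pos = rng.uniform(geo.top_y + 10.0, geo.bottom_y - 10.0)
    seg_start = 0
    for k in range(len(onsets)):
        a, b = seg_start, onsets[k]
        seg = _bridge_walk(rng, b - a, pos, starts_y[k], step_std)
        cy[a : b + 1] = _reflect(seg, y_lo, y_hi)
        cy[onsets[k]] = starts_y[k]
        # descent: positions during the unseen window (rendered as a streak)
        win = np.arange(onsets[k] + 1, resumes[k])
        if win.size:
            frac = (win - onsets[k]) / (resumes[k] - onsets[k])
            cy[win] = starts_y[k] + frac * (ends_y[k] - starts_y[k])
        cy[resumes[k]] = ends_y[k]
        pos = ends_y[k]
        seg_start = resumes[k]
    tail = _bridge_walk(
        rng,
        n_frames - 1 - seg_start,
        pos,
        pos + rng.normal(0.0, step_std * np.sqrt(max(n_frames - 1 - seg_start, 1))),
        step_std,
    )
    cy[seg_start:] = _reflect(tail, y_lo, y_hi)
    for k in range(len(onsets)):  # pinned values survive the tail overwrite
        if resumes[k] >= seg_start:
            cy[resumes[k]] = ends_y[k]

    x_lo, x_hi = 30.0, spec.frame_width - 30.0
    cx = _reflect(
        (x_lo + x_hi) / 2.0 + np.concatenate([[0.0], np.cumsum(rng.normal(0.0, step_std, n_frames - 1))]),
        x_lo,
        x_hi,
    )

    visible = rng.random(n_frames) >= spec.dropout_rate
    for f0, r0 in zip(onsets, resumes):
        visible[f0] = True
        visible[r0] = True
        if spec.fall_dropout:
            visible[f0 + 1 : r0] = False

    if spec.noise_px > 0:
        cx = cx + rng.normal(0.0, spec.noise_px, n_frames)
        cy = cy + rng.normal(0.0, spec.noise_px, n_frames)
    cy = np.clip(cy, geo.top_y, geo.bottom_y)
    cx = np.clip(cx, FLY_W / 2, spec.frame_width - FLY_W / 2)

    detections = [
        Detection(
            frame_index=i,
            time_s=i / spec.fps,
            bbox=(cx[i] - FLY_W / 2, cy[i] - FLY_H / 2, FLY_W, FLY_H),
            centroid=(float(cx[i]), float(cy[i])),
            confidence=1.0,
        )
        for i in range(n_frames)
        if visible[i]
    ]
    traj = Trajectory(
        source_id=f"synthetic-seed{spec.seed}", fps=spec.fps, detections=detections
    )
    truth = [
        make_fall_event(
            start_time_s=f0 / spec.fps,
            end_time_s=r0 / spec.fps,
            start_y=float(cy[f0]),
            end_y=float(cy[r0]),
            geometry=geo,
        )
        for f0, r0 in zip(onsets, resumes)
    ]
    return traj, truth


class SyntheticVideo:
    """Lazy grayscale frame stack rendered from a generated trajectory.

    Supports ``len`` and integer indexing, so it can feed
    :func:`flyfall.detector.track_video` directly without materializing
    long recordings in memory.  Appearance: dark background, a static
    bright glare band just below the stopper, a bright fly disk at each
    visible detection, and a faint (sub-threshold) motion streak during
    fall descents.
    """

    BACKGROUND = 8
    GLARE = 90
    FLY = 220
    STREAK = 20  # only 12 above background: below the detector threshold
    FLY_RADIUS = 3

    def __init__(
        self,
        traj: Trajectory,
        spec: SyntheticSpec,
        truth: Sequence[FallEvent] | None = None,
    ):
        self.spec = spec
        self.height = int(spec.geometry.bottom_y) + 25
        self.width = spec.frame_width
        self.n_frames = int(round(spec.duration_s * spec.fps))
        self._by_frame = {d.frame_index: d for d in traj.detections}
        self._streaks: dict[int, tuple[float, float, float]] = {}
        for e in truth or []:
            f0 = int(round(e.start_time_s * spec.fps))
            r0 = int(round(e.end_time_s * spec.fps))
            d0 = self._by_frame.get(f0)
            cx0 = d0.cx if d0 else self.width / 2.0
            for f in range(f0 + 1, r0):
                frac = (f - f0) / (r0 - f0)
                self._streaks[f] = (cx0, e.start_y, e.start_y + frac * (e.end_y - e.start_y))
        self._background = self._render_background()

    def _render_background(self) -> np.ndarray:
        frame = np.full((self.height, self.width), self.BACKGROUND, dtype=np.uint8)
        top = int(self.spec.geometry.top_y)
        frame[max(top - 8, 0) : top + 2, :] = self.GLARE  # stopper glare
        return frame

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        if not 0 <= i < self.n_frames:
            raise IndexError(i)
        frame = self._background.copy()
        if i in self._streaks:
            cx, y0, y1 = self._streaks[i]
            c = int(round(cx))
            rows = slice(int(round(min(y0, y1))), int(round(max(y0, y1))) + 1)
            frame[rows, max(c - 1, 0) : c + 2] = np.maximum(
                frame[rows, max(c - 1, 0) : c + 2], self.STREAK
            )
        det = self._by_frame.get(i)
        if det is not None:
            r = self.FLY_RADIUS
            ci, cj = int(round(det.cy)), int(round(det.cx))
            yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
            disk = yy**2 + xx**2 <= r**2
            rows = slice(ci - r, ci + r + 1)
            cols = slice(cj - r, cj + r + 1)
            if 0 <= ci - r and ci + r < self.height and 0 <= cj - r and cj + r < self.width:
                frame[rows, cols][disk] = self.FLY
        return frame

    def to_array(self) -> np.ndarray:
        return np.stack([self[i] for i in range(len(self))])


def render_video(
    traj: Trajectory,
    spec: SyntheticSpec,
    path: str | Path,
    truth: Sequence[FallEvent] | None = None,
) -> None:
    """Render the recording to a grayscale image stack on disk (TIFF)."""
    import imageio.v3 as iio

    video = SyntheticVideo(traj, spec, truth)
    try:
        iio.imwrite(Path(path), video.to_array())
    except OSError as exc:
        raise IOError(f"cannot write video to {path}: {exc}") from exc


def generate_evaluation_case(
    spec: SyntheticSpec, fp_extra: int = 0, fn_drop: int = 0
) -> tuple[list[float], list[float]]:
    """Build a (predicted, truth) timestamp pair with known error counts.

    Truth is the programmed onset list.  Predictions are the truths
    jittered uniformly by 0 to +1 s (automated timestamps trail the
    annotated onset within the matching tolerance), minus ``fn_drop``
    randomly removed entries, plus ``fp_extra`` spurious timestamps
    placed more than 2 s from every truth.  Matching at the default
    ±1 s tolerance therefore yields exactly ``fp_extra`` false
    positives and ``fn_drop`` false negatives.
    """
    if fn_drop > spec.n_falls:
        raise ValidationError(
            f"cannot drop {fn_drop} of {spec.n_falls} programmed falls"
        )
    rng = np.random.default_rng([spec.seed, 101])
    truth = _sample_fall_times(spec, rng)
    predicted = truth + rng.uniform(0.0, 1.0, truth.size)
    if fn_drop:
        drop = rng.choice(truth.size, size=fn_drop, replace=False)
        predicted = np.delete(predicted, drop)
    spurious: list[float] = []
    while len(spurious) < fp_extra:
        t = rng.uniform(0.0, spec.duration_s)
        if truth.size == 0 or np.min(np.abs(truth - t)) > 2.0:
            spurious.append(t)
    predicted = np.sort(np.concatenate([predicted, spurious]))
    return predicted.tolist(), np.sort(truth).tolist()


def noiseless(spec: SyntheticSpec) -> SyntheticSpec:
    """A copy of the spec with jitter and random dropout disabled."""
    return replace(spec, noise_px=0.0, dropout_rate=0.0)
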