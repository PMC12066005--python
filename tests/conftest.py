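import numpy as np
import pytest

from flyfall.core import Detection, Trajectory, VialGeometry

BOX_W, BOX_H = 9.0, 7.0


def make_detection(frame: int, cx: float, cy: float, fps: float = 30.0) -> Detection:
    return Detection(
        frame_index=frame,
        time_s=frame / fps,
        bbox=(cx - BOX_W / 2, cy - BOX_H / 2, BOX_W, BOX_H),
        centroid=(cx, cy),
        confidence=1.0,
    )


def make_trajectory(points, fps: float = 30.0, source_id: str = "test") -> Trajectory:
    """Build a trajectory from (frame, cx, cy) triples."""
    return Trajectory(
        source_id=source_id,
        fps=fps,
        detections=[make_detection(f, cx, cy, fps) for f, cx, cy in points],
    )


def random_trajectory(rng: np.random.Generator, geometry: VialGeometry, n: int = 60,
                      fps: float = 30.0) -> Trajectory:
    """Unstructured random trajectory: arbitrary jumps and gaps, for
    exercising every branch of the fall criteria."""
    frames = np.sort(rng.choice(np.arange(n * 3), size=n, replace=False))
    cys = rng.uniform(geometry.top_y, geometry.bottom_y, n)
    cxs = rng.uniform(20.0, 140.0, n)
    return make_trajectory(
        [(int(f), float(cx), float(cy)) for f, cx, cy in zip(frames, cxs, cys)],
        fps=fps,
    )


@pytest.fixture
def geometry() -> VialGeometry:
    return VialGeometry(top_y=50.0, bottom_y=375.0, height_cm=3.0)
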