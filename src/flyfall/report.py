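"""Report plots: per-fall trajectory gaps and per-hour fall bars.

The gap plot shows the fly's vertical position against time around
each scored fall — the fall appears as a break in the trace that starts
high and ends low (the y-axis is inverted so "up in the vial" is up in
the plot).  The hourly plot shows raw and normalized falls per hour,
with an arrow marking the hour of death when known.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .core import FallEvent, Trajectory, VialGeometry

GAP_WINDOW_S = 5.0


def plot_fall_gaps(
    traj: Trajectory,
    events: Sequence[FallEvent],
    geometry: VialGeometry,
    path: str | Path,
    max_panels: int = 6,
) -> None:
    """Plot vertical position vs time in a window around each fall."""
    events = list(events)[:max_panels]
    n = max(len(events), 1)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.2 * n), squeeze=False)
    times = [d.time_s for d in traj.detections]
    ys = [d.cy for d in traj.detections]
    for ax, event in zip(axes.ravel(), events or [None]):
        if event is None:
            ax.text(0.5, 0.5, "no falls scored", ha="center", va="center")
            ax.set_axis_off()
            continue
        t0 = event.start_time_s - GAP_WINDOW_S
        t1 = event.end_time_s + GAP_WINDOW_S
        pts = [(t, y) for t, y in zip(times, ys) if t0 <= t <= t1]
        if pts:
            ax.plot(*zip(*pts), ".", ms=3, color="tab:blue")
        ax.axvspan(event.start_time_s, event.end_time_s, color="tab:red", alpha=0.15)
        ax.set_ylim(geometry.bottom_y + 10, geometry.top_y - 10)  # up is up
        ax.set_xlabel("time (s)")
        ax.set_ylabel("vertical position (px)")
        ax.set_title(
            f"fall at {event.start_time_s:.2f} s, "
            f"{event.delta_y_px:.0f} px ({event.delta_y_cm:.2f} cm)",
            fontsize=9,
        )
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_hourly(
    hourly: pd.DataFrame,
    path: str | Path,
    death_hour: int | None = None,
) -> None:
    """Bar charts of raw and movement-normalized falls per hour."""
    fig, (ax_raw, ax_norm) = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    ax_raw.bar(hourly["hour"], hourly["falls"], color="tab:blue")
    ax_raw.set_ylabel("falls / hour")
    ax_norm.bar(hourly["hour"], hourly["normalized_falls"], color="tab:orange")
    ax_norm.set_ylabel("falls / hour\n(per relative movement unit)")
    ax_norm.set_xlabel("hour of recording")
    if death_hour is not None:
        for ax, col in ((ax_raw, "falls"), (ax_norm, "normalized_falls")):
            top = float(hourly[col].max() or 1.0)
            ax.annotate(
                "death",
                xy=(death_hour, top),
                xytext=(death_hour, top * 1.15),
                ha="center",
                arrowprops={"arrowstyle": "->", "color": "black"},
            )
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
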