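"""Trajectory and summary figures.

The 3D trajectory scatter colors points on a green-to-red gradient by
elapsed time (green = start of the interval, red = end), one panel per
time interval plus one panel for the whole recording, with axes in mm
bounded by the tank.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap  # noqa: E402

from .fuse3d import TrackPoint3D  # noqa: E402
from .synthgen import TankGeometry  # noqa: E402

GREEN_RED = LinearSegmentedColormap.from_list("green_red", ["#00a000", "#d00000"])


def _track_arrays(track: list[TrackPoint3D]) -> tuple[np.ndarray, np.ndarray]:
    pts = [(p.elapsed_s, p.x_mm, p.y_mm, p.z_mm) for p in track if p.accepted]
    if not pts:
        raise ValueError("cannot plot an empty track")
    arr = np.asarray(pts, dtype=float)
    return arr[:, 0], arr[:, 1:]


def plot_trajectory_3d(
    track: list[TrackPoint3D],
    tank: TankGeometry,
    out_path: str | Path,
    n_panels: int = 3,
) -> Path:
    """Write a multi-panel 3D scatter of the track.

    ``n_panels`` equal sub-intervals of the recording are shown next to a
    final panel covering the full span; within each panel the color runs
    green (earliest) to red (latest).
    """
    times, positions = _track_arrays(track)
    t0, t1 = times.min(), times.max()
    span = max(t1 - t0, 1.0)
    edges = [(t0 + i * span / n_panels, t0 + (i + 1) * span / n_panels) for i in range(n_panels)]
    edges.append((t0, t1))
    titles = [f"interval {i + 1}/{n_panels}" for i in range(n_panels)] + ["full recording"]

    ncols = len(edges)
    fig = plt.figure(figsize=(4.2 * ncols, 4.2))
    for ax_i, ((lo, hi), title) in enumerate(zip(edges, titles), start=1):
        ax = fig.add_subplot(1, ncols, ax_i, projection="3d")
        mask = (times >= lo) & (times <= hi)
        sub_t = times[mask]
        sub_p = positions[mask]
        if sub_p.size:
            frac = (sub_t - lo) / max(hi - lo, 1.0)
            ax.scatter(sub_p[:, 0], sub_p[:, 2], sub_p[:, 1], c=GREEN_RED(frac), s=3)
        ax.set_xlim(0, tank.width_x)
        ax.set_ylim(0, tank.depth_z)
        ax.set_zlim(0, tank.height_y)
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("z (mm)")
        ax.set_zlabel("y (mm)")
        ax.set_title(title)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def plot_total_distances(
    labels: list[str], totals_m: list[float], out_path: str | Path
) -> Path:
    """Bar chart of total movement distance (m) per experimental group."""
    fig, ax = plt.subplots(figsize=(1.6 * max(len(labels), 2) + 2, 4))
    ax.bar(labels, totals_m, color="#4878a8")
    for i, v in enumerate(totals_m):
        ax.text(i, v, f"{v:.0f}", ha="center", va="bottom")
    ax.set_ylabel("total distance (m)")
    ax.set_xlabel("group")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
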