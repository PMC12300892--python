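"""Ground-truthed synthetic dual-view frame generator.

A single fish swims inside a glass tank following an attractor-biased
correlated random walk.  One parameter, ``stress`` in [0, 1], moves the
model between the two behavioral regimes the analysis is meant to separate:

* ``stress = 0`` — free cruising: the fish wanders the whole tank with
  persistent headings and its speed relaxes toward ``base_speed_mm_s``.
* ``stress = 1`` — confined agitation: a pull toward an attractor point
  near the water surface restricts the visited volume while the target
  speed doubles, reproducing the confinement-plus-hyperactivity signature
  of acute ammonia exposure.

The velocity update per step (``dt = 1/fps`` seconds) is::

    v_t = alpha * v_{t-1} + beta * (a - p_{t-1}) * dt + eps_t,
    eps_t ~ Normal(0, sigma^2 I)

after which the speed magnitude is relaxed toward
``base_speed_mm_s * (1 + stress)`` with gain ``speed_relax``, and the
position advances by ``v_t * dt`` with specular reflection at the walls of
the free-movement box (tank minus ``wall_margin_mm``, so the rendered body
never clips at the tank image boundary).

Rendering projects the 3D position onto two synchronized camera views:
the front view images the x (tank long side) / y (height) plane and the
top view the x / z (depth) plane.  The fish is drawn as a filled ellipse
whose per-frame pixel intensities fluctuate (``fish_texture_sd``), the way
a live fish's appearance changes between one-second exposures through
moving water; consecutive frames therefore differ over the whole silhouette
and frame differencing recovers the union of the two silhouettes rather
than two disjoint edge crescents.  Optional transient bubble artifacts and
global illumination flicker exercise the robustness of the detector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from numba import njit
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .frames import VIEWS, FrameRecord, write_frame

DEFAULT_START = datetime(2025, 1, 1, 9, 0, 0)


@dataclass(frozen=True)
class TankGeometry:
    """Inner dimensions of the glass tank in millimetres.

    The long horizontal side is x, the vertical side is y (0 at the tank
    floor, increasing upward) and the short horizontal side is z (0 at the
    front wall).
    """

    width_x: float = 540.0
    depth_z: float = 370.0
    height_y: float = 400.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(d) and d > 0 for d in (self.width_x, self.depth_z, self.height_y)):
            raise ValueError("tank dimensions must be positive and finite")

    @property
    def dims(self) -> np.ndarray:
        """Axis lengths ordered (x, y, z)."""
        return np.array([self.width_x, self.height_y, self.depth_z])


@dataclass
class SimConfig:
    """Movement-model and rendering settings for one synthetic recording."""

    tank: TankGeometry = field(default_factory=TankGeometry)
    duration_s: float = 36000.0
    fps: float = 1.0
    stress: float = 0.0
    base_speed_mm_s: float = 20.0
    persistence_alpha: float = 0.95
    speed_relax: float = 0.5
    attractor_point: tuple[float, float, float] = (270.0, 330.0, 185.0)
    attractor_strength_beta: float | None = None  # default: 0.25 * stress
    noise_sigma: float = 4.0
    wall_margin_mm: float = 70.0
    # rendering
    frame_width: int = 1920
    frame_height: int = 1080
    roi_front: tuple[int, int, int, int] = (690, 340, 1230, 740)  # col0,row0,col1,row1
    roi_top: tuple[int, int, int, int] = (690, 355, 1230, 725)
    fish_length_px: float = 130.0
    fish_width_px: float = 36.0
    background_level: float = 20.0
    fish_level: float = 210.0
    fish_texture_sd: float = 130.0
    pixel_noise_sd: float = 2.0
    flicker_sd: float = 1.5
    bubble_rate: float = 0.0
    seed: int = 0
    start_time: datetime = DEFAULT_START

    def __post_init__(self) -> None:
        numeric = [
            self.duration_s, self.fps, self.stress, self.base_speed_mm_s,
            self.persistence_alpha, self.speed_relax, self.noise_sigma,
            self.wall_margin_mm, self.fish_length_px, self.fish_width_px,
            self.background_level, self.fish_level, self.fish_texture_sd,
            self.pixel_noise_sd, self.flicker_sd, self.bubble_rate,
            *self.attractor_point,
        ]
        if self.attractor_strength_beta is not None:
            numeric.append(self.attractor_strength_beta)
        if not all(np.isfinite(v) for v in numeric):
            raise ValueError("non-finite value in simulation configuration")
        if not 0.0 <= self.stress <= 1.0:
            raise ValueError("stress must lie in [0, 1]")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0.0 <= self.persistence_alpha < 1.0:
            raise ValueError("persistence_alpha must lie in [0, 1)")
        if not 0.0 <= self.speed_relax <= 1.0:
            raise ValueError("speed_relax must lie in [0, 1]")
        a = np.asarray(self.attractor_point, dtype=float)
        if np.any(a < 0) or np.any(a > self.tank.dims):
            raise ValueError("attractor_point must lie inside the tank")
        if 2 * self.wall_margin_mm >= float(self.tank.dims.min()):
            raise ValueError("wall_margin_mm leaves no free-movement volume")
        for name in ("roi_front", "roi_top"):
            c0, r0, c1, r1 = getattr(self, name)
            if not (0 <= c0 < c1 <= self.frame_width and 0 <= r0 < r1 <= self.frame_height):
                raise ValueError(f"{name} must be non-empty and inside the frame")

    @property
    def beta(self) -> float:
        """Attractor pull rate (1/s); by default grows linearly with stress."""
        if self.attractor_strength_beta is not None:
            return self.attractor_strength_beta
        return 0.25 * self.stress

    @property
    def target_speed(self) -> float:
        return self.base_speed_mm_s * (1.0 + self.stress)

    def roi(self, view: str) -> tuple[int, int, int, int]:
        if view == "front":
            return self.roi_front
        if view == "top":
            return self.roi_top
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tank"] = dataclasses.asdict(self.tank)
        d["start_time"] = self.start_time.isoformat()
        for key in ("attractor_point", "roi_front", "roi_top"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "tank" in d and isinstance(d["tank"], dict):
            d["tank"] = TankGeometry(**d["tank"])
        if isinstance(d.get("start_time"), str):
            d["start_time"] = datetime.fromisoformat(d["start_time"])
        for key in ("attractor_point", "roi_front", "roi_top"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth fish state at one capture instant."""

    timestamp: datetime
    x_mm: float
    y_mm: float
    z_mm: float
    heading_deg: float
    visible: bool


@dataclass
class GroundTruth:
    """The true trajectory a renderer drew, one record per frame."""

    start_time: datetime
    fps: float
    x_mm: np.ndarray
    y_mm: np.ndarray
    z_mm: np.ndarray
    heading_deg: np.ndarray
    visible: np.ndarray

    def __len__(self) -> int:
        return len(self.x_mm)

    @property
    def elapsed_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps

    @property
    def timestamps(self) -> list[datetime]:
        return [self.start_time + timedelta(seconds=float(t)) for t in self.elapsed_s]

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of (x, y, z) positions in mm."""
        return np.column_stack([self.x_mm, self.y_mm, self.z_mm])

    def record(self, i: int) -> TruthRecord:
        return TruthRecord(
            timestamp=self.start_time + timedelta(seconds=float(i / self.fps)),
            x_mm=float(self.x_mm[i]),
            y_mm=float(self.y_mm[i]),
            z_mm=float(self.z_mm[i]),
            heading_deg=float(self.heading_deg[i]),
            visible=bool(self.visible[i]),
        )

    def __iter__(self) -> Iterator[TruthRecord]:
        return (self.record(i) for i in range(len(self)))

    def path_length_mm(self) -> float:
        """Total length of the true trajectory polyline."""
        return float(np.linalg.norm(np.diff(self.positions, axis=0), axis=1).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_iso": [t.isoformat() for t in self.timestamps],
                "x_mm": self.x_mm,
                "y_mm": self.y_mm,
                "z_mm": self.z_mm,
                "heading_deg": self.heading_deg,
                "visible": self.visible.astype(int),
            }
        )


@njit(cache=False)
def _propagate(p0, v0, eps, alpha, beta, attractor, target, relax, dt, lo, hi):
    """Advance the correlated random walk; returns positions and headings."""
    n = eps.shape[0]
    pos = np.empty((n + 1, 3))
    head = np.empty(n + 1)
    p = p0.copy()
    v = v0.copy()
    pos[0] = p
    head[0] = np.degrees(np.arctan2(v[2], v[0]))
    for t in range(n):
        for k in range(3):
            v[k] = alpha * v[k] + beta * (attractor[k] - p[k]) * dt + eps[t, k]
        s = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
        if s > 1e-12:
            scale = ((1.0 - relax) * s + relax * target) / s
            for k in range(3):
                v[k] *= scale
        for k in range(3):
            p[k] += v[k] * dt
            # specular reflection keeps the point in [lo, hi]
            while p[k] < lo[k] or p[k] > hi[k]:
                if p[k] < lo[k]:
                    p[k] = 2.0 * lo[k] - p[k]
                else:
                    p[k] = 2.0 * hi[k] - p[k]
                v[k] = -v[k]
        pos[t + 1] = p
        head[t + 1] = np.degrees(np.arctan2(v[2], v[0]))
    return pos, head


def simulate_trajectory(config: SimConfig) -> GroundTruth:
    """Simulate the fish trajectory; returns ``duration_s * fps + 1`` records.

    The walk starts at the center of the free-movement box with a random
    initial heading at the target speed.  Fixed ``config.seed`` gives a
    byte-identical trajectory.
    """
    n_steps = int(round(config.duration_s * config.fps))
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    lo = np.full(3, config.wall_margin_mm)
    hi = config.tank.dims - config.wall_margin_mm
    p0 = (lo + hi) / 2.0
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    v0 = direction * config.target_speed
    eps = rng.normal(0.0, config.noise_sigma, size=(n_steps, 3))
    pos, head = _propagate(
        p0, v0, eps, config.persistence_alpha, config.beta,
        np.asarray(config.attractor_point, dtype=float), config.target_speed,
        config.speed_relax, 1.0 / config.fps, lo, hi,
    )
    return GroundTruth(
        start_time=config.start_time,
        fps=config.fps,
        x_mm=pos[:, 0],
        y_mm=pos[:, 1],
        z_mm=pos[:, 2],
        heading_deg=head,
        visible=np.ones(n_steps + 1, dtype=bool),
    )


def project_to_view(
    x_mm: float, y_mm: float, z_mm: float, view: str, config: SimConfig
) -> tuple[float, float]:
    """Project a tank-coordinate point to sub-pixel ROI coordinates.

    Returns ``(col, row)`` relative to the view's ROI origin.  The image row
    axis points downward, so the front view flips y (y = 0 at the tank
    floor maps to the bottom ROI row).
    """
    c0, r0, c1, r1 = config.roi(view)
    roi_w, roi_h = c1 - c0, r1 - r0
    tank = config.tank
    col = x_mm * roi_w / tank.width_x
    if view == "front":
        row = (tank.height_y - y_mm) * roi_h / tank.height_y
    else:
        row = z_mm * roi_h / tank.depth_z
    return col, row


def render_frame(
    record: TruthRecord,
    view: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> FrameRecord:
    """Render one frame of one view as an 8-bit grayscale image.

    The fish is a filled ellipse at the projected centroid.  The top view
    shows the full body length rotated to the heading; the front view shows
    the level side profile of a horizontal swimmer.  Background level,
    per-pixel noise,
    a per-frame global flicker offset and Poisson-count single-frame bubble
    artifacts complete the image.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
    h, w = config.frame_height, config.frame_width
    flicker = rng.normal(0.0, config.flicker_sd) if config.flicker_sd > 0 else 0.0
    img = np.full((h, w), config.background_level + flicker, dtype=np.float32)
    if config.pixel_noise_sd > 0:
        img += rng.normal(0.0, config.pixel_noise_sd, size=(h, w)).astype(np.float32)

    c0, r0, c1, r1 = config.roi(view)
    col, row = project_to_view(record.x_mm, record.y_mm, record.z_mm, view, config)
    cc, rr = c0 + col, r0 + row
    heading = np.radians(record.heading_deg)
    if view == "top":
        half_len = config.fish_length_px / 2.0
        rotation = -heading  # image rows grow with +z, ellipse rotation is CCW
    else:
        # side profile of a horizontal swimmer: full body length, level pose
        half_len = config.fish_length_px / 2.0
        rotation = 0.0
    if record.visible:
        rows, cols = draw_ellipse(
            rr, cc, config.fish_width_px / 2.0, half_len,
            shape=img.shape, rotation=rotation,
        )
        if rows.size == 0:
            raise RuntimeError(
                f"fish projected outside the image in view {view!r}; geometry misconfigured"
            )
        body = np.full(rows.shape, config.fish_level, dtype=np.float32)
        if config.fish_texture_sd > 0:
            body += rng.normal(0.0, config.fish_texture_sd, size=rows.shape).astype(np.float32)
        img[rows, cols] = body

    if config.bubble_rate > 0:
        for _ in range(rng.poisson(config.bubble_rate)):
            br = rng.uniform(r0, r1)
            bc = rng.uniform(c0, c1)
            radius = rng.uniform(2.0, 4.0)
            intensity = rng.uniform(config.fish_level, 255.0)
            rows, cols = draw_disk((br, bc), radius, shape=img.shape)
            img[rows, cols] = intensity

    frame = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FrameRecord(timestamp=record.timestamp, view=view, image=frame)


def render_sequence(
    truth: GroundTruth, view: str, config: SimConfig
) -> Iterator[FrameRecord]:
    """Yield rendered frames for one view, deterministically from the seed."""
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1 + VIEWS.index(view)])
    )
    for record in truth:
        yield render_frame(record, view, config, rng)


def write_dataset(truth: GroundTruth, config: SimConfig, out_dir: str | Path) -> dict:
    """Write PNG frames for both views plus ground truth and config.

    Produces ``YYYYMMDD_HHMMSS_<view>.png`` files, ``ground_truth.csv`` and
    ``config.yaml``; returns a manifest with per-view frame counts.  Only
    integer-second capture (fps = 1) is supported by the filename dialect;
    duplicate timestamps would collide and raise.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if abs(config.fps - 1.0) > 1e-9:
        raise ValueError("frame filenames carry 1-second resolution; fps must be 1")
    counts = {}
    for view in VIEWS:
        written = set()
        for frame in render_sequence(truth, view, config):
            path = write_frame(frame, out_dir)
            if path in written:
                raise ValueError(f"duplicate frame filename {path.name}; timestamps must be unique")
            written.add(path)
        counts[view] = len(written)
    truth.to_frame().to_csv(out_dir / "ground_truth.csv", index=False, float_format="%.6f")
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return {
        "out_dir": str(out_dir),
        "n_front": counts["front"],
        "n_top": counts["top"],
        "n_truth_records": len(truth),
    }
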