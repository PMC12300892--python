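"""Pixel-to-millimetre calibration and dual-view 3D fusion.

Both cameras see the full tank cross-section inside their ROI, so the
calibration is a per-axis linear scale: the tank's long side (x) spans the
ROI width in both views, the height (y) spans the front ROI height and the
depth (z) spans the top ROI height.  Timestamp-matched front/top detections
share the x axis; the two independent x estimates serve as a consistency
check and are averaged when they agree within ``x_tolerance_mm``.

The y axis is flipped here, in exactly one place: image rows grow
downward while tank y grows upward from the floor.  Rejected or missing
seconds leave gaps in the track — positions are never interpolated; the
kinematics layer bridges gaps with the straight-line step over the actual
elapsed time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .detect import Detection2D
from .synthgen import TankGeometry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ViewCalibration:
    """mm-per-pixel scales of one view: x and the view's second axis."""

    scale_x: float
    scale_second_axis: float

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_second_axis <= 0:
            raise ValueError("calibration scales must be positive")


@dataclass(frozen=True)
class CalibrationMap:
    """Per-view scales plus the tank the coordinates live in.

    Origin convention: x = 0 at the left tank wall, y = 0 at the tank
    floor (growing upward), z = 0 at the front wall.
    """

    front: ViewCalibration
    top: ViewCalibration
    tank: TankGeometry


@dataclass(frozen=True)
class TrackPoint3D:
    """Fused, calibrated fish position at one timestamp."""

    timestamp: datetime
    elapsed_s: float
    x_mm: float
    y_mm: float
    z_mm: float
    step_distance_mm: float
    x_discrepancy_mm: float
    accepted: bool


def build_calibration(
    tank: TankGeometry,
    roi_front: tuple[int, int, int, int],
    roi_top: tuple[int, int, int, int],
) -> CalibrationMap:
    """Derive mm/px scales from the tank dimensions and per-view ROIs."""
    fw, fh = roi_front[2] - roi_front[0], roi_front[3] - roi_front[1]
    tw, th = roi_top[2] - roi_top[0], roi_top[3] - roi_top[1]
    if fw <= 0 or fh <= 0 or tw <= 0 or th <= 0:
        raise ValueError("ROIs must be non-empty")
    return CalibrationMap(
        front=ViewCalibration(scale_x=tank.width_x / fw, scale_second_axis=tank.height_y / fh),
        top=ViewCalibration(scale_x=tank.width_x / tw, scale_second_axis=tank.depth_z / th),
        tank=tank,
    )


def pair_by_time(
    front: list[Detection2D], top: list[Detection2D]
) -> list[tuple[Detection2D, Detection2D]]:
    """Match front/top detections captured at the same second.

    Only pairs where both detections are valid survive; unpaired or
    invalid entries are dropped with a logged count.  Duplicate timestamps
    within a view indicate a corrupt dataset and raise.
    """
    pairs = []
    by_time: dict[datetime, Detection2D] = {}
    for det in top:
        if det.timestamp in by_time:
            raise ValueError(f"duplicate top-view timestamp {det.timestamp.isoformat()}")
        by_time[det.timestamp] = det
    seen_front: set[datetime] = set()
    for det in front:
        if det.timestamp in seen_front:
            raise ValueError(f"duplicate front-view timestamp {det.timestamp.isoformat()}")
        seen_front.add(det.timestamp)
        partner = by_time.get(det.timestamp)
        if partner is not None and det.valid and partner.valid:
            pairs.append((det, partner))
    dropped = len(front) + len(top) - 2 * len(pairs)
    if dropped:
        logger.info("pair_by_time: dropped %d unpaired or invalid detections", dropped)
    if not pairs:
        logger.warning("pair_by_time: no usable front/top pairs")
    return pairs


def fuse_to_3d(
    pair: tuple[Detection2D, Detection2D],
    calib: CalibrationMap,
    x_tolerance_mm: float = 30.0,
    start_time: datetime | None = None,
) -> TrackPoint3D:
    """Fuse one timestamp-matched detection pair into a 3D point.

    The two x estimates are averaged when they agree within
    ``x_tolerance_mm`` (about a fish half-length); otherwise the point is
    flagged rejected and carries the discrepancy for diagnostics.  Step
    distances are filled later by :func:`fuse_track`.
    """
    front, top = pair
    if front.view != "front" or top.view != "top":
        raise ValueError("pair must be (front, top) detections")
    if front.timestamp != top.timestamp:
        raise ValueError("paired detections must share a timestamp")
    if not (front.valid and top.valid):
        raise ValueError("cannot fuse invalid detections")
    x_front = front.cx_px * calib.front.scale_x
    x_top = top.cx_px * calib.top.scale_x
    discrepancy = abs(x_front - x_top)
    accepted = discrepancy <= x_tolerance_mm
    x = 0.5 * (x_front + x_top)
    y = calib.tank.height_y - front.cy_px * calib.front.scale_second_axis
    z = top.cy_px * calib.top.scale_second_axis
    elapsed = (
        (front.timestamp - start_time).total_seconds() if start_time is not None else float("nan")
    )
    return TrackPoint3D(
        timestamp=front.timestamp,
        elapsed_s=elapsed,
        x_mm=float(x),
        y_mm=float(y),
        z_mm=float(z),
        step_distance_mm=0.0,
        x_discrepancy_mm=float(discrepancy),
        accepted=bool(accepted),
    )


def fuse_track(
    pairs: list[tuple[Detection2D, Detection2D]],
    calib: CalibrationMap,
    x_tolerance_mm: float = 30.0,
    start_time: datetime | None = None,
) -> list[TrackPoint3D]:
    """Fuse a time-ordered pair list into a track with step distances.

    Step distances connect consecutive *accepted* points, bridging any
    rejected or missing seconds with the single straight-line step across
    the gap.
    """
    if start_time is None and pairs:
        start_time = pairs[0][0].timestamp
    points = [fuse_to_3d(pair, calib, x_tolerance_mm, start_time) for pair in pairs]
    prev: TrackPoint3D | None = None
    for i, pt in enumerate(points):
        if not pt.accepted:
            continue
        if prev is not None:
            d = float(
                np.sqrt(
                    (pt.x_mm - prev.x_mm) ** 2
                    + (pt.y_mm - prev.y_mm) ** 2
                    + (pt.z_mm - prev.z_mm) ** 2
                )
            )
            points[i] = TrackPoint3D(
                timestamp=pt.timestamp, elapsed_s=pt.elapsed_s,
                x_mm=pt.x_mm, y_mm=pt.y_mm, z_mm=pt.z_mm,
                step_distance_mm=d,
                x_discrepancy_mm=pt.x_discrepancy_mm, accepted=True,
            )
        prev = points[i]
    return points
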