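"""Per-frame-pair fish detection by frame differencing.

The chain is: crop to the tank ROI and convert to grayscale, take the
absolute difference of two consecutive frames, binarize it at a fixed
threshold (default 60 gray levels), label connected foreground regions,
keep the largest region if it is at least ``min_area_px`` pixels, and
read centroid, area and orientation off the region's image moments.

Connected regions stand in for contours: only area and moments are
consumed downstream, for which the two representations are equivalent.
Centroids are kept at sub-pixel precision and are expressed in 0-based
(col, row) coordinates relative to the ROI origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable

import numpy as np
from skimage.measure import label as sk_label

from .frames import FrameRecord


@dataclass(frozen=True)
class DetectionParams:
    """Detector settings; the ROI is half-open ``(col0, row0, col1, row1)``."""

    roi: tuple[int, int, int, int]
    threshold: int = 60
    min_area_px: int = 30
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 255:
            raise ValueError("threshold must lie strictly between 0 and 255")
        c0, r0, c1, r1 = self.roi
        if not (c0 < c1 and r0 < r1):
            raise ValueError("ROI must be non-empty")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class Detection2D:
    """Fish blob found in one frame pair of one view.

    ``cx_px``/``cy_px`` are sub-pixel centroid coordinates in the ROI frame;
    ``angle_deg`` is the orientation of the blob's principal axis in
    [-90, 90) degrees measured from the image column axis (positive toward
    increasing rows).  Invalid detections carry NaN coordinates.
    """

    timestamp: datetime
    view: str
    cx_px: float
    cy_px: float
    area_px: float
    angle_deg: float
    valid: bool


@dataclass(frozen=True)
class Component:
    """One connected foreground region: pixel coordinates and area."""

    rows: np.ndarray
    cols: np.ndarray

    @property
    def area(self) -> int:
        return int(self.rows.size)

    @property
    def top_left(self) -> tuple[int, int]:
        """Lexicographically smallest (row, col) pixel of the region."""
        order = np.lexsort((self.cols, self.rows))
        i = order[0]
        return int(self.rows[i]), int(self.cols[i])


def preprocess(frame: FrameRecord | np.ndarray, params: DetectionParams) -> np.ndarray:
    """Crop the frame to the ROI and return an 8-bit grayscale image.

    Color inputs are reduced by Rec. 601 luminance weighting; grayscale
    inputs pass through pixel-identically.
    """
    image = frame.image if isinstance(frame, FrameRecord) else frame
    image = np.asarray(image)
    c0, r0, c1, r1 = params.roi
    if image.ndim == 3:
        lum = image[..., :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])
        image = np.clip(np.rint(lum), 0, 255).astype(np.uint8)
    elif image.ndim != 2:
        raise ValueError(f"expected a 2D or 3-channel image, got shape {image.shape}")
    h, w = image.shape
    if not (0 <= c0 < c1 <= w and 0 <= r0 < r1 <= h):
        raise ValueError(f"ROI {params.roi} outside frame of shape {(h, w)}")
    return np.ascontiguousarray(image[r0:r1, c0:c1], dtype=np.uint8)


def frame_difference(prev_roi: np.ndarray, curr_roi: np.ndarray) -> np.ndarray:
    """Per-pixel absolute difference of two equal-shape 8-bit images."""
    prev_roi = np.asarray(prev_roi)
    curr_roi = np.asarray(curr_roi)
    if prev_roi.shape != curr_roi.shape:
        raise ValueError(f"shape mismatch: {prev_roi.shape} vs {curr_roi.shape}")
    a = prev_roi.astype(np.int16)
    b = curr_roi.astype(np.int16)
    return np.abs(b - a).astype(np.uint8)


def binarize(diff: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground where the difference strictly exceeds the threshold."""
    return np.asarray(diff) > threshold


def label_components(binary: np.ndarray, connectivity: int = 8) -> list[Component]:
    """Maximal connected foreground regions under 4- or 8-adjacency."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = sk_label(np.asarray(binary, dtype=bool), connectivity=1 if connectivity == 4 else 2)
    n = labels.max()
    if n == 0:
        return []
    order = np.argsort(labels, axis=None, kind="stable")
    flat = labels.ravel()[order]
    first_fg = np.searchsorted(flat, 1)
    order = order[first_fg:]
    flat = flat[first_fg:]
    bounds = np.searchsorted(flat, np.arange(1, n + 2))
    width = labels.shape[1]
    components = []
    for k in range(n):
        idx = order[bounds[k]:bounds[k + 1]]
        components.append(Component(rows=idx // width, cols=idx % width))
    return components


def select_fish_component(
    components: list[Component], min_area_px: int
) -> Component | None:
    """Largest-area region if it reaches the area floor, else ``None``.

    Largest-area selection discards transient small blobs (bubbles,
    surface ripple); the area floor additionally marks frames where even
    the largest blob is implausibly small — e.g. a nearly still fish —
    as invalid.  Area ties break on the smallest (row, col) top-left pixel
    so the choice is deterministic.
    """
    if not components:
        return None
    best = min(components, key=lambda comp: (-comp.area, comp.top_left))
    if best.area < min_area_px:
        return None
    return best


def component_features(component: Component) -> tuple[float, float, float, float]:
    """Centroid, area and principal-axis angle from image moments.

    The centroid is ``(m10/m00, m01/m00)`` over the region's pixels; the
    orientation is ``0.5 * atan2(2*mu11, mu20 - mu02)`` from the central
    second moments, mapped to [-90, 90) degrees.
    """
    if component.area == 0:
        raise ValueError("cannot compute features of an empty component")
    cols = component.cols.astype(np.int64)
    rows = component.rows.astype(np.int64)
    n = int(component.area)
    s_c = int(cols.sum())
    s_r = int(rows.sum())
    cx = s_c / n
    cy = s_r / n
    # central second moments scaled by n, in exact integer arithmetic so the
    # orientation of (near-)symmetric regions does not depend on summation
    # order: n * mu_pq = n * sum(c^p r^q) - (sum c)^p' (sum r)^q'
    mu20 = n * int(np.dot(cols, cols)) - s_c * s_c
    mu02 = n * int(np.dot(rows, rows)) - s_r * s_r
    mu11 = n * int(np.dot(cols, rows)) - s_c * s_r
    angle = 0.5 * np.degrees(np.arctan2(2.0 * mu11, float(mu20 - mu02)))
    if angle >= 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0
    return float(cx), float(cy), float(component.area), float(angle)


def detect_pair(
    prev: FrameRecord, curr: FrameRecord, params: DetectionParams
) -> Detection2D:
    """Detect the fish from one consecutive frame pair of one view.

    The detection carries the timestamp of the later frame.  When no
    region reaches the area floor (stationary fish, empty difference) the
    detection is returned with ``valid=False``.
    """
    if prev.view != curr.view:
        raise ValueError(f"views differ: {prev.view!r} vs {curr.view!r}")
    if curr.timestamp <= prev.timestamp:
        raise ValueError("frames must be in increasing timestamp order")
    diff = frame_difference(preprocess(prev, params), preprocess(curr, params))
    components = label_components(binarize(diff, params.threshold), params.connectivity)
    chosen = select_fish_component(components, params.min_area_px)
    if chosen is None:
        return Detection2D(
            timestamp=curr.timestamp, view=curr.view,
            cx_px=float("nan"), cy_px=float("nan"),
            area_px=0.0, angle_deg=float("nan"), valid=False,
        )
    cx, cy, area, angle = component_features(chosen)
    return Detection2D(
        timestamp=curr.timestamp, view=curr.view,
        cx_px=cx, cy_px=cy, area_px=area, angle_deg=angle, valid=True,
    )


def detect_sequence(
    frames: Iterable[FrameRecord], params: DetectionParams
) -> list[Detection2D]:
    """Run pairwise detection along a time-ordered frame sequence."""
    detections = []
    prev: FrameRecord | None = None
    for frame in frames:
        if prev is not None:
            detections.append(detect_pair(prev, frame, params))
        prev = frame
    return detections
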