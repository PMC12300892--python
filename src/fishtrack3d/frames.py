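"""Timestamped camera frames and the filename dialect that encodes them.

Each still image carries its capture datetime in its filename,
``YYYYMMDD_HHMMSS_<view>.png`` (views: ``front``, ``top``), at one-second
resolution.  Frames are 8-bit grayscale; color inputs are accepted and
reduced by luminance weighting at preprocessing time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import imageio.v3 as iio
import numpy as np

VIEWS = ("front", "top")

_FILENAME_RE = re.compile(
    r"^(?P<date>\d{8})_(?P<time>\d{6})_(?P<view>front|top)\.(?:png|jpg|jpeg)$",
    re.IGNORECASE,
)


@dataclass
class FrameRecord:
    """One timestamped image from one camera view."""

    timestamp: datetime
    view: str
    image: np.ndarray
    path: Path | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")


def format_frame_filename(timestamp: datetime, view: str, ext: str = "png") -> str:
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
    return f"{timestamp:%Y%m%d_%H%M%S}_{view}.{ext}"


def parse_frame_timestamp(filename: str | Path) -> tuple[datetime, str]:
    """Parse capture datetime and view from a frame filename.

    Raises ``ValueError`` naming the offending file when the name does not
    follow the ``YYYYMMDD_HHMMSS_<view>`` dialect.
    """
    name = Path(filename).name
    m = _FILENAME_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse frame filename: {name!r}")
    stamp = datetime.strptime(m["date"] + m["time"], "%Y%m%d%H%M%S")
    return stamp, m["view"].lower()


def read_frame(path: str | Path) -> FrameRecord:
    """Load a frame image, deriving timestamp and view from its name."""
    path = Path(path)
    try:
        image = iio.imread(path)
    except OSError as exc:  # pragma: no cover - depends on filesystem state
        raise OSError(f"cannot read frame image {path}") from exc
    timestamp, view = parse_frame_timestamp(path)
    return FrameRecord(timestamp=timestamp, view=view, image=image, path=path)


def write_frame(frame: FrameRecord, directory: str | Path) -> Path:
    """Write a frame as 8-bit grayscale PNG using the filename dialect."""
    directory = Path(directory)
    path = directory / format_frame_filename(frame.timestamp, frame.view)
    iio.imwrite(path, np.asarray(frame.image, dtype=np.uint8))
    return path


def load_frame_sequence(directory: str | Path, view: str) -> list[FrameRecord]:
    """Load all frames of one view from a directory, sorted by timestamp."""
    directory = Path(directory)
    records = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        stamp, v = parse_frame_timestamp(path)
        if v == view:
            records.append((stamp, path))
    records.sort(key=lambda item: item[0])
    return [read_frame(path) for _, path in records]
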