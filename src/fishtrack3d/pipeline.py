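"""Orchestration: file I/O, end-to-end runs, and the accuracy harness.

The pipeline stages are simulate (optional) -> detect -> fuse -> kinematics
-> statistics -> validation -> plots.  Every stage logs its record counts
into a provenance document so each input frame pair is accounted for as
valid, invalid, unpaired or rejected.

Detection accuracy is scored against the synthetic ground truth the way
the live experiment scored it against manual annotation: a simple random
sample of frame pairs is drawn and a detection counts as correct when it
is valid, the fish was visible, and the marked point falls within
``tolerance_px`` of the reference location.  Because frame differencing
localizes motion between the two capture instants, the reference for a
pair is the projected midpoint of the two true positions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import skimage
import yaml

from . import __version__, behav_stats, kinematics
from .detect import Detection2D, DetectionParams, detect_sequence
from .frames import VIEWS, load_frame_sequence, parse_frame_timestamp  # noqa: F401  (re-export)
from .fuse3d import CalibrationMap, TrackPoint3D, build_calibration, fuse_track, pair_by_time
from .kinematics import SpeedSeries, bin_speeds, occupancy, per_second_speeds, summarize_speeds
from .synthgen import GroundTruth, SimConfig, project_to_view, render_sequence, simulate_trajectory

logger = logging.getLogger(__name__)

DETECTION_LOG_COLUMNS = [
    "timestamp_iso", "view", "cx_px", "cy_px", "area_px", "angle_deg", "valid",
]
TRACK_COLUMNS = [
    "timestamp_iso", "elapsed_s", "x_mm", "y_mm", "z_mm",
    "step_distance_mm", "x_discrepancy_mm", "status",
]


@dataclass
class AccuracyReport:
    """Random-sampling detection accuracy against ground truth."""

    n_sampled: int
    n_correct: int
    accuracy: float
    tolerance_px: float
    seed: int


# ---------------------------------------------------------------------------
# CSV logs

def write_detection_log(detections: list[Detection2D], path: str | Path) -> Path:
    """Write detections as CSV; invalid rows carry empty coordinate fields."""
    path = Path(path)
    rows = []
    for det in detections:
        rows.append({
            "timestamp_iso": det.timestamp.isoformat(),
            "view": det.view,
            "cx_px": f"{det.cx_px:.4f}" if det.valid else "",
            "cy_px": f"{det.cy_px:.4f}" if det.valid else "",
            "area_px": f"{det.area_px:.0f}",
            "angle_deg": f"{det.angle_deg:.4f}" if det.valid else "",
            "valid": str(det.valid).lower(),
        })
    pd.DataFrame(rows, columns=DETECTION_LOG_COLUMNS).to_csv(path, index=False)
    return path


def read_detection_log(path: str | Path) -> list[Detection2D]:
    df = pd.read_csv(path, dtype={"valid": str}, keep_default_na=False)
    detections = []
    for row in df.itertuples(index=False):
        valid = row.valid == "true"
        detections.append(Detection2D(
            timestamp=datetime.fromisoformat(row.timestamp_iso),
            view=row.view,
            cx_px=float(row.cx_px) if valid else float("nan"),
            cy_px=float(row.cy_px) if valid else float("nan"),
            area_px=float(row.area_px),
            angle_deg=float(row.angle_deg) if valid else float("nan"),
            valid=valid,
        ))
    return detections


def write_track_csv(track: list[TrackPoint3D], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for pt in track:
        rows.append({
            "timestamp_iso": pt.timestamp.isoformat(),
            "elapsed_s": f"{pt.elapsed_s:.0f}",
            "x_mm": f"{pt.x_mm:.4f}",
            "y_mm": f"{pt.y_mm:.4f}",
            "z_mm": f"{pt.z_mm:.4f}",
            "step_distance_mm": f"{pt.step_distance_mm:.4f}",
            "x_discrepancy_mm": f"{pt.x_discrepancy_mm:.4f}",
            "status": "accepted" if pt.accepted else "rejected",
        })
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)
    return path


def read_track_csv(path: str | Path) -> list[TrackPoint3D]:
    df = pd.read_csv(path)
    return [
        TrackPoint3D(
            timestamp=datetime.fromisoformat(row.timestamp_iso),
            elapsed_s=float(row.elapsed_s),
            x_mm=float(row.x_mm), y_mm=float(row.y_mm), z_mm=float(row.z_mm),
            step_distance_mm=float(row.step_distance_mm),
            x_discrepancy_mm=float(row.x_discrepancy_mm),
            accepted=row.status == "accepted",
        )
        for row in df.itertuples(index=False)
    ]


def write_speed_csv(series: SpeedSeries, window_s: float, start_time: datetime, path: str | Path) -> Path:
    path = Path(path)
    from datetime import timedelta
    rows = [
        {
            "group_label": series.group_label,
            "window_index": i,
            "window_start_iso": (start_time + timedelta(seconds=i * window_s)).isoformat(),
            "mean_speed_mm_s": f"{v:.4f}",
        }
        for i, v in enumerate(series.values)
    ]
    pd.DataFrame(rows, columns=["group_label", "window_index", "window_start_iso", "mean_speed_mm_s"]).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Validation harness

def sample_frames_for_validation(items: list, n: int, seed: int) -> list:
    """Uniform random sample of n items without replacement, seeded."""
    if n > len(items):
        raise ValueError(f"cannot sample {n} from {len(items)} frames")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(items), size=n, replace=False)
    return [items[int(i)] for i in idx]


def _truth_index(truth: GroundTruth, timestamp: datetime) -> int:
    elapsed = (timestamp - truth.start_time).total_seconds()
    i = int(round(elapsed * truth.fps))
    if not 0 <= i < len(truth):
        raise KeyError(f"timestamp {timestamp.isoformat()} outside ground truth span")
    return i


def reference_point_px(
    truth: GroundTruth, timestamp: datetime, view: str, config: SimConfig
) -> tuple[float, float]:
    """ROI-pixel reference location for a detection stamped at ``timestamp``.

    Frame differencing sees the fish at both capture instants of the pair,
    so the reference is the projected midpoint of the true positions at
    the pair's two timestamps.
    """
    i = _truth_index(truth, timestamp)
    if i == 0:
        raise KeyError("first frame has no preceding frame to pair with")
    c1, r1 = project_to_view(truth.x_mm[i - 1], truth.y_mm[i - 1], truth.z_mm[i - 1], view, config)
    c2, r2 = project_to_view(truth.x_mm[i], truth.y_mm[i], truth.z_mm[i], view, config)
    return (c1 + c2) / 2.0, (r1 + r2) / 2.0


def score_against_truth(
    detections: list[Detection2D],
    truth: GroundTruth,
    config: SimConfig,
    tolerance_px: float = 5.0,
    n_sample: int | None = None,
    seed: int = 0,
) -> AccuracyReport:
    """Score sampled detections against the rendered ground truth.

    A detection is correct iff it is valid, the fish was visible in both
    frames of its pair, and its centroid lies within ``tolerance_px`` of
    the projected reference point.
    """
    if not detections:
        raise ValueError("no detections to score")
    sampled = detections
    if n_sample is not None:
        sampled = sample_frames_for_validation(detections, n_sample, seed)
    n_correct = 0
    n_scored = 0
    for det in sampled:
        i = _truth_index(truth, det.timestamp)
        n_scored += 1
        visible = bool(truth.visible[i] and truth.visible[i - 1])
        if not (det.valid and visible):
            continue
        ref_c, ref_r = reference_point_px(truth, det.timestamp, det.view, config)
        dist = float(np.hypot(det.cx_px - ref_c, det.cy_px - ref_r))
        if dist <= tolerance_px:
            n_correct += 1
    if n_scored == 0:
        raise ValueError("no detections overlap the ground truth timestamps")
    return AccuracyReport(
        n_sampled=n_scored,
        n_correct=n_correct,
        accuracy=n_correct / n_scored,
        tolerance_px=tolerance_px,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# End-to-end runs

def default_detection_params(config: SimConfig, view: str, **overrides) -> DetectionParams:
    return DetectionParams(roi=config.roi(view), **overrides)


def run_synthetic_experiment(
    config: SimConfig,
    detection: dict | None = None,
    x_tolerance_mm: float = 30.0,
    window_s: float = 10.0,
    group_label: str = "",
) -> dict:
    """Simulate, render, detect, fuse and summarize one recording in memory.

    Frames are rendered and consumed streamingly (two frames per view live
    at a time), so a 10-hour full-resolution run fits in ordinary memory.
    Returns the ground truth, per-view detections, fused track, speed
    series and stage counts.
    """
    detection = detection or {}
    truth = simulate_trajectory(config)
    detections: dict[str, list[Detection2D]] = {}
    for view in VIEWS:
        params = default_detection_params(config, view, **detection)
        detections[view] = detect_sequence(render_sequence(truth, view, config), params)
    calib = build_calibration(config.tank, config.roi_front, config.roi_top)
    pairs = pair_by_time(detections["front"], detections["top"])
    track = fuse_track(pairs, calib, x_tolerance_mm, start_time=config.start_time)
    total_mm, _ = kinematics.accumulate(track)
    times, speeds = per_second_speeds(track)
    series = bin_speeds(times, speeds, window_s=window_s, group_label=group_label)
    counts = {
        "frames_per_view": len(truth),
        "frame_pairs_per_view": len(truth) - 1,
        "valid_detections_front": sum(d.valid for d in detections["front"]),
        "valid_detections_top": sum(d.valid for d in detections["top"]),
        "paired": len(pairs),
        "accepted": sum(p.accepted for p in track),
        "rejected": sum(not p.accepted for p in track),
        "speeds": int(speeds.size),
        "binned": int(series.values.size),
    }
    return {
        "config": config,
        "truth": truth,
        "detections": detections,
        "calibration": calib,
        "track": track,
        "total_distance_mm": total_mm,
        "speed_times_s": times,
        "speeds_mm_s": speeds,
        "series": series,
        "counts": counts,
    }


def detect_directory(
    dataset_dir: str | Path, params_by_view: dict[str, DetectionParams]
) -> dict[str, list[Detection2D]]:
    """Run detection over an on-disk dataset written by ``write_dataset``."""
    dataset_dir = Path(dataset_dir)
    out = {}
    for view in VIEWS:
        frames = load_frame_sequence(dataset_dir, view)
        out[view] = detect_sequence(frames, params_by_view[view])
    return out


def config_hash(config: dict) -> str:
    """Stable hash of a configuration document."""
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, out_dir: str | Path, make_plots: bool = True) -> dict:
    """Execute the full multi-group pipeline from a configuration document.

    The config has sections ``simulation`` (SimConfig fields shared by all
    groups), ``groups`` (list of per-group overrides with at least a
    ``label``), ``detection``, ``fusion``, ``analysis`` and ``validation``.
    Writes detection/track/speed CSVs, a statistics report (JSON + CSV),
    figures and a provenance JSON; returns the in-memory results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if int(config.get("n_fish", 1)) != 1:
        raise ValueError("the pipeline tracks a single fish; n_fish must be 1")
    sim_common = dict(config.get("simulation", {}))
    groups = config.get("groups") or [{"label": "group0"}]
    det_cfg = dict(config.get("detection", {}))
    fusion_cfg = dict(config.get("fusion", {}))
    analysis_cfg = dict(config.get("analysis", {}))
    valid_cfg = dict(config.get("validation", {}))
    window_s = float(analysis_cfg.get("window_s", 10.0))
    alpha = float(analysis_cfg.get("alpha", 0.05))
    grid = tuple(analysis_cfg.get("grid", (10, 10, 10)))

    results = []
    provenance_groups = {}
    for group_entry in groups:
        group_entry = dict(group_entry)
        label = str(group_entry.pop("label"))
        sim_kwargs = {**sim_common, **group_entry}
        sim = SimConfig.from_dict(sim_kwargs)
        logger.info("running group %s (stress=%.2f, seed=%d)", label, sim.stress, sim.seed)
        try:
            res = run_synthetic_experiment(
                sim, detection=det_cfg,
                x_tolerance_mm=float(fusion_cfg.get("x_tolerance_mm", 30.0)),
                window_s=window_s, group_label=label,
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'experiment' failed for group {label}") from exc
        all_detections = res["detections"]["front"] + res["detections"]["top"]
        accuracy = score_against_truth(
            all_detections, res["truth"], sim,
            tolerance_px=float(valid_cfg.get("tolerance_px", 5.0)),
            n_sample=valid_cfg.get("n_sample"),
            seed=int(valid_cfg.get("seed", sim.seed)),
        )
        res["accuracy"] = accuracy
        res["occupancy"] = occupancy(res["track"], sim.tank, grid)
        res["label"] = label
        slug = label.replace(" ", "_").replace("/", "-")
        write_detection_log(all_detections, out_dir / f"detections_{slug}.csv")
        write_track_csv(res["track"], out_dir / f"track_{slug}.csv")
        write_speed_csv(res["series"], window_s, sim.start_time, out_dir / f"speeds_{slug}.csv")
        results.append(res)
        provenance_groups[label] = {
            **res["counts"],
            "accuracy": accuracy.accuracy,
            "total_distance_mm": res["total_distance_mm"],
            "visited_fraction": res["occupancy"].visited_fraction,
        }

    summary_rows = [summarize_speeds(res["series"]) for res in results]
    pd.DataFrame(summary_rows).to_csv(out_dir / "speed_summary.csv", index=False)

    report = None
    if len(results) >= 2:
        report = behav_stats.compare_groups([res["series"] for res in results], alpha=alpha)
        with open(out_dir / "statistics.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        if report.dunn is not None:
            k = len(report.group_labels)
            dunn_df = pd.DataFrame(
                [
                    [
                        "X" if i == j else
                        f"{report.labels[i][j]} p={report.dunn.p_adjusted[i, j]:.6g}"
                        for j in range(k)
                    ]
                    for i in range(k)
                ],
                index=report.group_labels, columns=report.group_labels,
            )
            dunn_df.to_csv(out_dir / "dunn_matrix.csv")

    if make_plots:
        from . import plotting
        for res in results:
            slug = res["label"].replace(" ", "_").replace("/", "-")
            plotting.plot_trajectory_3d(
                res["track"], res["config"].tank, out_dir / f"trajectory_{slug}.png",
            )
        plotting.plot_total_distances(
            [res["label"] for res in results],
            [res["total_distance_mm"] / 1000.0 for res in results],
            out_dir / "total_distances.png",
        )

    provenance = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pd.__version__,
        },
        "groups": provenance_groups,
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return {"results": results, "report": report, "provenance": provenance}
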