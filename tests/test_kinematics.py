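"""Distances, speeds, binning and occupancy."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from fishtrack3d.fuse3d import TrackPoint3D
from fishtrack3d.kinematics import (
    SpeedSeries,
    accumulate,
    bin_speeds,
    occupancy,
    per_second_speeds,
    step_distance,
    summarize_speeds,
)
from fishtrack3d.synthgen import TankGeometry

T0 = datetime(2025, 1, 1, 9, 0, 0)


def track_point(elapsed, x, y=100.0, z=100.0, accepted=True):
    return TrackPoint3D(
        timestamp=T0 + timedelta(seconds=elapsed), elapsed_s=float(elapsed),
        x_mm=float(x), y_mm=float(y), z_mm=float(z),
        step_distance_mm=0.0, x_discrepancy_mm=0.0, accepted=accepted,
    )


class TestStepDistance:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            ((0, 0, 0), (1, 2, 2), 3.0),
            ((1, 1, 1), (1, 1, 1), 0.0),
            ((0, 0, 0), (3, 4, 0), 5.0),
        ],
    )
    def test_known_distances(self, p1, p2, expected):
        assert step_distance(p1, p2) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            step_distance((0, 0, float("nan")), (1, 1, 1))

    def test_metric_properties_on_random_triples(self, rng):
        pts = rng.uniform(-100, 100, size=(1000, 3, 3))
        for p, q, r in pts:
            dpq = step_distance(p, q)
            assert dpq >= 0
            assert dpq == pytest.approx(step_distance(q, p))
            assert dpq <= step_distance(p, r) + step_distance(r, q) + 1e-9


class TestAccumulate:
    def test_collinear_points(self):
        track = [track_point(i, 100 + 10 * i) for i in range(3)]
        total, steps = accumulate(track)
        assert total == pytest.approx(20.0)
        assert steps.tolist() == pytest.approx([10.0, 10.0])

    def test_total_at_least_net_displacement(self, rng):
        track = [track_point(i, *rng.uniform(50, 400, 3)) for i in range(50)]
        total, _ = accumulate(track)
        net = step_distance(
            (track[0].x_mm, track[0].y_mm, track[0].z_mm),
            (track[-1].x_mm, track[-1].y_mm, track[-1].z_mm),
        )
        assert total >= net - 1e-9

    def test_too_few_points_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            total, steps = accumulate([track_point(0, 100)])
        assert total == 0.0
        assert steps.size == 0


class TestPerSecondSpeeds:
    def test_unit_interval_speed(self):
        track = [track_point(0, 100), track_point(1, 130)]
        _, speeds = per_second_speeds(track)
        assert speeds.tolist() == pytest.approx([30.0])

    def test_gap_divides_by_elapsed_time(self):
        track = [track_point(0, 100), track_point(3, 130)]
        times, speeds = per_second_speeds(track)
        assert times.tolist() == [3.0]
        assert speeds.tolist() == pytest.approx([10.0])

    def test_stationary_zero(self):
        track = [track_point(0, 100), track_point(1, 100)]
        _, speeds = per_second_speeds(track)
        assert speeds.tolist() == [0.0]

    def test_rejected_points_skipped(self):
        track = [
            track_point(0, 100),
            track_point(1, 500, accepted=False),
            track_point(2, 120),
        ]
        times, speeds = per_second_speeds(track)
        assert times.tolist() == [2.0]
        assert speeds.tolist() == pytest.approx([10.0])


class TestBinSpeeds:
    def test_ten_hour_recording_gives_3600_bins(self):
        times = np.arange(1, 36001, dtype=float)
        speeds = np.full(36000, 20.0)
        series = bin_speeds(times, speeds, 10.0)
        assert series.values.size == 3600
        assert series.n_expected == 3600

    def test_trailing_incomplete_window_dropped(self):
        times = np.arange(1, 26, dtype=float)
        series = bin_speeds(times, np.ones(25), 10.0)
        assert series.values.size == 2

    def test_constant_speeds_preserved(self):
        times = np.arange(1, 101, dtype=float)
        series = bin_speeds(times, np.full(100, 7.5), 10.0)
        assert np.allclose(series.values, 7.5)

    def test_windowed_mean_conservation(self, rng):
        # mean over complete windows equals count-weighted mean of bins, exactly
        times = np.arange(1, 96, dtype=float)
        keep = rng.random(95) > 0.2  # gaps
        times = times[keep]
        speeds = rng.uniform(0, 50, keep.sum())
        series = bin_speeds(times, speeds, 10.0)
        n_complete = series.n_expected
        in_complete = times < n_complete * 10.0
        counts = np.bincount(
            (times[in_complete] // 10).astype(int), minlength=n_complete
        )
        counts = counts[counts > 0]
        weighted = np.sum(series.values * counts) / counts.sum()
        assert weighted == pytest.approx(speeds[in_complete].mean(), abs=1e-12)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            bin_speeds(np.array([1.0]), np.array([1.0]), 0.0)


class TestSummarizeSpeeds:
    def test_known_sample(self):
        s = summarize_speeds(SpeedSeries("g", np.array([0.0, 10.0, 20.0]), 3))
        assert (s["min"], s["max"], s["mean"]) == (0.0, 20.0, 10.0)
        assert s["sd"] == pytest.approx(10.0)

    def test_single_value_degenerate(self):
        with pytest.raises(ValueError):
            summarize_speeds(SpeedSeries("g", np.array([5.0]), 1))

    def test_matches_direct_recomputation(self, rng):
        v = rng.gamma(2.0, 10.0, 1000)
        s = summarize_speeds(SpeedSeries("g", v, 1000))
        assert s["mean"] == pytest.approx(float(np.sum(v)) / 1000, abs=1e-12)
        assert s["sd"] == pytest.approx(
            float(np.sqrt(np.sum((v - v.mean()) ** 2) / 999)), abs=1e-12
        )


class TestOccupancy:
    def test_single_cell(self, tank):
        track = [track_point(i, 100.0, 100.0, 100.0) for i in range(5)]
        occ = occupancy(track, tank, (10, 10, 10))
        assert occ.visited_fraction == pytest.approx(0.001)
        assert occ.per_cell_counts.sum() == 5

    def test_full_coverage(self, tank):
        centers = []
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    centers.append([
                        (i + 0.5) * tank.width_x / 10,
                        (j + 0.5) * tank.height_y / 10,
                        (k + 0.5) * tank.depth_z / 10,
                    ])
        occ = occupancy(np.array(centers), tank, (10, 10, 10))
        assert occ.visited_fraction == 1.0

    def test_marginal_point_counts_in_boundary_cell(self, tank):
        occ = occupancy(np.array([[-1.0, 5.0, 5.0]]), tank, (10, 10, 10))
        assert occ.per_cell_counts[0, 0, 0] == 1

    def test_far_outside_point_rejected(self, tank):
        with pytest.raises(ValueError):
            occupancy(np.array([[-100.0, 5.0, 5.0]]), tank, (10, 10, 10))
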