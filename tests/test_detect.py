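"""Frame-differencing detector: unit behavior and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fishtrack3d.detect import (
    Component,
    DetectionParams,
    binarize,
    component_features,
    detect_pair,
    detect_sequence,
    frame_difference,
    label_components,
    preprocess,
    select_fish_component,
)
from fishtrack3d.synthgen import render_frame, simulate_trajectory

from conftest import make_small_config
from oracles import direct_moments, flood_fill_components

PARAMS = DetectionParams(roi=(0, 0, 64, 64))


class TestPreprocess:
    def test_half_open_crop_shape(self):
        frame = np.zeros((1080, 1920), dtype=np.uint8)
        out = preprocess(frame, DetectionParams(roi=(100, 100, 1200, 900)))
        assert out.shape == (800, 1100)

    def test_gray_input_is_pixel_identical(self, rng):
        frame = rng.integers(0, 256, (50, 60), dtype=np.uint8)
        out = preprocess(frame, DetectionParams(roi=(10, 5, 40, 30)))
        assert np.array_equal(out, frame[5:30, 10:40])

    def test_full_frame_roi_is_identity(self, rng):
        frame = rng.integers(0, 256, (50, 60), dtype=np.uint8)
        out = preprocess(frame, DetectionParams(roi=(0, 0, 60, 50)))
        assert np.array_equal(out, frame)

    def test_color_converted_by_luminance(self):
        frame = np.zeros((4, 4, 3), dtype=np.uint8)
        frame[..., 1] = 100  # pure green
        out = preprocess(frame, DetectionParams(roi=(0, 0, 4, 4)))
        assert np.all(out == round(0.587 * 100))

    def test_roi_outside_frame_rejected(self):
        frame = np.zeros((20, 20), dtype=np.uint8)
        with pytest.raises(ValueError, match="ROI"):
            preprocess(frame, DetectionParams(roi=(0, 0, 30, 10)))


class TestFrameDifference:
    def test_identical_frames_give_zero(self, rng):
        a = rng.integers(0, 256, (30, 30), dtype=np.uint8)
        assert not frame_difference(a, a.copy()).any()

    def test_constant_offset(self):
        a = np.full((8, 8), 10, dtype=np.uint8)
        b = np.full((8, 8), 70, dtype=np.uint8)
        assert np.all(frame_difference(a, b) == 60)

    def test_symmetry(self, rng):
        a = rng.integers(0, 256, (30, 30), dtype=np.uint8)
        b = rng.integers(0, 256, (30, 30), dtype=np.uint8)
        assert np.array_equal(frame_difference(a, b), frame_difference(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            frame_difference(np.zeros((3, 3)), np.zeros((4, 3)))


class TestBinarize:
    def test_strict_threshold_boundary(self):
        diff = np.array([[60, 61]], dtype=np.uint8)
        out = binarize(diff, 60)
        assert out.tolist() == [[False, True]]

    def test_zero_difference_has_no_foreground(self):
        assert not binarize(np.zeros((10, 10), dtype=np.uint8), 60).any()

    @given(
        img=arrays(np.uint8, (16, 16), elements=st.integers(0, 255)),
        t1=st.integers(1, 253),
        t2=st.integers(1, 253),
    )
    @settings(max_examples=50)
    def test_raising_threshold_never_adds_foreground(self, img, t1, t2):
        lo, hi = sorted((t1, t2))
        assert binarize(img, hi).sum() <= binarize(img, lo).sum()


class TestLabelComponents:
    def test_two_disjoint_squares(self):
        img = np.zeros((10, 10), dtype=bool)
        img[1:4, 1:4] = True
        img[6:9, 6:9] = True
        comps = label_components(img, 8)
        assert sorted(c.area for c in comps) == [9, 9]

    def test_diagonal_connectivity_semantics(self):
        img = np.zeros((4, 4), dtype=bool)
        img[1, 1] = img[2, 2] = True
        assert len(label_components(img, 8)) == 1
        assert len(label_components(img, 4)) == 2

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(30):
            img = rng.random((64, 64)) < rng.uniform(0.05, 0.5)
            for conn in (4, 8):
                mine = label_components(img, conn)
                oracle = flood_fill_components(img, conn)
                mine_sets = {frozenset(zip(c.rows.tolist(), c.cols.tolist())) for c in mine}
                oracle_sets = {frozenset(c) for c in oracle}
                assert mine_sets == oracle_sets


class TestSelectFishComponent:
    @staticmethod
    def _component(pixels):
        rows = np.array([p[0] for p in pixels])
        cols = np.array([p[1] for p in pixels])
        return Component(rows=rows, cols=cols)

    def test_largest_area_wins(self):
        fish = self._component([(r, c) for r in range(30) for c in range(30)])
        bubble = self._component([(50, 50), (50, 51), (51, 50)])
        assert select_fish_component([bubble, fish], 30) is fish

    def test_area_floor_marks_invalid(self):
        small = self._component([(0, 0), (0, 1)])
        assert select_fish_component([small], 30) is None
        assert select_fish_component([], 30) is None

    def test_tie_breaks_on_top_left_pixel(self):
        a = self._component([(5, 5), (5, 6)])
        b = self._component([(2, 9), (2, 10)])
        for order in ([a, b], [b, a]):
            assert select_fish_component(order, 1) is b


class TestComponentFeatures:
    def test_single_pixel(self):
        comp = Component(rows=np.array([5]), cols=np.array([10]))
        cx, cy, area, _ = component_features(comp)
        assert (cx, cy, area) == (10.0, 5.0, 1.0)

    def test_two_by_two_block(self):
        comp = Component(rows=np.array([0, 0, 1, 1]), cols=np.array([0, 1, 0, 1]))
        cx, cy, area, _ = component_features(comp)
        assert (cx, cy, area) == (0.5, 0.5, 4.0)

    def test_rectangle_orientation(self):
        wide = Component(
            rows=np.repeat(np.arange(6), 20), cols=np.tile(np.arange(20), 6)
        )
        tall = Component(
            rows=np.repeat(np.arange(20), 6), cols=np.tile(np.arange(6), 20)
        )
        assert component_features(wide)[3] == 0.0
        assert component_features(tall)[3] == -90.0

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(30):
            img = rng.random((32, 32)) < 0.3
            if not img.any():
                continue
            for comp in label_components(img, 8):
                pixels = set(zip(comp.rows.tolist(), comp.cols.tolist()))
                ocx, ocy, oarea, oang = direct_moments(pixels)
                cx, cy, area, ang = component_features(comp)
                assert (cx, cy, area) == pytest.approx((ocx, ocy, oarea))
                assert ang == pytest.approx(oang)

    def test_centroid_inside_component_bbox(self, rng):
        for _ in range(20):
            img = rng.random((40, 40)) < 0.2
            comp = select_fish_component(label_components(img, 8), 1)
            if comp is None:
                continue
            cx, cy, _, _ = component_features(comp)
            assert comp.cols.min() <= cx <= comp.cols.max()
            assert comp.rows.min() <= cy <= comp.rows.max()

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            component_features(Component(rows=np.array([]), cols=np.array([])))


class TestDetectPair:
    def test_identical_frames_invalid(self):
        cfg = make_small_config()
        truth = simulate_trajectory(cfg)
        frame = render_frame(truth.record(0), "front", cfg, np.random.default_rng(0))
        later = type(frame)(
            timestamp=truth.record(1).timestamp, view="front", image=frame.image
        )
        det = detect_pair(frame, later, DetectionParams(roi=cfg.roi_front))
        assert not det.valid
        assert np.isnan(det.cx_px)

    def test_moving_fish_detected_near_pair_midpoint(self):
        from fishtrack3d.pipeline import reference_point_px

        cfg = make_small_config(seed=11)
        truth = simulate_trajectory(cfg)
        rng = np.random.default_rng(7)
        frames = [render_frame(truth.record(i), "top", cfg, rng) for i in (4, 5)]
        (det,) = detect_sequence(frames, DetectionParams(roi=cfg.roi_top))
        assert det.valid
        rc, rr = reference_point_px(truth, det.timestamp, "top", cfg)
        assert np.hypot(det.cx_px - rc, det.cy_px - rr) <= 3.0

    def test_bubble_does_not_steal_detection(self):
        from fishtrack3d.pipeline import reference_point_px

        cfg = make_small_config(seed=2, bubble_rate=1.5)
        truth = simulate_trajectory(cfg)
        rng = np.random.default_rng(3)
        frames = [render_frame(truth.record(i), "top", cfg, rng) for i in (0, 1)]
        det = detect_pair(frames[0], frames[1], DetectionParams(roi=cfg.roi_top))
        assert det.valid
        rc, rr = reference_point_px(truth, det.timestamp, "top", cfg)
        assert np.hypot(det.cx_px - rc, det.cy_px - rr) <= 5.0

    def test_view_mismatch_rejected(self):
        cfg = make_small_config()
        truth = simulate_trajectory(cfg)
        rng = np.random.default_rng(0)
        a = render_frame(truth.record(0), "front", cfg, rng)
        b = render_frame(truth.record(1), "top", cfg, rng)
        with pytest.raises(ValueError, match="view"):
            detect_pair(a, b, DetectionParams(roi=cfg.roi_front))
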