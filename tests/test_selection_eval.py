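"""Minimum enclosing circle, candidate scoring, selection, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fruitpick as fp
from fruitpick.selection_eval import circle_mask

from conftest import brute_force_circle


class TestMinEnclosingCircle:
    def test_two_points_span_a_diameter(self):
        (cy, cx), r = fp.min_enclosing_circle([(0, 0), (2, 0)])
        assert (cy, cx) == pytest.approx((1.0, 0.0))
        assert r == pytest.approx(1.0)

    def test_obtuse_triangle_circle_rests_on_longest_side(self):
        (cy, cx), r = fp.min_enclosing_circle([(0, 0), (4, 0), (2, 2)])
        assert (cy, cx) == pytest.approx((2.0, 0.0))
        assert r == pytest.approx(2.0)

    def test_single_point_has_zero_radius(self):
        (cy, cx), r = fp.min_enclosing_circle([(3, 4)])
        assert (cy, cx, r) == (3.0, 4.0, 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fp.min_enclosing_circle([])

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_candidate_circle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, (int(rng.integers(2, 13)), 2))
        (cy, cx), r = fp.min_enclosing_circle(pts)
        ref_c, ref_r = brute_force_circle(pts)
        assert r == pytest.approx(ref_r, abs=1e-6)
        assert np.hypot(cy - ref_c[0], cx - ref_c[1]) < 1e-5


class TestCompositeScore:
    def test_single_candidate_scores_one(self):
        assert fp.composite_score([(300, 700)])[0] == pytest.approx(1.0)

    def test_half_area_double_depth_scores_half(self):
        scores = fp.composite_score([(400, 500), (200, 1000)])
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(0.5)

    def test_equal_candidates_score_equally(self):
        scores = fp.composite_score([(250, 800), (250, 800)])
        assert scores[0] == scores[1]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        scale_a=st.floats(0.1, 10),
        scale_d=st.floats(0.1, 10),
        seed=st.integers(0, 50),
    )
    def test_scale_invariance(self, scale_a, scale_d, seed):
        rng = np.random.default_rng(seed)
        cands = rng.uniform(10, 1000, (5, 2))
        base = fp.composite_score(cands)
        scaled = fp.composite_score(cands * [scale_a, scale_d])
        assert np.allclose(base, scaled)


class TestSelectTarget:
    def _scene(self, pick_flags, areas, depths):
        h, w = 60, 120
        labels = np.zeros((h, w), dtype=np.uint8)
        depth = np.zeros((h, w), dtype=np.uint16)
        instances, reports = [], []
        col = 10
        for i, (pick, area, d) in enumerate(zip(pick_flags, areas, depths)):
            side = int(np.sqrt(area))
            mask = np.zeros((h, w), dtype=bool)
            mask[10 : 10 + side, col : col + side] = True
            col += side + 10
            depth[mask] = d
            instances.append(fp.InstanceMask(i, mask))
            reports.append(
                fp.OcclusionReport(
                    instance_id=i,
                    n_regions=1 if pick else 2,
                    blind_spots=[],
                    obstacle_classes=set() if pick else {"stem"},
                    occluded=not pick,
                    pickable=pick,
                )
            )
        return reports, instances, fp.DepthMap(depth)

    def test_blocked_instances_are_filtered_out(self):
        reports, instances, depth = self._scene([True, False], [100, 400], [900, 500])
        target = fp.select_target(reports, instances, depth)
        assert target.instance_id == 0

    def test_larger_and_closer_dominates(self):
        reports, instances, depth = self._scene([True, True], [400, 100], [500, 900])
        target = fp.select_target(reports, instances, depth)
        assert target.instance_id == 0
        assert target.score == pytest.approx(1.0)

    def test_all_blocked_yields_none(self):
        reports, instances, depth = self._scene([False, False], [100, 100], [500, 500])
        assert fp.select_target(reports, instances, depth) is None

    def test_circle_encloses_instance_pixels(self):
        reports, instances, depth = self._scene([True], [225], [700])
        target = fp.select_target(reports, instances, depth)
        pix = instances[0].pixels
        dists = np.hypot(pix[:, 0] - target.center[0], pix[:, 1] - target.center[1])
        assert dists.max() <= target.radius + 1e-6


class TestSegmentationMetrics:
    def test_perfect_prediction_is_100(self):
        g = np.array([[1, 2], [3, 0]])
        assert fp.pixel_accuracy([g], [g]) == 100.0
        assert fp.class_iou([g], [g], 1) == 100.0

    def test_three_of_four_pixels_is_75(self):
        g = np.array([[1, 1], [0, 0]])
        p = np.array([[1, 1], [0, 2]])
        assert fp.pixel_accuracy([p], [g]) == pytest.approx(75.0)

    def test_image_mean_then_average_order(self):
        g = np.zeros((2, 2), dtype=int)
        p_good = g.copy()
        p_half = np.array([[0, 0], [1, 1]])
        assert fp.pixel_accuracy([p_good, p_half], [g, g]) == pytest.approx(75.0)

    def test_disjoint_masks_have_zero_iou(self):
        g = np.array([[1, 1], [0, 0]])
        p = np.array([[0, 0], [1, 1]])
        assert fp.class_iou([p], [g], 1) == 0.0

    def test_half_overlap_is_50(self):
        g = np.ones((4, 4), dtype=int)
        p = np.zeros((4, 4), dtype=int)
        p[:, :2] = 1
        assert fp.class_iou([p], [g], 1) == pytest.approx(50.0)

    def test_absent_class_skipped_in_mean(self):
        g = np.array([[1, 1], [0, 0]])
        assert np.isnan(fp.class_iou([g], [g], 5))
        assert fp.mean_iou([g], [g], [0, 1, 5]) == pytest.approx(100.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fp.pixel_accuracy([np.zeros((2, 2))], [np.zeros((3, 3))])


class TestDetectionMetrics:
    def _disk_targets(self, centers, radius=4.0):
        return [
            fp.GroundTruthTarget(center=c, radius=radius, pickable=True)
            for c in centers
        ]

    def test_perfect_predictions_score_100_everywhere(self):
        gts = self._disk_targets([(10, 10), (10, 30), (30, 10)])
        p, r, f1 = fp.detection_prf(gts, gts, shape=(40, 40))
        assert (p, r, f1) == (100.0, 100.0, 100.0)

    def test_eight_tp_two_fp_two_fn_gives_80_80_80(self):
        centers = [(10 + 12 * i, 10 + 12 * j) for i in range(4) for j in range(3)][:10]
        gts = self._disk_targets(centers)
        preds = self._disk_targets(centers[:8] + [(150, 150), (150, 170)])
        p, r, f1 = fp.detection_prf(preds, gts, shape=(200, 200))
        assert (p, r, f1) == (pytest.approx(80.0),) * 3

    def test_overlap_must_exceed_half_of_ground_truth(self):
        gt_mask = np.zeros((10, 20), dtype=bool)
        gt_mask[0:10, 0:10] = True  # 100 px
        under = np.zeros_like(gt_mask)
        under[0:10, 5:10] = True  # 50 px overlap: not > 0.5
        over = np.zeros_like(gt_mask)
        over[0:10, 4:10] = True  # 60 px overlap
        p, r, _ = fp.detection_prf([under], [gt_mask])
        assert (p, r) == (0.0, 0.0)
        p, r, _ = fp.detection_prf([over], [gt_mask])
        assert (p, r) == (100.0, 100.0)

    def test_no_predictions_gives_zero_by_convention(self):
        gts = self._disk_targets([(5, 5)])
        p, r, f1 = fp.detection_prf([], gts, shape=(10, 10))
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_f1_bounded_by_max_of_p_and_r(self):
        gts = self._disk_targets([(10, 10), (10, 30)])
        preds = self._disk_targets([(10, 10), (100, 100), (100, 120)])
        p, r, f1 = fp.detection_prf(preds, gts, shape=(140, 140))
        assert 0 <= f1 <= max(p, r)


class TestPositioningError:
    def test_identical_centers_zero_error(self):
        gt = fp.GroundTruthTarget(center=(5, 5), radius=10)
        assert fp.positioning_error((5, 5), gt) == 0.0

    def test_three_four_offset_with_radius_ten_is_50(self):
        gt = fp.GroundTruthTarget(center=(0, 0), radius=10)
        assert fp.positioning_error((3, 4), gt) == pytest.approx(50.0)

    def test_offset_equal_to_radius_is_100(self):
        gt = fp.GroundTruthTarget(center=(0, 0), radius=7)
        assert fp.positioning_error((0, 7), gt) == pytest.approx(100.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        dy=st.floats(-50, 50),
        dx=st.floats(-50, 50),
        ty=st.floats(-100, 100),
        tx=st.floats(-100, 100),
        r=st.floats(0.5, 40),
    )
    def test_translation_invariant_and_inverse_in_radius(self, dy, dx, ty, tx, r):
        gt = fp.GroundTruthTarget(center=(ty, tx), radius=r)
        pe = fp.positioning_error((ty + dy, tx + dx), gt)
        gt2 = fp.GroundTruthTarget(center=(0, 0), radius=r)
        assert pe == pytest.approx(fp.positioning_error((dy, dx), gt2), rel=1e-9, abs=1e-9)
        gt_double = fp.GroundTruthTarget(center=(ty, tx), radius=2 * r)
        assert fp.positioning_error((ty + dy, tx + dx), gt_double) == pytest.approx(
            pe / 2, rel=1e-9, abs=1e-9
        )

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            fp.GroundTruthTarget(center=(0, 0), radius=0)


def test_circle_mask_is_inclusive_disk():
    mask = circle_mask((2, 2), 2.0, (5, 5))
    assert mask[2, 2] and mask[0, 2] and mask[2, 4]
    assert not mask[0, 0]
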