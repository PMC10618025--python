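"""Detection/angle/counting metrics against hand evaluation and oracles."""

import math

import numpy as np
import pytest

from spikenet.metrics import (MatchResult, UndefinedMetricError, angle_errors,
                              average_precision, counting_errors, evaluate, match,
                              precision_recall, circular_angle_diff)
from spikenet.rotgeom import OrientedBox

from conftest import ap_threshold_sweep_oracle, random_box


def random_scene(rng, n_gt=5, n_extra=3):
    """Ground truth plus detections: jittered copies and random false alarms."""
    gts = [random_box(rng) for _ in range(n_gt)]
    dets = []
    for g in gts:
        if rng.uniform() < 0.8:
            d = OrientedBox(g.cx + rng.normal(0, 1.5), g.cy + rng.normal(0, 1.5),
                            g.w * rng.uniform(0.85, 1.15), g.h * rng.uniform(0.9, 1.2),
                            g.theta_deg + rng.normal(0, 5))
            dets.append((d, float(rng.uniform(0.3, 1.0))))
    for _ in range(n_extra):
        dets.append((random_box(rng), float(rng.uniform(0.0, 0.9))))
    rng.shuffle(dets)
    return dets, gts


class TestMatch:
    def test_perfect_overlap_all_tp(self, rng):
        gts = [random_box(rng) for _ in range(5)]
        dets = [(g, 0.9) for g in gts]
        m = match([dets], [gts], 0.5)
        assert m.n_tp == 5 and m.n_fp == 0 and m.n_fn == 0

    def test_empty_image_all_fp(self, rng):
        dets = [(random_box(rng), 0.7) for _ in range(3)]
        m = match([dets], [[]], 0.5)
        assert m.n_tp == 0 and m.n_fp == 3 and m.n_fn == 0

    def test_each_gt_matched_at_most_once(self, rng):
        g = random_box(rng)
        dets = [(g, 0.9), (g, 0.8), (g, 0.7)]
        m = match([dets], [[g]], 0.5)
        assert m.n_tp == 1 and m.n_fp == 2 and m.n_fn == 0

    def test_partition_invariant(self, rng):
        for _ in range(10):
            dets, gts = random_scene(rng, n_gt=5, n_extra=5)
            m = match([dets], [gts], 0.5)
            assert m.n_tp + m.n_fn == len(gts)
            assert m.n_tp + m.n_fp == len(dets)

    def test_greedy_confidence_order_oracle(self, rng):
        """Confidence-ordered greedy matching re-derived independently."""
        from spikenet.rotgeom import rotated_iou

        for _ in range(10):
            dets, gts = random_scene(rng, n_gt=5, n_extra=5)
            m = match([dets], [gts], 0.4)
            order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
            taken, tp_pairs = set(), []
            for i in order:
                ious = [(rotated_iou(dets[i][0], g), j) for j, g in enumerate(gts)
                        if j not in taken]
                if ious:
                    best_iou, best_j = max(ious)
                    if best_iou >= 0.4:
                        taken.add(best_j)
                        tp_pairs.append((i, best_j))
            assert sorted((d, g) for d, g, _ in m.tp[0]) == sorted(tp_pairs)


class TestPrecisionRecall:
    def test_direct_ratios(self):
        m = MatchResult(tp=[[(i, i, 0.9) for i in range(8)]], fp=[[100, 101]], fn=[[]])
        p, r = precision_recall(m)
        assert p == pytest.approx(0.8)
        assert r == 1.0

    def test_recall_ratio(self):
        m = MatchResult(tp=[[(0, 0, 0.9)] * 3], fp=[[]], fn=[[1]])
        assert precision_recall(m)[1] == pytest.approx(0.75)

    def test_degenerate_zero_conventions(self):
        m = MatchResult(tp=[[]], fp=[[]], fn=[[]])
        assert precision_recall(m) == (0.0, 0.0)


class TestAveragePrecision:
    def test_single_perfect_detection(self, rng):
        g = random_box(rng)
        assert average_precision([[(g, 0.8)]], [[g]], 0.5) == 1.0

    def test_no_detections(self, rng):
        assert average_precision([[]], [[random_box(rng)]], 0.5) == 0.0

    def test_no_ground_truth(self, rng):
        assert average_precision([[(random_box(rng), 0.5)]], [[]], 0.5) == 0.0

    def test_hand_worked_example(self):
        """4 gt, 6 detections: 3 TPs at conf .9/.7/.5, FPs at .8/.6/.4.

        Cumulative (TP, FP) in confidence order: (1,0) (1,1) (2,1) (2,2)
        (3,2) (3,3); envelope precisions at the three recall steps are 1,
        2/3, 3/5, so AP = (1/4)(1 + 2/3 + 3/5) = 0.5666...
        """
        gts = [OrientedBox(20 * i + 10, 10, 4, 10, 0) for i in range(4)]
        far = [OrientedBox(20 * i + 10, 200, 4, 10, 0) for i in range(3)]
        dets = [(gts[0], 0.9), (far[0], 0.8), (gts[1], 0.7),
                (far[1], 0.6), (gts[2], 0.5), (far[2], 0.4)]
        ap = average_precision([dets], [gts], 0.5)
        assert ap == pytest.approx((1 + 2 / 3 + 3 / 5) / 4, abs=1e-12)

    def test_matches_threshold_sweep_oracle(self, rng):
        for _ in range(10):
            dets, gts = random_scene(rng)
            ap = average_precision([dets], [gts], 0.5)
            assert ap == pytest.approx(ap_threshold_sweep_oracle([dets], [gts], 0.5),
                                       abs=1e-9)

    def test_order_invariance(self, rng):
        dets, gts = random_scene(rng)
        ap = average_precision([dets], [gts], 0.5)
        for _ in range(3):
            shuffled = list(dets)
            rng.shuffle(shuffled)
            assert average_precision([shuffled], [gts], 0.5) == pytest.approx(ap, abs=1e-12)


class TestAngleErrors:
    def _matched(self, pairs):
        """Build dets/gts/match where detection i pairs with gt i."""
        dets, gts, tp = [], [], []
        for i, (p, q) in enumerate(pairs):
            g = OrientedBox(30 * i + 15, 15, 4, 12, q)
            d = OrientedBox(30 * i + 15, 15, 4, 12, p)
            gts.append(g)
            dets.append((d, 0.9))
            tp.append((i, i, 1.0))
        return [dets], [gts], MatchResult(tp=[tp], fp=[[]], fn=[[]])

    def test_perfect_zero(self):
        dets, gts, m = self._matched([(30, 30), (150, 150)])
        assert angle_errors(m, dets, gts) == (0.0, 0.0)

    def test_worked_pairs(self):
        dets, gts, m = self._matched([(10, 13), (50, 46)])
        rmse, mae = angle_errors(m, dets, gts)
        assert mae == pytest.approx(3.5)
        assert rmse == pytest.approx(math.sqrt(12.5))

    def test_circular_difference_near_wrap(self):
        dets, gts, m = self._matched([(179, 1)])
        rmse, mae = angle_errors(m, dets, gts)
        assert mae == pytest.approx(2.0)
        assert rmse == pytest.approx(2.0)

    def test_zero_tp_raises(self):
        m = MatchResult(tp=[[]], fp=[[0]], fn=[[0]])
        with pytest.raises(UndefinedMetricError):
            angle_errors(m, [[]], [[]])

    def test_circular_diff_bounds(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0, 180, 2)
            d = circular_angle_diff(a, b)
            assert 0 <= d <= 90.0
            assert d == pytest.approx(circular_angle_diff(b, a))


class TestCountingErrors:
    def test_identical_counts(self):
        assert counting_errors([3, 7], [3, 7]) == (0.0, 0.0, 0.0)

    def test_worked_example(self):
        rmse, rrmse, mae = counting_errors([8, 24], [10, 20])
        assert mae == pytest.approx(3.0)
        assert rmse == pytest.approx(math.sqrt(10))
        assert rrmse == pytest.approx(0.2)

    def test_single_image(self):
        rmse, rrmse, mae = counting_errors([5], [4])
        assert rmse == mae == 1.0
        assert rrmse == pytest.approx(0.25)

    def test_zero_true_count_gives_nan_relative(self):
        rmse, rrmse, mae = counting_errors([5, 2], [4, 0])
        assert math.isnan(rrmse)
        assert rmse == pytest.approx(math.sqrt((1 + 4) / 2))
        assert mae == pytest.approx(1.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            counting_errors([1], [1, 2])

    def test_mae_le_rmse(self, rng):
        for _ in range(20):
            a = rng.integers(1, 30, 10)
            t = np.maximum(0, a + rng.integers(-5, 6, 10))
            rmse, _, mae = counting_errors(t, a)
            assert mae <= rmse + 1e-12


class TestEvaluate:
    def test_perfect_run(self, rng):
        gts = [[random_box(rng) for _ in range(4)] for _ in range(3)]
        dets = [[(g, 0.9) for g in img] for img in gts]
        s = evaluate(dets, gts, 0.5)
        assert (s.precision, s.recall, s.ap) == (1.0, 1.0, 1.0)
        assert s.rmse_z == s.mae_z == 0.0
        assert s.rmse_c == s.rrmse_c == s.mae_c == 0.0

    def test_empty_detections(self, rng):
        gts = [[random_box(rng) for _ in range(4)]]
        s = evaluate([[]], gts, 0.5)
        assert s.ap == 0.0 and s.recall == 0.0
        assert math.isnan(s.rmse_z)
        assert s.mae_c == 4.0

    def test_summary_consistent_with_components(self, rng):
        dets, gts = random_scene(rng)
        s = evaluate([dets], [gts], 0.5)
        m = match([dets], [gts], 0.5)
        p, r = precision_recall(m)
        assert (s.precision, s.recall) == (p, r)
        assert s.ap == average_precision([dets], [gts], 0.5)
        assert s.n_gt == len(gts)

    def test_json_round_trip(self, rng):
        import json

        dets, gts = random_scene(rng)
        s = evaluate([dets], [gts], 0.5)
        d = json.loads(s.to_json())
        assert d["ap"] == s.ap and d["n_images"] == 1
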