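"""Box geometry, matching, precision/recall and AP against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maizedet.examples import (FPN_AP, OURS_AP, OURS_RECALL, PEST_CLASSES)
from maizedet.metrics import (Box, EmptyGroundTruthError, EvalReport,
                              InvalidBoxError, MatchFlags, PRCurve,
                              average_precision, evaluate, iou,
                              match_detections, mean_ap, precision_recall)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pr_oracle(flags, n_gt):
    """Loop-based cumulative precision/recall."""
    prec, rec, tp = [], [], 0
    for k, f in enumerate(flags, start=1):
        tp += bool(f)
        prec.append(tp / k)
        rec.append(tp / n_gt)
    return np.array(prec), np.array(rec)


def ap_grid_oracle(precision, recall, n_grid=100_000):
    """Riemann integration of the monotone-envelope PR curve on a fine grid."""
    grid = (np.arange(n_grid) + 0.5) / n_grid
    env_at = np.zeros(n_grid)
    for p, r in zip(precision, recall):
        env_at[grid <= r] = np.maximum(env_at[grid <= r], p)
    return env_at.mean()


def random_flags(rng, max_dets=20):
    n_gt = int(rng.integers(1, 10))
    n_det = int(rng.integers(0, max_dets))
    flags = np.zeros(n_det, dtype=bool)
    n_tp = int(rng.integers(0, min(n_det, n_gt) + 1))
    flags[rng.choice(n_det, size=n_tp, replace=False)] = True if n_det else None
    return MatchFlags(flags=flags, n_gt=n_gt)


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------

class TestIoU:
    def test_identical_boxes_give_one(self):
        b = Box(5, 5, 4, 6)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes_give_zero(self):
        assert iou(Box(2, 2, 2, 2), Box(50, 50, 2, 2)) == 0.0

    def test_half_overlap_rectangles(self):
        a = Box.from_corners(0, 0, 10, 10)
        b = Box.from_corners(5, 0, 15, 10)
        assert iou(a, b) == pytest.approx(50 / 150)

    def test_invalid_box_rejected(self):
        with pytest.raises(InvalidBoxError):
            Box(0, 0, -1, 5)
        with pytest.raises(InvalidBoxError):
            Box(0, 0, 3, 0)

    @given(st.tuples(*[st.floats(-50, 50) for _ in range(4)],
                     *[st.floats(0.5, 40) for _ in range(4)]))
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_and_range(self, vals):
        ax, ay, bx, by, aw, ah, bw, bh = vals
        a, b = Box(ax, ay, aw, ah), Box(bx, by, bw, bh)
        v = iou(a, b)
        assert v == pytest.approx(iou(b, a))
        assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

class TestMatching:
    def test_single_overlapping_detection_is_tp(self):
        gt = [Box.from_corners(0, 0, 10, 10, label="a")]
        det = [Box.from_corners(0, 0, 10, 6, label="a", score=0.9)]  # IoU 0.6
        m = match_detections(det, gt)
        assert m.flags.tolist() == [True]

    def test_low_overlap_detection_is_fp(self):
        gt = [Box.from_corners(0, 0, 10, 10, label="a")]
        det = [Box.from_corners(0, 0, 10, 4, label="a", score=0.9)]  # IoU 0.4
        assert match_detections(det, gt).flags.tolist() == [False]

    def test_threshold_is_strict_by_default(self):
        gt = [Box.from_corners(0, 0, 10, 10)]
        det = [Box.from_corners(0, 0, 10, 5, score=0.9)]  # IoU exactly 0.5
        assert match_detections(det, gt).flags.tolist() == [False]
        assert match_detections(det, gt, inclusive=True).flags.tolist() == [True]

    def test_second_detection_on_consumed_gt_is_fp(self):
        gt = [Box.from_corners(0, 0, 10, 10)]
        dets = [Box.from_corners(0, 0, 10, 9, score=0.9),
                Box.from_corners(0, 1, 10, 10, score=0.8)]
        m = match_detections(dets, gt)
        assert m.flags.tolist() == [True, False]

    def test_score_order_decides_who_wins(self):
        # same two detections, swapped confidences: the flags follow score rank
        gt = [Box.from_corners(0, 0, 10, 10)]
        dets = [Box.from_corners(0, 1, 10, 10, score=0.8),
                Box.from_corners(0, 0, 10, 9, score=0.9)]
        m = match_detections(dets, gt)
        assert m.flags.tolist() == [True, False]  # descending-score order
        assert m.order.tolist() == [1, 0]

    def test_unscored_detection_rejected(self):
        with pytest.raises(ValueError, match="score"):
            match_detections([Box(1, 1, 2, 2)], [Box(1, 1, 2, 2)])

    def test_greedy_matches_exhaustive_oracle_on_random_fixtures(self, rng):
        """Greedy-by-score assignment equals a per-rank exhaustive re-check."""
        for _ in range(50):
            gts = [Box(rng.uniform(5, 45), rng.uniform(5, 45),
                       rng.uniform(3, 12), rng.uniform(3, 12))
                   for _ in range(rng.integers(1, 5))]
            dets = [Box(rng.uniform(5, 45), rng.uniform(5, 45),
                        rng.uniform(3, 12), rng.uniform(3, 12),
                        score=float(rng.random()))
                    for _ in range(rng.integers(0, 7))]
            m = match_detections(dets, gts)
            # oracle: replay the greedy protocol with explicit bookkeeping
            order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
            free = set(range(len(gts)))
            expect = []
            for di in order:
                ious = {gi: iou(dets[di], gts[gi]) for gi in free}
                best = max(ious, key=lambda g: ious[g]) if ious else None
                if best is not None and ious[best] > 0.5:
                    expect.append(True)
                    free.remove(best)
                else:
                    expect.append(False)
            assert m.flags.tolist() == expect


# ---------------------------------------------------------------------------
# precision / recall / AP
# ---------------------------------------------------------------------------

class TestPRCurve:
    def test_forced_example(self):
        m = MatchFlags(flags=[True, True, False], n_gt=4)
        pr = precision_recall(m)
        assert pr.precision.tolist() == pytest.approx([1, 1, 2 / 3])
        assert pr.recall.tolist() == pytest.approx([0.25, 0.5, 0.5])

    def test_perfect_detector_reaches_one_one(self):
        pr = precision_recall(MatchFlags(flags=[True] * 5, n_gt=5))
        assert pr.precision[-1] == 1.0 and pr.recall[-1] == 1.0

    def test_no_ground_truth_with_detections_raises(self):
        with pytest.raises(EmptyGroundTruthError):
            precision_recall(MatchFlags(flags=[False], n_gt=0))

    def test_matches_loop_oracle_on_random_flags(self, rng):
        for _ in range(200):
            m = random_flags(rng)
            pr = precision_recall(m)
            p, r = pr_oracle(m.flags, m.n_gt)
            np.testing.assert_allclose(pr.precision, p)
            np.testing.assert_allclose(pr.recall, r)

    def test_nonmonotone_recall_rejected(self):
        with pytest.raises(ValueError):
            PRCurve(precision=[1, 1], recall=[0.5, 0.4])


class TestAveragePrecision:
    def test_perfect_curve_gives_one(self):
        pr = precision_recall(MatchFlags(flags=[True, True], n_gt=2))
        assert average_precision(pr) == pytest.approx(1.0)

    def test_all_false_positives_give_zero(self):
        pr = precision_recall(MatchFlags(flags=[False, False], n_gt=3))
        assert average_precision(pr) == 0.0

    def test_empty_curve_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert average_precision(PRCurve(np.array([]), np.array([]))) == 0.0

    def test_tp_fp_tp_example_matches_grid_integration(self):
        pr = precision_recall(MatchFlags(flags=[True, False, True], n_gt=2))
        expect = ap_grid_oracle(pr.precision, pr.recall)
        assert average_precision(pr) == pytest.approx(expect, abs=1e-3)

    def test_matches_fine_grid_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            m = random_flags(rng)
            if len(m.flags) == 0:
                continue
            pr = precision_recall(m)
            ap = average_precision(pr)
            assert 0.0 <= ap <= 1.0
            assert ap == pytest.approx(
                ap_grid_oracle(pr.precision, pr.recall, n_grid=20_000), abs=2e-3)

    def test_eleven_point_variant_bounded_by_envelope_max(self, rng):
        m = MatchFlags(flags=[True, False, True, False], n_gt=3)
        pr = precision_recall(m)
        ap11 = average_precision(pr, method="eleven_point")
        assert 0.0 <= ap11 <= 1.0

    def test_unknown_method_rejected(self):
        pr = precision_recall(MatchFlags(flags=[True], n_gt=1))
        with pytest.raises(ValueError, match="method"):
            average_precision(pr, method="voc2007ish")


class TestMeanAP:
    def test_published_per_class_values_aggregate_to_printed_means(self):
        # ten-class worked example: per-class APs -> their arithmetic mean
        assert round(mean_ap(OURS_AP), 1) == 70.1
        assert round(mean_ap(OURS_RECALL), 1) == 74.3
        assert round(mean_ap(FPN_AP), 1) == 65.2

    def test_constant_map_returns_constant(self):
        assert mean_ap({c: 100.0 for c in PEST_CLASSES}) == 100.0

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            mean_ap({})


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------

def _random_scene_boxes(rng, classes, n):
    return [Box(rng.uniform(10, 90), rng.uniform(10, 90),
                rng.uniform(4, 20), rng.uniform(4, 20),
                label=rng.choice(classes), score=float(rng.random()))
            for _ in range(n)]


class TestEvaluate:
    def test_detections_equal_ground_truth_gives_perfect_report(self):
        gts = {0: [Box(10, 10, 5, 5, label="a"), Box(30, 30, 8, 8, label="b")],
               1: [Box(20, 20, 6, 6, label="a")]}
        dets = {k: [Box(b.cx, b.cy, b.w, b.h, label=b.label, score=1.0)
                    for b in v] for k, v in gts.items()}
        rep = evaluate(dets, gts, ["a", "b"])
        assert rep.mean_ap_pct == 100.0
        assert rep.mean_recall_pct == 100.0
        assert all(m.ap_pct == 100.0 for m in rep.per_class.values())

    def test_no_detections_gives_zero(self):
        gts = {0: [Box(10, 10, 5, 5, label="a")]}
        rep = evaluate({0: []}, gts, ["a"])
        assert rep.mean_ap_pct == 0.0 and rep.mean_recall_pct == 0.0

    def test_unknown_label_rejected_with_label_in_message(self):
        gts = {0: [Box(10, 10, 5, 5, label="a")]}
        dets = {0: [Box(10, 10, 5, 5, label="zzz", score=0.5)]}
        with pytest.raises(ValueError, match="zzz"):
            evaluate(dets, gts, ["a"])

    def test_multiclass_equals_per_class_pipeline(self, rng):
        """Per-class values decompose: running one class alone matches."""
        classes = ["a", "b", "c"]
        gts, dets = {}, {}
        for img in range(4):
            gts[img] = _random_scene_boxes(rng, classes, int(rng.integers(1, 5)))
            for b in gts[img]:
                b.score = None
            dets[img] = _random_scene_boxes(rng, classes, int(rng.integers(0, 6)))
        full = evaluate(dets, gts, classes)
        for cls in classes:
            solo = evaluate(
                {k: [b for b in v if b.label == cls] for k, v in dets.items()},
                {k: [b for b in v if b.label == cls] for k, v in gts.items()},
                [cls])
            assert solo.per_class[cls].ap_pct == pytest.approx(
                full.per_class[cls].ap_pct)
            assert solo.per_class[cls].recall_pct == pytest.approx(
                full.per_class[cls].recall_pct)

    def test_mean_row_is_mean_of_columns(self, rng):
        classes = ["a", "b"]
        gts = {0: _random_scene_boxes(rng, classes, 4)}
        dets = {0: _random_scene_boxes(rng, classes, 5)}
        rep = evaluate(dets, gts, classes)
        assert rep.mean_ap_pct == pytest.approx(
            np.mean([m.ap_pct for m in rep.per_class.values()]))

    def test_report_serialises_to_csv_and_text(self, tmp_path):
        rep = EvalReport(per_class={"a": __import__(
            "maizedet.metrics", fromlist=["ClassMetrics"]).ClassMetrics(50.0, 40.0)},
            mean_recall_pct=50.0, mean_ap_pct=40.0)
        out = tmp_path / "r.csv"
        rep.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "class,recall,ap"
        assert lines[-1].startswith("Mean")
        txt = rep.to_text()
        assert "Mean" in txt and "40.0" in txt
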