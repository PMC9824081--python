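import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdtrack.geometry import BoundingBox
from herdtrack.metrics import (
    COCO_IOU_THRESHOLDS,
    ConfusionCounts,
    UndefinedMetricError,
    accumulate_mot,
    average_precision,
    count_tracked,
    extract_contacts,
    map_over,
    match_frame,
    mota,
    mot_error_ratio,
    prf,
    trajectories,
)
from herdtrack.mot_io import TrackRecord

from oracles import average_precision_bruteforce, clear_events


def _rec(frame, tid, x, y, w=10.0, h=10.0):
    return TrackRecord(frame=frame, track_id=tid, box=BoundingBox(x, y, w, h))


class TestMatchFrame:
    def test_identical_sets_all_tp(self):
        boxes = [BoundingBox(100 * i, 0, 20, 20) for i in range(5)]
        counts, pairs = match_frame(boxes, list(boxes))
        assert (counts.tp, counts.fp, counts.fn) == (5, 0, 0)
        assert len(pairs) == 5

    def test_no_predictions_all_fn(self):
        boxes = [BoundingBox(100 * i, 0, 20, 20) for i in range(3)]
        counts, _ = match_frame(boxes, [])
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 3)

    def test_below_threshold_overlap_not_matched(self):
        gt = [BoundingBox(0, 0, 2, 2), BoundingBox(10, 10, 2, 2)]
        pred = [BoundingBox(1, 0, 2, 2)]  # IoU 1/3 < 0.5
        counts, _ = match_frame(gt, pred, iou_threshold=0.5)
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 2)

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_count_conservation(self, seed):
        rng = np.random.default_rng(seed)
        gt = [BoundingBox(*rng.uniform(0, 300, 2), *rng.uniform(5, 40, 2))
              for _ in range(rng.integers(0, 8))]
        pred = [BoundingBox(*rng.uniform(0, 300, 2), *rng.uniform(5, 40, 2))
                for _ in range(rng.integers(0, 8))]
        counts, _ = match_frame(gt, pred)
        assert counts.tp + counts.fn == len(gt)
        assert counts.tp + counts.fp == len(pred)


class TestPrf:
    def test_hand_values(self):
        p, r, f1 = prf(ConfusionCounts(tp=8, fp=2, fn=2))
        assert (p, r, f1) == (0.8, 0.8, 0.8)

    def test_perfect(self):
        assert prf(ConfusionCounts(tp=5, fp=0, fn=0)) == (1.0, 1.0, 1.0)

    def test_undefined_recall_flagged(self):
        with pytest.raises(UndefinedMetricError):
            prf(ConfusionCounts(tp=0, fp=3, fn=0))

    @settings(deadline=None, max_examples=100)
    @given(tp=st.integers(1, 100), fp=st.integers(0, 100),
           fn=st.integers(0, 100))
    def test_f1_harmonic_identity(self, tp, fp, fn):
        p, r, f1 = prf(ConfusionCounts(tp=tp, fp=fp, fn=fn))
        assert f1 == pytest.approx(2 * p * r / (p + r))


class TestAveragePrecision:
    def test_all_correct_is_one(self):
        gt = [(1, BoundingBox(100 * i, 0, 20, 20)) for i in range(4)]
        preds = [(1, b, c) for (_, b), c in zip(gt, [0.9, 0.2, 0.5, 0.7])]
        assert average_precision(preds, gt) == pytest.approx(1.0)

    def test_ranked_mixture_matches_bruteforce_pr_summation(self):
        # 5 GT; prediction ranking TP,FP,TP,TP,FP
        gt = [(1, BoundingBox(100 * i, 0, 20, 20)) for i in range(5)]
        preds = [
            (1, BoundingBox(0, 0, 20, 20), 0.95),      # TP
            (1, BoundingBox(900, 900, 20, 20), 0.90),  # FP
            (1, BoundingBox(100, 0, 20, 20), 0.85),    # TP
            (1, BoundingBox(200, 0, 20, 20), 0.80),    # TP
            (1, BoundingBox(950, 950, 20, 20), 0.75),  # FP
        ]
        expected = average_precision_bruteforce(
            [True, False, True, True, False], n_gt=5
        )
        assert average_precision(preds, gt) == pytest.approx(expected)

    def test_confidence_rescaling_invariance(self):
        gt = [(1, BoundingBox(100 * i, 0, 20, 20)) for i in range(3)]
        preds = [
            (1, BoundingBox(0, 0, 20, 20), 0.9),
            (1, BoundingBox(500, 500, 20, 20), 0.6),
            (1, BoundingBox(100, 0, 20, 20), 0.3),
        ]
        scaled = [(f, b, c * 0.1) for f, b, c in preds]
        assert average_precision(preds, gt) == pytest.approx(
            average_precision(scaled, gt)
        )

    def test_map_single_class_equals_ap(self):
        gt = {"cattle": [(1, BoundingBox(100 * i, 0, 20, 20))
                         for i in range(3)]}
        preds = {"cattle": [(1, b, 0.9) for _, b in gt["cattle"]]}
        m, per_class = map_over(preds, gt, iou_thresholds=[0.5])
        assert m == pytest.approx(per_class["cattle"])
        assert m == pytest.approx(1.0)

    def test_coco_grid_has_ten_thresholds(self):
        assert len(COCO_IOU_THRESHOLDS) == 10
        assert COCO_IOU_THRESHOLDS[0] == 0.5
        assert COCO_IOU_THRESHOLDS[-1] == 0.95

    def test_class_without_gt_excluded_with_warning(self):
        gt = {"cattle": [(1, BoundingBox(0, 0, 20, 20))]}
        preds = {
            "cattle": [(1, BoundingBox(0, 0, 20, 20), 0.9)],
            "dog": [(1, BoundingBox(50, 50, 20, 20), 0.9)],
        }
        with pytest.warns(UserWarning):
            m, per_class = map_over(preds, gt, iou_thresholds=[0.5])
        assert set(per_class) == {"cattle"}


class TestAccumulateMot:
    def test_perfect_tracking(self, walk_gt):
        gt = walk_gt(k=3, n_frames=20)
        log = accumulate_mot(gt, gt)
        assert log.total_fn == log.total_fp == log.total_idsw == 0
        assert mota(log) == 1.0

    def test_swapped_ids_from_frame_50_two_switches(self, walk_gt):
        gt = walk_gt(k=2, n_frames=100)
        pred = [
            TrackRecord(
                frame=r.frame,
                track_id=(3 - r.track_id if r.frame >= 50 else r.track_id),
                box=r.box,
            )
            for r in gt
        ]
        log = accumulate_mot(gt, pred)
        assert log.total_idsw == 2
        assert log.total_fn == 0 and log.total_fp == 0

    def test_coverage_gap_is_fragmentation_not_switch(self, walk_gt):
        gt = walk_gt(k=1, n_frames=30)
        pred = [r for r in gt if not (10 <= r.frame <= 19)]
        log = accumulate_mot(gt, pred)
        assert log.fragmentations == 1
        assert log.total_idsw == 0
        assert log.total_fn == 10

    def test_duplicate_gt_ids_rejected(self):
        gt = [_rec(1, 1, 0, 0), _rec(1, 1, 50, 0)]
        with pytest.raises(ValueError):
            accumulate_mot(gt, [])

    def test_mota_hand_values(self):
        log = accumulate_mot([], [])
        log.fn, log.fp, log.idsw, log.gt = [2], [1], [1], [100]
        assert mota(log) == pytest.approx(0.96)
        assert mot_error_ratio(log) == pytest.approx(0.04)
        log.gt = [128]
        assert mota(log) == pytest.approx(0.96875)

    def test_mota_undefined_without_gt(self):
        with pytest.raises(UndefinedMetricError):
            mota(accumulate_mot([], []))

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_bruteforce_event_counter(self, seed):
        """Random small scenarios: totals agree exactly with the
        independent brute-force CLEAR counter."""
        rng = np.random.default_rng(seed)
        n_ids, n_frames = int(rng.integers(1, 5)), int(rng.integers(5, 30))
        gt, pred = [], []
        for tid in range(1, n_ids + 1):
            x0, y0 = rng.uniform(0, 500, 2)
            vx, vy = rng.uniform(-4, 4, 2)
            pid = int(tid + rng.integers(0, 2) * 10)
            for f in range(1, n_frames + 1):
                box = BoundingBox(x0 + vx * f, y0 + vy * f, 30, 25)
                gt.append(TrackRecord(frame=f, track_id=tid, box=box))
                if rng.random() < 0.85:
                    if rng.random() < 0.03:
                        pid = int(tid + rng.integers(0, 5) * 10)
                    jx, jy = rng.normal(0, 1.5, 2)
                    pred.append(
                        TrackRecord(
                            frame=f, track_id=pid,
                            box=BoundingBox(box.x + jx, box.y + jy, 30, 25),
                        )
                    )
        log = accumulate_mot(gt, pred)
        ref = clear_events(
            [(r.frame, r.track_id, *r.box.as_tuple()) for r in gt],
            [(r.frame, r.track_id, *r.box.as_tuple()) for r in pred],
        )
        assert log.total_fn == ref["fn"]
        assert log.total_fp == ref["fp"]
        assert log.total_idsw == ref["idsw"]
        assert log.fragmentations == ref["frag"]
        assert mota(log) == pytest.approx(ref["mota"], abs=1e-9)


class TestSummaries:
    def test_count_tracked_empty(self):
        assert count_tracked([]) == 0

    def test_count_tracked_thresholds(self, walk_gt):
        recs = walk_gt(k=20, n_frames=50, spacing=80)
        recs += [_rec(1, 99, 5000, 5000), _rec(2, 99, 5000, 5000)]
        assert count_tracked(recs, min_length=25) == 20

    def test_contacts_parallel_distant_tracks_none(self, walk_gt):
        recs = walk_gt(k=2, n_frames=60, spacing=500)
        assert extract_contacts(recs, distance_threshold=100) == []

    def test_contact_interval_extraction(self):
        recs = []
        for f in range(1, 81):
            recs.append(_rec(f, 1, 100, 100))
            # id 2 approaches for frames 21..60, then leaves
            x = 100 if 21 <= f <= 60 else 2000
            recs.append(_rec(f, 2, x, 130))
        contacts = extract_contacts(recs, distance_threshold=50,
                                    min_duration=25)
        assert contacts == [(1, 2, 21, 60)]

    def test_contacts_threshold_zero_none(self, walk_gt):
        recs = walk_gt(k=2, n_frames=30, spacing=0)
        assert extract_contacts(recs, 0.0) == []

    def test_short_contact_filtered(self):
        recs = []
        for f in range(1, 31):
            recs.append(_rec(f, 1, 100, 100))
            recs.append(_rec(f, 2, 100 if f <= 10 else 2000, 120))
        assert extract_contacts(recs, 60, min_duration=25) == []

    def test_trajectories_polyline(self, walk_gt):
        recs = walk_gt(k=2, n_frames=5)
        polys = trajectories(recs)
        assert set(polys) == {1, 2}
        frames = [f for f, _, _ in polys[1]]
        assert frames == [1, 2, 3, 4, 5]
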