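import numpy as np
import pytest

from herdtrack.geometry import BoundingBox
from herdtrack.kalman import KalmanBoxFilter, box_to_state, state_to_box
from herdtrack.mot_io import Detection
from herdtrack.sort import (
    KalmanTrack,
    SortConfig,
    SortTracker,
    TrackState,
    associate,
    run_sort,
)


def _det(frame, x, y, w=60.0, h=40.0):
    return Detection(frame=frame, box=BoundingBox(x, y, w, h))


def _one_hot(dim, i):
    v = np.zeros(dim)
    v[i] = 1.0
    return v


class TestKalman:
    def test_zero_velocity_prediction_keeps_box(self):
        kf = KalmanBoxFilter()
        box = BoundingBox(100, 100, 60, 40)
        mean, cov = kf.initiate(box_to_state(box))
        mean, cov = kf.predict(mean, cov)
        pred = state_to_box(mean)
        assert pred.as_tuple() == pytest.approx(box.as_tuple())

    def test_constant_velocity_is_learned(self):
        """Exact 1 px/frame measurements teach the filter the velocity:
        the prediction overshoots the last measurement and approaches
        the true next position."""
        kf = KalmanBoxFilter()
        mean, cov = kf.initiate(box_to_state(BoundingBox(0, 100, 60, 40)))
        for i in range(1, 6):
            mean, cov = kf.predict(mean, cov)
            mean, cov = kf.update(
                mean, cov, box_to_state(BoundingBox(float(i), 100, 60, 40))
            )
        mean, cov = kf.predict(mean, cov)
        pred = state_to_box(mean)
        assert 5.0 < pred.x <= 6.0 + 1e-9
        assert pred.x == pytest.approx(6.0, abs=0.5)

    def test_update_matches_textbook_kalman_equations(self):
        """One predict/update cycle agrees with the generic
        linear-Gaussian equations evaluated directly with numpy."""
        from herdtrack.kalman import (
            STD_WEIGHT_POSITION as wp,
            STD_WEIGHT_VELOCITY as wv,
        )

        kf = KalmanBoxFilter()
        z0 = box_to_state(BoundingBox(0, 100, 60, 40))
        z1 = box_to_state(BoundingBox(1, 100, 60, 40))
        mean, cov = kf.initiate(z0)
        mean, cov = kf.predict(mean, cov)
        got_mean, got_cov = kf.update(mean, cov, z1)

        # independent evaluation of x' = x + K(z - Hx), P' = P - K S K^T
        H = np.eye(4, 8)
        h = mean[3]
        R = np.diag(np.square([wp * h, wp * h, 1e-1, wp * h]))
        S = H @ cov @ H.T + R
        K = cov @ H.T @ np.linalg.inv(S)
        exp_mean = mean + K @ (z1 - H @ mean)
        exp_cov = cov - K @ S @ K.T
        assert got_mean == pytest.approx(exp_mean)
        assert got_cov == pytest.approx(exp_cov)

    def test_covariance_grows_without_update(self):
        kf = KalmanBoxFilter()
        mean, cov = kf.initiate(box_to_state(BoundingBox(0, 0, 60, 40)))
        traces = []
        for _ in range(5):
            mean, cov = kf.predict(mean, cov)
            traces.append(np.trace(cov))
        assert all(b > a for a, b in zip(traces, traces[1:]))

    def test_update_with_predicted_measurement_keeps_mean(self):
        kf = KalmanBoxFilter()
        mean, cov = kf.initiate(box_to_state(BoundingBox(50, 50, 60, 40)))
        mean, cov = kf.predict(mean, cov)
        meas = mean[:4].copy()
        new_mean, new_cov = kf.update(mean, cov, meas)
        assert new_mean[:4] == pytest.approx(mean[:4])
        # measured components become more certain
        assert np.trace(new_cov[:4, :4]) < np.trace(cov[:4, :4])

    def test_repeated_identical_measurements_converge(self):
        kf = KalmanBoxFilter()
        target = box_to_state(BoundingBox(300, 200, 80, 50))
        mean, cov = kf.initiate(box_to_state(BoundingBox(280, 190, 70, 45)))
        for _ in range(50):
            mean, cov = kf.predict(mean, cov)
            mean, cov = kf.update(mean, cov, target)
        assert mean[:4] == pytest.approx(target, rel=1e-3)


class TestAssociate:
    def test_gallery_member_matches_at_zero_distance(self):
        cfg = SortConfig()
        kf = KalmanBoxFilter()
        emb = _one_hot(4, 0)
        tr = KalmanTrack(1, _det(1, 100, 100), kf, cfg, emb)
        assert tr.state is TrackState.CONFIRMED
        matches, _, _ = associate([tr], [_det(2, 100, 100)], [emb], cfg)
        assert matches == [(0, 0)]
        assert tr.appearance_distance(emb) == pytest.approx(0.0)

    def test_appearance_distance_above_gate_forbidden_in_stage1(self):
        """Orthogonal embeddings (cosine distance 1 > 0.9) cannot match by
        appearance, but stage 2 IoU still links overlapping boxes."""
        cfg = SortConfig(max_dist=0.9)
        kf = KalmanBoxFilter()
        tr = KalmanTrack(1, _det(1, 100, 100), kf, cfg, _one_hot(4, 0))
        far_emb = _one_hot(4, 1)
        # same box: stage 2 rescues; distant box: nothing matches
        matches, _, _ = associate([tr], [_det(2, 100, 100)], [far_emb], cfg)
        assert matches == [(0, 0)]
        matches, un_t, un_d = associate(
            [tr], [_det(2, 2000, 2000)], [far_emb], cfg
        )
        assert not matches and un_t == [0] and un_d == [0]

    def test_iou_distance_above_gate_forbidden_in_stage2(self):
        cfg = SortConfig(max_iou_distance=0.8)
        kf = KalmanBoxFilter()
        tr = KalmanTrack(1, _det(1, 0, 0, 10, 10), kf, cfg)
        # overlap 1x10 / union 190: IoU ~0.053, distance ~0.947 > 0.8
        matches, un_t, un_d = associate(
            [tr], [_det(2, 9, 0, 10, 10)], None, cfg
        )
        assert not matches

    def test_embedding_dim_mismatch_rejected(self):
        cfg = SortConfig()
        tr = KalmanTrack(1, _det(1, 0, 0), KalmanBoxFilter(), cfg, _one_hot(4, 0))
        with pytest.raises(ValueError):
            tr.appearance_distance(np.zeros(7))


class TestLifecycle:
    def test_confirm_on_first_match_with_n_init_1(self):
        cfg = SortConfig(n_init=1)
        tr = KalmanTrack(1, _det(1, 0, 0), KalmanBoxFilter(), cfg)
        assert tr.state is TrackState.CONFIRMED

    def test_tentative_unmatched_is_dropped(self):
        cfg = SortConfig(n_init=3)
        tr = KalmanTrack(1, _det(1, 0, 0), KalmanBoxFilter(), cfg)
        assert tr.state is TrackState.TENTATIVE
        tr.predict()
        tr.mark_missed()
        assert tr.state is TrackState.DELETED

    def test_max_age_boundary(self):
        cfg = SortConfig(max_age=1500)
        tr = KalmanTrack(1, _det(1, 0, 0), KalmanBoxFilter(), cfg)
        for _ in range(1500):
            tr.predict()
            tr.mark_missed()
        assert tr.state is TrackState.CONFIRMED  # exactly at the limit: kept
        tr.predict()
        tr.mark_missed()
        assert tr.state is TrackState.DELETED  # limit + 1: deleted

    def test_deleted_is_terminal(self):
        cfg = SortConfig(n_init=2)
        tr = KalmanTrack(1, _det(1, 0, 0), KalmanBoxFilter(), cfg)
        tr.predict()
        tr.mark_missed()
        with pytest.raises(ValueError):
            tr.update(_det(2, 0, 0))
        with pytest.raises(ValueError):
            tr.mark_missed()

    def test_gallery_fifo_eviction_at_budget(self):
        cfg = SortConfig(nn_budget=100)
        kf = KalmanBoxFilter()
        tr = KalmanTrack(1, _det(1, 0, 0), kf, cfg, np.full(4, 0.0))
        for i in range(1, 120):
            tr.predict()
            tr.update(_det(i + 1, 0, 0), np.full(4, float(i)))
        assert len(tr.gallery) == 100
        # 120 embeddings total (initial + i=1..119): survivors are 20..119
        assert tr.gallery[0][0] == pytest.approx(20.0)
        assert tr.gallery[-1][0] == pytest.approx(119.0)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SortConfig(max_dist=0.0)
        with pytest.raises(ValueError):
            SortConfig(max_age=0)


class TestRunSort:
    def test_empty_sequence(self):
        assert run_sort([]) == []

    def test_single_target_single_constant_id(self, walk_detections):
        recs = run_sort(walk_detections(k=1, n_frames=40))
        assert {r.track_id for r in recs} == {1}
        assert len(recs) == 40

    def test_deterministic(self, walk_detections):
        dets = walk_detections(k=3, n_frames=50)
        assert run_sort(dets) == run_sort(list(dets))

    def test_perfectly_discriminative_embeddings_prevent_switches(self):
        """Two targets cross with a detection gap; one-hot identity
        embeddings yield zero switches."""
        from herdtrack.metrics import evaluate_tracking
        from herdtrack.simulate import crossing_scenario

        sc = crossing_scenario(seed=11)
        # one-hot embedding keyed by which ground-truth box the detection
        # overlaps most (a stand-in for a perfect appearance model)
        def perfect_embedder(det):
            from herdtrack.geometry import iou as biou

            best, best_o = 0, -1.0
            for rec in sc.gt_frame(det.frame):
                o = biou(rec.box, det.box)
                if o > best_o:
                    best_o, best = o, rec.track_id
            return _one_hot(8, best)

        recs = run_sort(sc.detections, embedder=perfect_embedder,
                        n_frames=sc.config.n_frames)
        rep = evaluate_tracking(sc.gt_tracks, recs)
        assert rep.idsw == 0
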