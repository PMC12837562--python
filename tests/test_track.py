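import itertools

import numpy as np
import pytest

from spermtrack.core import BoundingBox, Detection
from spermtrack.simulate import GroundTruthDetector
from spermtrack.track import (
    KalmanFilter,
    Tracker,
    TrackerConfig,
    TrackStatus,
    appearance_feature,
    cosine_gallery_distance,
    matching_cascade,
    predict,
    solve_assignment,
    track_video,
    update,
)


def _measurement(cx, cy, a, h):
    return np.array([cx, cy, a, h], dtype=float)


class TestKalman:
    def test_constant_velocity_exact_with_zero_noise(self):
        kf = KalmanFilter(std_weight_position=0, std_weight_velocity=0)
        st = kf.initiate(_measurement(10, 20, 1, 8))
        st.mean[4:8] = [1, 0, 0, 0]
        for k in range(1, 6):
            st = kf.predict(st)
            assert st.mean[:2] == pytest.approx([10 + k, 20])

    def test_covariance_grows_under_prediction(self):
        kf = KalmanFilter()
        st = kf.initiate(_measurement(0, 0, 1, 10))
        for _ in range(5):
            before = np.trace(st.covariance)
            st = kf.predict(st)
            assert np.trace(st.covariance) >= before

    def test_update_with_predicted_measurement_keeps_mean(self):
        kf = KalmanFilter()
        st = kf.initiate(_measurement(5, 5, 1, 10))
        post = kf.update(st, _measurement(5, 5, 1, 10))
        assert post.mean[:4] == pytest.approx([5, 5, 1, 10])

    def test_scalar_closed_form(self):
        """The cx component follows the textbook 1-D Bayesian update."""
        kf = KalmanFilter()
        st = kf.initiate(_measurement(0, 0, 1, 10))
        P = st.covariance[0, 0]
        R = kf._measurement_noise(st.mean)[0, 0]
        post = kf.update(st, _measurement(3, 0, 1, 10))
        assert post.mean[0] == pytest.approx(P / (P + R) * 3.0)

    def test_posterior_variance_not_larger(self):
        kf = KalmanFilter()
        st = kf.initiate(_measurement(0, 0, 1, 10))
        st = kf.predict(st)
        post = kf.update(st, _measurement(1, -1, 1, 11))
        for i in range(4):
            assert post.covariance[i, i] <= st.covariance[i, i] + 1e-12

    def test_module_level_wrappers(self):
        kf = KalmanFilter()
        st = kf.initiate(_measurement(4, 4, 1, 8))
        assert predict(st).mean[:2] == pytest.approx([4, 4])
        assert update(st, BoundingBox(0, 0, 8, 8)).mean[3] > 0


class TestAppearance:
    def test_unit_norm(self, rng):
        frame = rng.random((60, 60))
        f = appearance_feature(frame, BoundingBox(10, 10, 40, 40))
        assert np.linalg.norm(f) == pytest.approx(1.0, abs=1e-9)

    def test_identical_crops_zero_distance(self, rng):
        frame = rng.random((60, 60))
        box = BoundingBox(5, 5, 30, 30)
        f1 = appearance_feature(frame, box)
        f2 = appearance_feature(frame, box)
        assert cosine_gallery_distance(f1, [f2]) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_changes_feature(self, rng):
        patch = rng.random((32, 32))
        frame = np.zeros((64, 64))
        frame[:32, :32] = patch
        frame[:32, 32:] = np.rot90(patch)
        f1 = appearance_feature(frame, BoundingBox(0, 0, 32, 32))
        f2 = appearance_feature(frame, BoundingBox(32, 0, 64, 32))
        assert cosine_gallery_distance(f1, [f2]) > 0.01

    def test_empty_gallery_error(self):
        with pytest.raises(ValueError):
            cosine_gallery_distance(np.ones(4) / 2, [])

    def test_orthogonal_distance_one(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        assert cosine_gallery_distance(a, [b]) == pytest.approx(1.0)


class TestAssignment:
    def test_small_example(self):
        pairs = solve_assignment(np.array([[1.0, 2.0], [3.0, 1.0]]))
        assert sorted(pairs) == [(0, 0), (1, 1)]

    def test_diagonal_preference(self):
        c = np.full((4, 4), 10.0) - 9 * np.eye(4)
        assert sorted(solve_assignment(c)) == [(i, i) for i in range(4)]

    def test_matches_brute_force(self, rng):
        for _ in range(60):
            n, m = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            c = rng.random((n, m))
            cost = sum(c[r, col] for r, col in solve_assignment(c))
            k = min(n, m)
            best = min(
                sum(c[r, col] for r, col in zip(rows, cols))
                for rows in itertools.combinations(range(n), k)
                for cols in itertools.permutations(range(m), k)
            )
            assert cost == pytest.approx(best)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            solve_assignment(np.array([[np.inf, 1.0]]))


def _run_detections(tracker, frame, boxes, n):
    out = None
    for _ in range(n):
        out = tracker.step([Detection(box=b, confidence=1.0) for b in boxes], frame)
    return out


class TestLifecycle:
    def test_empty_stream_no_tracks(self):
        tracker = Tracker()
        frame = np.zeros((50, 50), dtype=np.uint8)
        for _ in range(10):
            assert tracker.step([], frame) == []

    def test_confirmation_after_n_init(self):
        frame = np.zeros((50, 50), dtype=np.uint8)
        frame[10:20, 10:20] = 255
        tracker = Tracker(TrackerConfig(n_init=3))
        box = BoundingBox(10, 10, 20, 20)
        assert _run_detections(tracker, frame, [box], 2) == []
        confirmed = _run_detections(tracker, frame, [box], 1)
        assert len(confirmed) == 1 and confirmed[0].status is TrackStatus.CONFIRMED

    def test_ids_never_reused(self):
        frame = np.zeros((50, 50), dtype=np.uint8)
        tracker = Tracker(TrackerConfig(n_init=1))
        b1 = BoundingBox(5, 5, 15, 15)
        tracker.step([Detection(box=b1, confidence=1.0)], frame)
        first_id = tracker.tracks[0].track_id
        # lose it long enough to delete, then a new object appears
        for _ in range(tracker.config.max_age + 2):
            tracker.step([], frame)
        tracker.step([Detection(box=b1, confidence=1.0)], frame)
        assert tracker.tracks[0].track_id > first_id

    def test_reassociation_within_max_age(self):
        frame = np.zeros((80, 80), dtype=np.uint8)
        frame[30:40, 30:50] = 200
        box = BoundingBox(30, 30, 50, 40)
        tracker = Tracker(TrackerConfig(max_age=30))
        for _ in range(5):
            tracker.step([Detection(box=box, confidence=1.0)], frame)
        tid = tracker.tracks[0].track_id
        for _ in range(10):  # occluded < max_age
            tracker.step([], frame)
        out = tracker.step([Detection(box=box, confidence=1.0)], frame)
        assert [t.track_id for t in out] == [tid]

    def test_gated_out_detection_unmatched(self):
        frame = np.zeros((200, 200), dtype=np.uint8)
        tracker = Tracker(TrackerConfig(n_init=1))
        near = BoundingBox(10, 10, 20, 20)
        far = BoundingBox(150, 150, 160, 160)
        tracker.step([Detection(box=near, confidence=1.0)], frame)
        tracker.step([Detection(box=near, confidence=1.0)], frame)
        matches, _, unmatched_d = matching_cascade(
            tracker.tracks, [Detection(box=far, confidence=1.0)], frame, tracker.config
        )
        assert matches == [] and unmatched_d == [0]

    def test_cascade_prefers_recent_track(self):
        """Two tracks gate the same detection; the one seen more recently
        wins the cascade level-by-level."""
        frame = np.zeros((100, 100), dtype=np.uint8)
        frame[20:30, 20:30] = 180
        box = BoundingBox(20, 20, 30, 30)
        tracker = Tracker(TrackerConfig(n_init=1, max_cosine_distance=2.0))
        # track A observed throughout; track B missed for a while
        tracker.step([Detection(box=box, confidence=1.0),
                      Detection(box=BoundingBox(21, 21, 31, 31), confidence=0.9)], frame)
        ids = sorted(t.track_id for t in tracker.tracks)
        for _ in range(4):  # only the first box keeps being detected
            tracker.step([Detection(box=box, confidence=1.0)], frame)
        fresh = [t for t in tracker.tracks if t.time_since_update == 1]
        stale = [t for t in tracker.tracks if t.time_since_update > 1]
        if fresh and stale:  # the surviving fresh track must be the match
            matches, _, _ = matching_cascade(
                tracker.tracks, [Detection(box=box, confidence=1.0)], frame, tracker.config
            )
            matched_track = tracker.tracks[matches[0][0]]
            assert matched_track.time_since_update == 1


class TestTrackVideo:
    def test_perfect_detector_one_trajectory_per_sperm(self, clean_scene):
        video, gt = clean_scene
        trajs, rows = track_video(video, GroundTruthDetector(gt))
        assert len(trajs) == len(gt.trajectories)
        # confirmed from frame n_init-1 onward -> length n_frames - 2
        for tr in trajs.values():
            assert tr.times.size == len(video) - 2
            assert tr.observed.all()

    def test_two_separated_swimmers_no_switches(self, clean_scene):
        from spermtrack.evaluate import tracking_consistency

        video, gt = clean_scene
        _, rows = track_video(video, GroundTruthDetector(gt))
        pred = {}
        for r in rows:
            pred.setdefault(r.frame, []).append((r.track_id, r.box))
        truth = {a.frame_index: a.boxes for a in gt.annotations}
        assert tracking_consistency(pred, truth, 0.45).id_switches == 0

    def test_duplicate_boxes_may_double_track(self):
        """A detector emitting duplicate boxes for one object can spawn a
        second track — the documented double-rectangle failure mode."""
        frame = np.zeros((80, 80), dtype=np.uint8)
        frame[30:40, 30:50] = 200
        box = BoundingBox(30, 30, 50, 40)
        dup = BoundingBox(31, 29, 51, 41)

        def detector(f):
            return [Detection(box=box, confidence=1.0), Detection(box=dup, confidence=0.9)]

        from spermtrack.core import CalibrationProfile, VideoSequence

        video = VideoSequence(frames=[frame] * 10, calibration=CalibrationProfile(0.28, 10))
        trajs, _ = track_video(video, detector)
        assert len(trajs) >= 2
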