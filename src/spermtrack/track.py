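"""Online multi-object tracking of detected sperm (SORT/DeepSORT style).

Each track holds a constant-velocity Kalman filter over the box state
``(cx, cy, a, h)`` — center, aspect ratio w/h, height — plus velocities,
and a bounded gallery of appearance features from the frames where it was
matched.  Each new frame is associated to existing tracks by a *matching
cascade*: tracks are visited in order of how recently they were last seen,
and at each level a Hungarian assignment is solved on appearance (cosine)
cost, gated by the Mahalanobis distance of the predicted state.  Remaining
unconfirmed and just-missed tracks get a second chance through plain IoU
association.  Unmatched detections spawn tentative tracks, which are
confirmed after ``n_init`` consecutive hits; tracks unseen for more than
``max_age`` frames are deleted.  Track ids are never reused.

The appearance descriptor is a classical orientation-binned gradient
histogram (4x4 cells x 8 orientation bins, L2-normalized) computed on the
resized box crop.  Nearly stationary, low-texture sperm do not call for a
learned re-identification embedding; any feature extractor with the same
signature can be plugged in.

Nothing here is trained: identity preservation rests on motion gating,
appearance similarity, and the recency-ordered cascade.
"""

from __future__ import annotations

import enum
import inspect
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
from skimage.transform import resize

from .core import BoundingBox, CalibrationProfile, Detection, TrackRow, VideoSequence, iou
from .kinematics import Trajectory

__all__ = [
    "KalmanState",
    "KalmanFilter",
    "TrackStatus",
    "TrackState",
    "TrackerConfig",
    "predict",
    "update",
    "appearance_feature",
    "cosine_gallery_distance",
    "solve_assignment",
    "matching_cascade",
    "Tracker",
    "track_video",
]

# chi-square 0.95 quantile for 4 degrees of freedom: Mahalanobis gate on
# the 4-D box measurement
CHI2_GATE_4DOF = 9.4877

_INF_COST = 1e5


@dataclass
class KalmanState:
    """Gaussian state: 8-vector mean (cx, cy, a, h + velocities), 8x8 covariance."""

    mean: np.ndarray
    covariance: np.ndarray

    def box(self) -> BoundingBox:
        cx, cy, a, h = self.mean[:4]
        w = a * h
        return BoundingBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def _box_to_measurement(box: BoundingBox) -> np.ndarray:
    h = box.height
    a = box.width / h if h > 0 else 0.0
    cx, cy = box.center
    return np.array([cx, cy, a, h], dtype=float)


class KalmanFilter:
    """Constant-velocity Kalman filter on (cx, cy, a, h).

    Process and measurement noise are scaled to the box height, following
    the convention of the tracker family this module implements; the
    weights are exposed so tests can zero the process noise and check the
    exact linear prediction.
    """

    def __init__(
        self,
        std_weight_position: float = 1.0 / 20,
        std_weight_velocity: float = 1.0 / 160,
    ):
        self.std_weight_position = std_weight_position
        self.std_weight_velocity = std_weight_velocity
        self._F = np.eye(8)
        for i in range(4):
            self._F[i, 4 + i] = 1.0
        self._H = np.eye(4, 8)

    def initiate(self, measurement: np.ndarray) -> KalmanState:
        mean = np.zeros(8)
        mean[:4] = measurement
        h = max(measurement[3], 1e-6)
        std = [
            2 * self.std_weight_position * h,
            2 * self.std_weight_position * h,
            1e-2,
            2 * self.std_weight_position * h,
            10 * self.std_weight_velocity * h,
            10 * self.std_weight_velocity * h,
            1e-5,
            10 * self.std_weight_velocity * h,
        ]
        return KalmanState(mean=mean, covariance=np.diag(np.square(std)))

    def _process_noise(self, mean: np.ndarray) -> np.ndarray:
        h = max(abs(mean[3]), 1e-6)
        std = [
            self.std_weight_position * h,
            self.std_weight_position * h,
            1e-2,
            self.std_weight_position * h,
            self.std_weight_velocity * h,
            self.std_weight_velocity * h,
            1e-5,
            self.std_weight_velocity * h,
        ]
        return np.diag(np.square(std))

    def _measurement_noise(self, mean: np.ndarray) -> np.ndarray:
        h = max(abs(mean[3]), 1e-6)
        std = [
            self.std_weight_position * h,
            self.std_weight_position * h,
            1e-1,
            self.std_weight_position * h,
        ]
        return np.diag(np.square(std))

    def predict(self, state: KalmanState) -> KalmanState:
        mean = self._F @ state.mean
        cov = self._F @ state.covariance @ self._F.T + self._process_noise(state.mean)
        return KalmanState(mean=mean, covariance=cov)

    def project(self, state: KalmanState) -> tuple[np.ndarray, np.ndarray]:
        mean = self._H @ state.mean
        S = self._H @ state.covariance @ self._H.T + self._measurement_noise(state.mean)
        return mean, S

    def update(self, state: KalmanState, measurement: np.ndarray) -> KalmanState:
        proj_mean, S = self.project(state)
        K = scipy.linalg.solve(S.T, (state.covariance @ self._H.T).T, assume_a="pos").T
        innovation = measurement - proj_mean
        mean = state.mean + K @ innovation
        cov = state.covariance - K @ S @ K.T
        cov = 0.5 * (cov + cov.T)  # keep symmetric
        return KalmanState(mean=mean, covariance=cov)

    def gating_distance(self, state: KalmanState, measurements: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each measurement row to the
        projected state distribution."""
        mean, S = self.project(state)
        L = np.linalg.cholesky(S)
        d = np.atleast_2d(measurements) - mean
        z = scipy.linalg.solve_triangular(L, d.T, lower=True)
        return np.sum(z * z, axis=0)


_DEFAULT_KF = KalmanFilter()


def predict(state: KalmanState, kf: KalmanFilter | None = None) -> KalmanState:
    """Constant-velocity prediction step."""
    return (kf or _DEFAULT_KF).predict(state)


def update(state: KalmanState, box: BoundingBox, kf: KalmanFilter | None = None) -> KalmanState:
    """Measurement update with a detected box."""
    return (kf or _DEFAULT_KF).update(state, _box_to_measurement(box))


# ---------------------------------------------------------------------------
# Appearance


def appearance_feature(
    frame: np.ndarray, box: BoundingBox, grid: int = 4, bins: int = 8, crop_size: int = 32
) -> np.ndarray:
    """Orientation-binned gradient histogram of the box crop, L2-normalized.

    The crop is resized to ``crop_size`` squared, gradients are binned by
    unsigned orientation into ``bins`` bins over a ``grid x grid`` cell
    layout, and the concatenated histogram is normalized to unit length.
    A featureless crop returns the uniform unit vector.
    """
    f = np.asarray(frame, dtype=float)
    x0 = int(np.clip(math.floor(box.x_min), 0, f.shape[1] - 1))
    x1 = int(np.clip(math.ceil(box.x_max), x0 + 1, f.shape[1]))
    y0 = int(np.clip(math.floor(box.y_min), 0, f.shape[0] - 1))
    y1 = int(np.clip(math.ceil(box.y_max), y0 + 1, f.shape[0]))
    crop = f[y0:y1, x0:x1]
    crop = resize(crop, (crop_size, crop_size), anti_aliasing=True, mode="reflect")
    gy, gx = np.gradient(crop)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)
    bin_idx = np.minimum((ang / np.pi * bins).astype(int), bins - 1)
    cell = crop_size // grid
    feat = np.zeros(grid * grid * bins)
    for cy in range(grid):
        for cx in range(grid):
            sl = (slice(cy * cell, (cy + 1) * cell), slice(cx * cell, (cx + 1) * cell))
            feat[(cy * grid + cx) * bins : (cy * grid + cx + 1) * bins] = np.bincount(
                bin_idx[sl].ravel(), weights=mag[sl].ravel(), minlength=bins
            )
    norm = np.linalg.norm(feat)
    if norm < 1e-12:
        return np.full(feat.size, 1.0 / math.sqrt(feat.size))
    return feat / norm


def cosine_gallery_distance(feature: np.ndarray, gallery: Sequence[np.ndarray]) -> float:
    """Minimum cosine distance (1 - dot) between a feature and a gallery of
    unit-norm features; an empty gallery is an error."""
    if len(gallery) == 0:
        raise ValueError("empty appearance gallery")
    sims = np.asarray(gallery) @ np.asarray(feature)
    return float(1.0 - sims.max())


# ---------------------------------------------------------------------------
# Assignment


def solve_assignment(cost: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-cost one-to-one assignment (Hungarian algorithm).

    Works for rectangular matrices; rows/columns beyond the smaller
    dimension stay unassigned.  Costs must be finite — callers encode
    gated-out pairs with a large sentinel and drop them afterwards.
    """
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    if cost.size == 0:
        return []
    if not np.all(np.isfinite(cost)):
        raise ValueError("assignment costs must be finite")
    rows, cols = scipy.optimize.linear_sum_assignment(cost)
    return list(zip(rows.tolist(), cols.tolist()))


# ---------------------------------------------------------------------------
# Tracks


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class TrackState:
    """One tracked sperm: Kalman state, appearance gallery, lifecycle counters."""

    track_id: int
    kalman: KalmanState
    gallery: list[np.ndarray] = field(default_factory=list)
    hits: int = 1
    age: int = 1
    time_since_update: int = 0
    status: TrackStatus = TrackStatus.TENTATIVE
    last_detection: Detection | None = None


@dataclass(frozen=True)
class TrackerConfig:
    max_age: int = 30
    n_init: int = 3
    gallery_size: int = 50
    max_cosine_distance: float = 0.4
    gating_threshold: float = CHI2_GATE_4DOF
    iou_threshold: float = 0.3

    def __post_init__(self) -> None:
        if min(self.max_age, self.n_init, self.gallery_size) <= 0:
            raise ValueError("counts must be positive")


def matching_cascade(
    tracks: Sequence[TrackState],
    detections: Sequence[Detection],
    frame: np.ndarray,
    config: TrackerConfig,
    kf: KalmanFilter | None = None,
    features: Sequence[np.ndarray] | None = None,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Associate detections with tracks.

    Confirmed tracks are matched level by level in order of
    ``time_since_update`` (most recently seen first); each level solves a
    Hungarian assignment on appearance cost, with pairs outside the
    Mahalanobis gate or above the cosine-distance cap excluded.  Tracks
    still unmatched after the cascade — if unconfirmed or missed for just
    one frame — are then associated to the remaining detections by IoU.

    Returns (matches as (track_idx, det_idx), unmatched track indices,
    unmatched detection indices).
    """
    kf = kf or _DEFAULT_KF
    if features is None:
        features = [appearance_feature(frame, d.box) for d in detections]
    measurements = (
        np.stack([_box_to_measurement(d.box) for d in detections])
        if detections
        else np.empty((0, 4))
    )

    unmatched_dets = list(range(len(detections)))
    matches: list[tuple[int, int]] = []

    confirmed = [i for i, t in enumerate(tracks) if t.status is TrackStatus.CONFIRMED]
    unconfirmed = [i for i, t in enumerate(tracks) if t.status is TrackStatus.TENTATIVE]

    unmatched_confirmed = set(confirmed)
    for level in range(1, config.max_age + 1):
        if not unmatched_dets:
            break
        level_tracks = [i for i in unmatched_confirmed if tracks[i].time_since_update == level]
        if not level_tracks:
            continue
        cost = np.full((len(level_tracks), len(unmatched_dets)), _INF_COST)
        for r, ti in enumerate(level_tracks):
            t = tracks[ti]
            gate = kf.gating_distance(t.kalman, measurements[unmatched_dets])
            for c, di in enumerate(unmatched_dets):
                if gate[c] > config.gating_threshold:
                    continue
                d = cosine_gallery_distance(features[di], t.gallery) if t.gallery else 0.0
                if d > config.max_cosine_distance:
                    continue
                cost[r, c] = d
        for r, c in solve_assignment(cost):
            if cost[r, c] >= _INF_COST:
                continue
            ti, di = level_tracks[r], unmatched_dets[c]
            matches.append((ti, di))
            unmatched_confirmed.discard(ti)
        unmatched_dets = [di for di in unmatched_dets if di not in {m[1] for m in matches}]

    # IoU fallback: tentative tracks plus confirmed tracks missed exactly once
    iou_tracks = unconfirmed + [i for i in unmatched_confirmed if tracks[i].time_since_update == 1]
    if iou_tracks and unmatched_dets:
        cost = np.full((len(iou_tracks), len(unmatched_dets)), _INF_COST)
        for r, ti in enumerate(iou_tracks):
            tbox = tracks[ti].kalman.box()
            for c, di in enumerate(unmatched_dets):
                try:
                    ov = iou(tbox, detections[di].box)
                except ValueError:
                    ov = 0.0
                if ov >= config.iou_threshold:
                    cost[r, c] = 1.0 - ov
        for r, c in solve_assignment(cost):
            if cost[r, c] >= _INF_COST:
                continue
            matches.append((iou_tracks[r], unmatched_dets[c]))
        matched_d = {m[1] for m in matches}
        unmatched_dets = [di for di in unmatched_dets if di not in matched_d]

    matched_t = {m[0] for m in matches}
    unmatched_tracks = [i for i in range(len(tracks)) if i not in matched_t]
    return matches, unmatched_tracks, unmatched_dets


class Tracker:
    """Stateful online tracker; feed it one frame of detections at a time."""

    def __init__(
        self,
        config: TrackerConfig | None = None,
        kf: KalmanFilter | None = None,
        feature_extractor: Callable[[np.ndarray, BoundingBox], np.ndarray] = appearance_feature,
    ):
        self.config = config or TrackerConfig()
        self.kf = kf or KalmanFilter()
        self.feature_extractor = feature_extractor
        self.tracks: list[TrackState] = []
        self._next_id = 1

    def step(self, detections: Sequence[Detection], frame: np.ndarray) -> list[TrackState]:
        """Advance one frame; returns the currently confirmed tracks."""
        for t in self.tracks:
            t.kalman = self.kf.predict(t.kalman)
            t.age += 1
            t.time_since_update += 1
            t.last_detection = None

        features = [self.feature_extractor(frame, d.box) for d in detections]
        matches, unmatched_tracks, unmatched_dets = matching_cascade(
            self.tracks, detections, frame, self.config, self.kf, features
        )

        for ti, di in matches:
            t = self.tracks[ti]
            t.kalman = self.kf.update(t.kalman, _box_to_measurement(detections[di].box))
            t.gallery.append(features[di])
            if len(t.gallery) > self.config.gallery_size:
                t.gallery = t.gallery[-self.config.gallery_size :]
            t.hits += 1
            t.time_since_update = 0
            t.last_detection = detections[di]
            if t.status is TrackStatus.TENTATIVE and t.hits >= self.config.n_init:
                t.status = TrackStatus.CONFIRMED

        for ti in unmatched_tracks:
            t = self.tracks[ti]
            if t.status is TrackStatus.TENTATIVE:
                t.status = TrackStatus.DELETED
            elif t.time_since_update > self.config.max_age:
                t.status = TrackStatus.DELETED

        for di in unmatched_dets:
            d = detections[di]
            state = self.kf.initiate(_box_to_measurement(d.box))
            self.tracks.append(
                TrackState(
                    track_id=self._next_id,
                    kalman=state,
                    gallery=[features[di]],
                    status=(
                        TrackStatus.CONFIRMED
                        if self.config.n_init <= 1
                        else TrackStatus.TENTATIVE
                    ),
                    last_detection=d,
                )
            )
            self._next_id += 1

        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.DELETED]
        return [t for t in self.tracks if t.status is TrackStatus.CONFIRMED]


def _call_detector(detector, frame: np.ndarray, k: int):
    try:
        takes_index = len(inspect.signature(detector).parameters) >= 2
    except (TypeError, ValueError):
        takes_index = False
    return detector(frame, k) if takes_index else detector(frame)


def track_video(
    sequence: VideoSequence,
    detector: Callable,
    config: TrackerConfig | None = None,
    include_predicted: bool = True,
) -> tuple[dict[int, Trajectory], list[TrackRow]]:
    """Detect and track through a whole video.

    Returns per-track head trajectories (um, via the sequence calibration;
    the head point falls back to the box center when the detector provides
    none) and the flat per-frame track rows.  Frames where a confirmed
    track was only predicted are included with ``observed=False`` (and are
    excluded from kinematics by default downstream).
    """
    cal = sequence.calibration
    tracker = Tracker(config=config)
    samples: dict[int, list[tuple[int, float, float, bool, TrackRow]]] = {}
    rows: list[TrackRow] = []
    for k, frame in enumerate(sequence.frames):
        detections = _call_detector(detector, frame, k)
        confirmed = tracker.step(detections, frame)
        for t in confirmed:
            if t.last_detection is not None:
                d = t.last_detection
                head = d.head if d.head is not None else d.box.center
                row = TrackRow(
                    frame=k, track_id=t.track_id, box=d.box,
                    confidence=d.confidence, head=head, observed=True,
                )
            elif include_predicted:
                box = t.kalman.box()
                row = TrackRow(
                    frame=k, track_id=t.track_id, box=box,
                    confidence=0.0, head=box.center, observed=False,
                )
            else:
                continue
            rows.append(row)
            samples.setdefault(t.track_id, []).append(
                (k, row.head[0], row.head[1], row.observed, row)
            )

    fps = cal.frames_per_second
    trajectories = {}
    for tid, entries in samples.items():
        entries.sort(key=lambda e: e[0])
        frames_idx = np.array([e[0] for e in entries])
        pos_px = np.array([[e[1], e[2]] for e in entries], dtype=float)
        observed = np.array([e[3] for e in entries], dtype=bool)
        trajectories[tid] = Trajectory(
            track_id=tid,
            times=frames_idx / fps,
            positions=pos_px * cal.microns_per_pixel,
            observed=observed,
            fps=fps,
        )
    return trajectories, rows
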