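"""Detection and tracking evaluation.

Detections are scored against ground-truth boxes by IoU-thresholded
greedy matching: in descending confidence order each detection claims the
unmatched truth box of highest overlap, counting as a true positive only
when the overlap *strictly* exceeds the IoU threshold (default 0.45).
Precision, recall and F-value follow, a confidence-threshold sweep yields
the precision-recall curve, and average precision is the discrete
right-endpoint sum

    AP = sum_i (r_i - r_{i-1}) * P(r_i),    with r_0 = 0,

i.e. the uninterpolated area under the PR curve; an interpolated variant
(precision envelope) is available behind a flag.  With a single object
class, mAP equals AP by definition.

Tracking quality is summarized by identity-consistency counts: an id
switch is recorded whenever a truth track's matched predicted identity
changes between consecutive matched frames, and a fragmentation whenever a
truth track loses and later regains a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import AnnotatedBox, BoundingBox, Detection, iou

__all__ = [
    "MatchResult",
    "PRCurve",
    "EvalConfig",
    "match_frame",
    "precision_recall_f",
    "sweep_confidence",
    "average_precision",
    "mean_ap",
    "tracking_consistency",
]


@dataclass
class MatchResult:
    true_positives: int = 0
    false_positives: int = 0
    false_negatives: int = 0
    matched: list[tuple[int, int, float]] = field(default_factory=list)  # (det, truth, IoU)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            self.true_positives + other.true_positives,
            self.false_positives + other.false_positives,
            self.false_negatives + other.false_negatives,
            self.matched + other.matched,
        )


@dataclass
class PRCurve:
    """PR-curve points (r_i, P(r_i)) with their generating thresholds."""

    recalls: np.ndarray
    precisions: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.recalls = np.asarray(self.recalls, dtype=float)
        self.precisions = np.asarray(self.precisions, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.recalls.shape != self.precisions.shape:
            raise ValueError("recalls and precisions must align")
        for v in (self.recalls, self.precisions):
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError("PR values must lie in [0, 1]")


@dataclass(frozen=True)
class EvalConfig:
    iou_threshold: float = 0.45
    confidence_grid: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 51), 3))
    n_classes: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_threshold < 1.0:
            raise ValueError("iou_threshold must be in (0, 1)")


def _boxes_of(truth: Sequence[AnnotatedBox] | Sequence[BoundingBox]) -> list[BoundingBox]:
    return [b.box if isinstance(b, AnnotatedBox) else b for b in truth]


def match_frame(
    detections: Sequence[Detection],
    truth: Sequence[AnnotatedBox] | Sequence[BoundingBox],
    iou_threshold: float = 0.45,
) -> MatchResult:
    """Greedy one-to-one matching of one frame.

    Detections are visited in descending confidence; each claims the
    still-unmatched truth box with the highest IoU, provided the IoU is
    strictly above the threshold (ties broken toward the lower truth
    index).  Unclaimed detections are false positives; unclaimed truth
    boxes are false negatives.
    """
    truth_boxes = _boxes_of(truth)
    order = sorted(range(len(detections)), key=lambda i: -detections[i].confidence)
    taken = [False] * len(truth_boxes)
    result = MatchResult(false_negatives=len(truth_boxes))
    for di in order:
        best_j, best_iou = -1, iou_threshold
        for j, tb in enumerate(truth_boxes):
            if taken[j]:
                continue
            try:
                ov = iou(detections[di].box, tb)
            except ValueError:
                continue
            if ov > best_iou:  # strict: ties at the threshold do not count
                best_j, best_iou = j, ov
        if best_j >= 0:
            taken[best_j] = True
            result.true_positives += 1
            result.false_negatives -= 1
            result.matched.append((di, best_j, best_iou))
        else:
            result.false_positives += 1
    return result


def precision_recall_f(m: MatchResult) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean (F-value); NaN where the
    defining denominator is zero."""
    tp, fp, fn = m.true_positives, m.false_positives, m.false_negatives
    p = tp / (tp + fp) if tp + fp > 0 else float("nan")
    r = tp / (tp + fn) if tp + fn > 0 else float("nan")
    f = 2 * p * r / (p + r) if p + r > 0 else float("nan")
    return p, r, f


def sweep_confidence(
    detections_by_frame: Mapping[int, Sequence[Detection]],
    truth_by_frame: Mapping[int, Sequence[AnnotatedBox]],
    config: EvalConfig | None = None,
) -> tuple[PRCurve, np.ndarray]:
    """Sweep the confidence threshold over its grid.

    At each threshold, detections below it are dropped, all frames are
    matched and pooled, and (precision, recall, F) are computed.  Returns
    the PR curve (sorted by increasing recall, which for a sweep means
    decreasing threshold) and the F-value per grid threshold.
    """
    config = config or EvalConfig()
    precisions, recalls, fvals = [], [], []
    for thr in config.confidence_grid:
        total = MatchResult()
        for k, truth in truth_by_frame.items():
            dets = [d for d in detections_by_frame.get(k, []) if d.confidence >= thr]
            total = total + match_frame(dets, truth, config.iou_threshold)
        p, r, f = precision_recall_f(total)
        precisions.append(p)
        recalls.append(r)
        fvals.append(f)
    precisions = np.asarray(precisions)
    recalls = np.asarray(recalls)
    thresholds = np.asarray(config.confidence_grid)
    # drop thresholds where precision is undefined (no detections survive)
    keep = np.isfinite(precisions) & np.isfinite(recalls)
    order = np.argsort(recalls[keep], kind="stable")
    curve = PRCurve(
        recalls=recalls[keep][order],
        precisions=precisions[keep][order],
        thresholds=thresholds[keep][order],
    )
    return curve, np.asarray(fvals)


def average_precision(curve: PRCurve, interpolated: bool = False) -> float:
    """Discrete AP over a recall-sorted PR curve.

    The default is the literal right-endpoint sum with r_0 = 0 prepended;
    ``interpolated=True`` first replaces each precision by the maximum
    precision at any equal-or-higher recall (the standard PASCAL-style
    envelope), for comparison only.
    """
    r = curve.recalls
    p = curve.precisions
    if r.size == 0:
        return 0.0
    if np.any(np.diff(r) < 0):
        raise ValueError("curve points must be sorted by recall")
    if interpolated:
        p = np.maximum.accumulate(p[::-1])[::-1]
    r_prev = np.concatenate([[0.0], r[:-1]])
    return float(np.sum((r - r_prev) * p))


def mean_ap(per_class_aps: Sequence[float]) -> float:
    """Arithmetic mean of per-class APs; with one class, mAP == AP exactly."""
    if len(per_class_aps) == 0:
        raise ValueError("mean_ap of an empty list is undefined")
    return float(np.mean(per_class_aps))


@dataclass
class TrackingConsistency:
    id_switches: int
    fragmentations: int
    matched_frames: int


def tracking_consistency(
    predicted_by_frame: Mapping[int, Sequence[tuple[int, BoundingBox]]],
    truth_by_frame: Mapping[int, Sequence[AnnotatedBox]],
    iou_threshold: float = 0.45,
) -> TrackingConsistency:
    """Identity-consistency counts for predicted tracks against truth tracks.

    Per frame, truth boxes are greedily matched to predicted boxes by IoU
    (highest overlap first, one-to-one, strict threshold).  For each truth
    id, an id switch is a change of matched predicted id between
    consecutive *matched* frames; a fragmentation is a matched -> unmatched
    -> matched gap.
    """
    last_pred: dict[int, int] = {}
    was_matched: dict[int, bool] = {}
    switches = frags = matched_frames = 0
    for k in sorted(truth_by_frame):
        truth = truth_by_frame[k]
        preds = list(predicted_by_frame.get(k, []))
        # score all pairs, match greedily by descending IoU
        pairs = []
        for ti, ab in enumerate(truth):
            for pi, (pid, pbox) in enumerate(preds):
                try:
                    ov = iou(ab.box, pbox)
                except ValueError:
                    continue
                if ov > iou_threshold:
                    pairs.append((ov, ti, pi))
        pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
        used_t: set[int] = set()
        used_p: set[int] = set()
        frame_match: dict[int, int] = {}
        for ov, ti, pi in pairs:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            tid = truth[ti].track_id if truth[ti].track_id is not None else ti
            frame_match[tid] = preds[pi][0]
        for ti, ab in enumerate(truth):
            tid = ab.track_id if ab.track_id is not None else ti
            if tid in frame_match:
                pid = frame_match[tid]
                matched_frames += 1
                if tid in last_pred and last_pred[tid] != pid:
                    switches += 1
                if tid in was_matched and not was_matched[tid]:
                    frags += 1
                last_pred[tid] = pid
                was_matched[tid] = True
            elif tid in was_matched:
                was_matched[tid] = False
    return TrackingConsistency(
        id_switches=switches, fragmentations=frags, matched_frames=matched_frames
    )
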