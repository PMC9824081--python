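"""Detection and CLEAR-style tracking metrics.

Detection side: per-frame Hungarian box matching at an IoU threshold,
precision / recall / F1, and average precision with the COCO-style
threshold grid 0.50:0.05:0.95.

Tracking side: a per-frame event accumulator in the CLEAR convention —
previous-frame correspondences are kept while they still satisfy the
IoU gate, the remainder is matched by Hungarian on IoU — producing
per-frame FN/FP/ID-switch counts against the ground-truth object count,
from which MOTA = 1 − (ΣFN + ΣFP + ΣIDSW) / ΣGT.  An identity switch is
counted when a ground-truth identity's matched predicted ID differs
from the predicted ID it last matched; a fragmentation is a
tracked → not-tracked transition of a ground-truth identity that is
later tracked again.

Undefined ratios (empty denominators) raise
:class:`UndefinedMetricError` rather than silently returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assignment import gated_assignment
from .geometry import BoundingBox, centroid, iou
from .mot_io import TrackRecord, group_by_frame

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "MotEventLog",
    "TrackingReport",
    "DetectionReport",
    "match_frame",
    "prf",
    "average_precision",
    "map_over",
    "COCO_IOU_THRESHOLDS",
    "accumulate_mot",
    "mota",
    "count_tracked",
    "extract_contacts",
    "trajectories",
]

COCO_IOU_THRESHOLDS = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


class UndefinedMetricError(ArithmeticError):
    """A metric's denominator is zero; the value does not exist."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


def match_frame(
    gt_boxes: Sequence[BoundingBox],
    pred_boxes: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    """Match one frame's predictions to ground truth by Hungarian
    assignment maximising total IoU among pairs with IoU >= threshold.

    Matched pairs are true positives; unmatched predictions false
    positives; unmatched ground truth false negatives.
    """
    n_g, n_p = len(gt_boxes), len(pred_boxes)
    if n_g == 0 or n_p == 0:
        return ConfusionCounts(tp=0, fp=n_p, fn=n_g), []
    overlap = np.zeros((n_g, n_p))
    for i, g in enumerate(gt_boxes):
        for j, p in enumerate(pred_boxes):
            overlap[i, j] = iou(g, p)
    feasible = overlap >= iou_threshold
    matches, _, _ = gated_assignment(1.0 - overlap, feasible)
    tp = len(matches)
    return ConfusionCounts(tp=tp, fp=n_p - tp, fn=n_g - tp), matches


def prf(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1) from confusion counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN);
    F1 = 2TP/(2TP+FP+FN).  Raises on an empty denominator.
    """
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no predictions")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no ground truth")
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return precision, recall, f1


def average_precision(
    scored_preds: Sequence[tuple[int, BoundingBox, float]],
    gt: Sequence[tuple[int, BoundingBox]],
    iou_threshold: float = 0.5,
) -> float:
    """Average precision of scored predictions against ground truth.

    ``scored_preds`` are (frame, box, confidence); ``gt`` are
    (frame, box).  Predictions are swept in descending confidence; each
    claims the highest-IoU unclaimed ground-truth box of its frame with
    IoU >= threshold.  AP is the all-points interpolated area under the
    precision-recall curve (precision envelope integrated over recall).
    """
    if not gt:
        raise UndefinedMetricError("AP undefined: no ground truth")
    gt_by_frame: dict[int, list[BoundingBox]] = {}
    for frame, box in gt:
        gt_by_frame.setdefault(frame, []).append(box)
    claimed: dict[int, list[bool]] = {
        f: [False] * len(bs) for f, bs in gt_by_frame.items()
    }
    order = sorted(range(len(scored_preds)),
                   key=lambda i: -scored_preds[i][2])
    tp_flags = []
    for i in order:
        frame, box, _ = scored_preds[i]
        best_j, best_iou = -1, iou_threshold
        for j, g in enumerate(gt_by_frame.get(frame, [])):
            if claimed[frame][j]:
                continue
            o = iou(g, box)
            if o >= best_iou:
                best_iou, best_j = o, j
        if best_j >= 0:
            claimed[frame][best_j] = True
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    n_gt = len(gt)
    tps = np.cumsum(tp_flags) if tp_flags else np.array([])
    fps = np.cumsum([not t for t in tp_flags]) if tp_flags else np.array([])
    if len(tps) == 0:
        return 0.0
    recall = tps / n_gt
    precision = tps / (tps + fps)
    # all-points interpolation: envelope of precision, integrate over recall
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def map_over(
    preds_by_class: Mapping[str, Sequence[tuple[int, BoundingBox, float]]],
    gt_by_class: Mapping[str, Sequence[tuple[int, BoundingBox]]],
    iou_thresholds: Sequence[float] = COCO_IOU_THRESHOLDS,
) -> tuple[float, dict[str, float]]:
    """mAP over classes and IoU thresholds (mean of per-class AP,
    each itself averaged over the threshold grid).

    Classes absent from the ground truth are excluded with a warning.
    Returns (mAP, per-class AP dict).
    """
    import warnings

    per_class: dict[str, float] = {}
    for cls, preds in preds_by_class.items():
        gt = gt_by_class.get(cls, [])
        if not gt:
            warnings.warn(f"class {cls!r} has no ground truth; excluded")
            continue
        aps = [average_precision(preds, gt, thr) for thr in iou_thresholds]
        per_class[cls] = float(np.mean(aps))
    if not per_class:
        raise UndefinedMetricError("mAP undefined: no evaluable class")
    return float(np.mean(list(per_class.values()))), per_class


@dataclass
class MotEventLog:
    """Per-frame CLEAR event counts plus totals."""

    frames: list[int] = field(default_factory=list)
    fn: list[int] = field(default_factory=list)
    fp: list[int] = field(default_factory=list)
    idsw: list[int] = field(default_factory=list)
    gt: list[int] = field(default_factory=list)
    matches: list[int] = field(default_factory=list)
    fragmentations: int = 0

    @property
    def total_fn(self) -> int:
        return sum(self.fn)

    @property
    def total_fp(self) -> int:
        return sum(self.fp)

    @property
    def total_idsw(self) -> int:
        return sum(self.idsw)

    @property
    def total_gt(self) -> int:
        return sum(self.gt)


def accumulate_mot(
    gt_tracks: Sequence[TrackRecord],
    pred_tracks: Sequence[TrackRecord],
    iou_threshold: float = 0.5,
) -> MotEventLog:
    """Accumulate CLEAR tracking events frame by frame.

    Matching per frame: ground-truth/prediction pairs matched in the
    previous frame are kept if they still overlap at or above the
    threshold; the rest are matched by Hungarian assignment maximising
    IoU.  This persistence rule prevents spurious switch counting when
    two valid matchings tie.
    """
    gt_frames = group_by_frame(gt_tracks)
    pred_frames = group_by_frame(pred_tracks)
    for label, frames in (("GT", gt_frames), ("predicted", pred_frames)):
        for frame, recs in frames.items():
            ids = [r.track_id for r in recs]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {label} ids in frame {frame}")

    log = MotEventLog()
    prev_pairs: dict[int, int] = {}       # gt_id -> pred_id matched last frame
    last_matched_pred: dict[int, int] = {}  # gt_id -> pred_id ever matched
    was_tracked: dict[int, bool] = {}       # gt_id -> matched at last appearance
    pending_frag: set[int] = set()          # gt ids in a coverage gap

    all_frames = sorted(set(gt_frames) | set(pred_frames))
    for frame in all_frames:
        gts = gt_frames.get(frame, [])
        preds = pred_frames.get(frame, [])
        gt_ids = [r.track_id for r in gts]
        pred_ids = [r.track_id for r in preds]
        gt_boxes = {r.track_id: r.box for r in gts}
        pred_boxes = {r.track_id: r.box for r in preds}

        pairs: dict[int, int] = {}
        # 1. persistence: keep still-valid previous correspondences
        for g_id, p_id in prev_pairs.items():
            if g_id in gt_boxes and p_id in pred_boxes:
                if iou(gt_boxes[g_id], pred_boxes[p_id]) >= iou_threshold:
                    pairs[g_id] = p_id
        # 2. Hungarian on the remainder, maximising IoU
        free_g = [g for g in gt_ids if g not in pairs]
        used_p = set(pairs.values())
        free_p = [p for p in pred_ids if p not in used_p]
        if free_g and free_p:
            overlap = np.zeros((len(free_g), len(free_p)))
            for i, g in enumerate(free_g):
                for j, p in enumerate(free_p):
                    overlap[i, j] = iou(gt_boxes[g], pred_boxes[p])
            feasible = overlap >= iou_threshold
            m, _, _ = gated_assignment(1.0 - overlap, feasible)
            for i, j in m:
                pairs[free_g[i]] = free_p[j]

        n_match = len(pairs)
        idsw = 0
        for g_id, p_id in pairs.items():
            prev = last_matched_pred.get(g_id)
            if prev is not None and prev != p_id:
                idsw += 1
            last_matched_pred[g_id] = p_id

        # fragmentation bookkeeping per gt identity present this frame
        for g_id in gt_ids:
            tracked_now = g_id in pairs
            if g_id in pending_frag and tracked_now:
                log.fragmentations += 1
                pending_frag.discard(g_id)
            if was_tracked.get(g_id, False) and not tracked_now:
                pending_frag.add(g_id)
            was_tracked[g_id] = tracked_now

        log.frames.append(frame)
        log.matches.append(n_match)
        log.fn.append(len(gt_ids) - n_match)
        log.fp.append(len(pred_ids) - n_match)
        log.idsw.append(idsw)
        log.gt.append(len(gt_ids))
        prev_pairs = pairs
    return log


def mota(log: MotEventLog) -> float:
    """MOTA = 1 − (ΣFN + ΣFP + ΣIDSW) / ΣGT; at most 1, may be negative."""
    if log.total_gt == 0:
        raise UndefinedMetricError("MOTA undefined: no ground-truth objects")
    return 1.0 - (log.total_fn + log.total_fp + log.total_idsw) / log.total_gt


def mot_error_ratio(log: MotEventLog) -> float:
    """The raw error ratio (ΣFN + ΣFP + ΣIDSW) / ΣGT."""
    if log.total_gt == 0:
        raise UndefinedMetricError("error ratio undefined: no ground truth")
    return (log.total_fn + log.total_fp + log.total_idsw) / log.total_gt


@dataclass(frozen=True)
class TrackingReport:
    mota: float
    idsw: int
    fn: int
    fp: int
    gt: int
    fragmentations: int
    tracked_count: int


@dataclass(frozen=True)
class DetectionReport:
    precision: float
    recall: float
    f1: float
    map_value: float | None = None
    ap_per_class: dict | None = None


def count_tracked(
    pred_tracks: Sequence[TrackRecord], min_length: int = 25
) -> int:
    """Number of distinct predicted identities present in at least
    ``min_length`` frames."""
    lengths: dict[int, int] = {}
    for r in pred_tracks:
        lengths[r.track_id] = lengths.get(r.track_id, 0) + 1
    return sum(1 for n in lengths.values() if n >= min_length)


def evaluate_tracking(
    gt_tracks: Sequence[TrackRecord],
    pred_tracks: Sequence[TrackRecord],
    iou_threshold: float = 0.5,
    min_track_length: int = 25,
) -> TrackingReport:
    """One-call CLEAR evaluation producing a tracking report."""
    log = accumulate_mot(gt_tracks, pred_tracks, iou_threshold)
    return TrackingReport(
        mota=mota(log),
        idsw=log.total_idsw,
        fn=log.total_fn,
        fp=log.total_fp,
        gt=log.total_gt,
        fragmentations=log.fragmentations,
        tracked_count=count_tracked(pred_tracks, min_track_length),
    )


def extract_contacts(
    tracks: Sequence[TrackRecord],
    distance_threshold: float,
    min_duration: int = 25,
) -> list[tuple[int, int, int, int]]:
    """Proximity-contact intervals between identity pairs.

    A contact frame is one where two identities' box centroids are
    closer than ``distance_threshold`` pixels.  Consecutive contact
    frames merge into maximal intervals; intervals shorter than
    ``min_duration`` frames are dropped.  Returns
    (id_a, id_b, start_frame, end_frame) with id_a < id_b, end
    inclusive.
    """
    by_frame = group_by_frame(tracks)
    open_intervals: dict[tuple[int, int], tuple[int, int]] = {}
    finished: list[tuple[int, int, int, int]] = []
    frames = sorted(by_frame)
    for frame in frames:
        recs = by_frame[frame]
        cents = {r.track_id: centroid(r.box) for r in recs}
        ids = sorted(cents)
        current: set[tuple[int, int]] = set()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                (xa, ya), (xb, yb) = cents[a], cents[b]
                if ((xa - xb) ** 2 + (ya - yb) ** 2) ** 0.5 < distance_threshold:
                    current.add((a, b))
        for pair in current:
            if pair in open_intervals:
                start, last = open_intervals[pair]
                if frame == last + 1:
                    open_intervals[pair] = (start, frame)
                else:
                    if last - start + 1 >= min_duration:
                        finished.append((*pair, start, last))
                    open_intervals[pair] = (frame, frame)
            else:
                open_intervals[pair] = (frame, frame)
        for pair in list(open_intervals):
            if pair not in current:
                start, last = open_intervals.pop(pair)
                if last - start + 1 >= min_duration:
                    finished.append((*pair, start, last))
    for pair, (start, last) in open_intervals.items():
        if last - start + 1 >= min_duration:
            finished.append((*pair, start, last))
    finished.sort()
    return finished


def trajectories(
    tracks: Sequence[TrackRecord],
) -> dict[int, list[tuple[int, float, float]]]:
    """Per-identity centroid polyline (frame, x, y) for trajectory maps."""
    out: dict[int, list[tuple[int, float, float]]] = {}
    for r in sorted(tracks, key=lambda r: (r.track_id, r.frame)):
        x, y = centroid(r.box)
        out.setdefault(r.track_id, []).append((r.frame, x, y))
    return out
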