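"""Strong-SORT-style tracker: Kalman motion prediction, two-stage
association (appearance gallery, then IoU), and a
Tentative / Confirmed / Deleted track lifecycle.

Association runs in two gated Hungarian stages each frame:

1. *Appearance*: confirmed tracks vs. detections, cost = minimum cosine
   distance between the detection's embedding and the track's gallery
   of recent embeddings, gated at ``max_dist``.
2. *IoU*: all remaining tracks (tentative ones included) vs. remaining
   detections, cost = 1 − IoU of the Kalman-predicted box against the
   detection, gated at ``max_iou_distance``.

When no embedder is supplied the appearance stage is skipped and the
tracker degrades to IoU-only association.  Lifecycle: a track confirms
after ``n_init`` associations, a tentative track that misses a frame is
dropped, and any track unseen for more than ``max_age`` frames is
deleted (terminal).  Each track keeps a FIFO gallery of at most
``nn_budget`` embeddings.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np

from .assignment import gated_assignment
from .geometry import BoundingBox, iou
from .kalman import KalmanBoxFilter, box_to_state, state_to_box
from .mot_io import Detection, TrackRecord, group_by_frame

__all__ = ["SortConfig", "TrackState", "KalmanTrack", "SortTracker", "run_sort"]


@dataclass(frozen=True)
class SortConfig:
    """Association gates and lifecycle parameters.

    Defaults are the working configuration for herd footage:
    a permissive appearance gate (``max_dist`` 0.9), IoU-distance gate
    0.8, immediate confirmation (``n_init`` 1), tracks kept alive for up
    to 1500 frames (one minute at 25 fps) without a detection, and a
    100-embedding appearance gallery per track.
    """

    max_dist: float = 0.9
    max_iou_distance: float = 0.8
    max_age: int = 1500
    n_init: int = 1
    nn_budget: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.max_dist <= 2.0):
            raise ValueError("max_dist must be in (0, 2]")
        if not (0.0 < self.max_iou_distance <= 1.0):
            raise ValueError("max_iou_distance must be in (0, 1]")
        if not (self.max_age >= self.n_init >= 1):
            raise ValueError("need max_age >= n_init >= 1")


class TrackState(Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


class KalmanTrack:
    """One tracked identity with Kalman state and appearance gallery."""

    def __init__(self, track_id: int, det: Detection, kf: KalmanBoxFilter,
                 cfg: SortConfig, embedding: np.ndarray | None = None):
        self.track_id = track_id
        self.kf = kf
        self.mean, self.covariance = kf.initiate(box_to_state(det.box))
        self.state = TrackState.TENTATIVE
        self.hits = 0
        self.time_since_update = 0
        self.gallery: deque[np.ndarray] = deque(maxlen=cfg.nn_budget)
        self._cfg = cfg
        self._register_hit(embedding)

    def _register_hit(self, embedding: np.ndarray | None) -> None:
        self.hits += 1
        self.time_since_update = 0
        if embedding is not None:
            self.gallery.append(np.asarray(embedding, dtype=float))
        if self.state is TrackState.TENTATIVE and self.hits >= self._cfg.n_init:
            self.state = TrackState.CONFIRMED

    @property
    def predicted_box(self) -> BoundingBox:
        return state_to_box(self.mean)

    def predict(self) -> None:
        """Advance one frame: constant-velocity mean, inflated covariance."""
        if self.state is TrackState.DELETED:
            raise ValueError("deleted tracks never advance")
        self.mean, self.covariance = self.kf.predict(self.mean, self.covariance)
        self.time_since_update += 1

    def update(self, det: Detection, embedding: np.ndarray | None = None) -> None:
        """Kalman correction with the matched detection."""
        if self.state is TrackState.DELETED:
            raise ValueError("deleted tracks never update")
        self.mean, self.covariance = self.kf.update(
            self.mean, self.covariance, box_to_state(det.box)
        )
        self._register_hit(embedding)

    def mark_missed(self) -> None:
        """Lifecycle step for an unassociated frame."""
        if self.state is TrackState.DELETED:
            raise ValueError("deleted tracks never change state")
        if self.state is TrackState.TENTATIVE:
            self.state = TrackState.DELETED
        elif self.time_since_update > self._cfg.max_age:
            self.state = TrackState.DELETED

    def appearance_distance(self, embedding: np.ndarray) -> float:
        """Minimum cosine distance from ``embedding`` to the gallery."""
        if not self.gallery:
            return np.inf
        emb = np.asarray(embedding, dtype=float)
        gal = np.stack(list(self.gallery))
        if gal.shape[1] != emb.shape[0]:
            raise ValueError(
                f"embedding dim {emb.shape[0]} != gallery dim {gal.shape[1]}"
            )
        norms = np.linalg.norm(gal, axis=1) * np.linalg.norm(emb)
        norms = np.where(norms == 0, 1.0, norms)
        sims = gal @ emb / norms
        return float(1.0 - sims.max())


def associate(
    tracks: Sequence[KalmanTrack],
    dets: Sequence[Detection],
    embeddings: Sequence[np.ndarray] | None,
    cfg: SortConfig,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Two-stage gated association; returns (matches, unmatched_tracks,
    unmatched_detections) as index lists."""
    n_t, n_d = len(tracks), len(dets)
    matches: list[tuple[int, int]] = []
    remaining_t = list(range(n_t))
    remaining_d = list(range(n_d))

    if embeddings is not None and n_t and n_d:
        stage1_t = [
            i for i in remaining_t
            if tracks[i].state is TrackState.CONFIRMED and tracks[i].gallery
        ]
        if stage1_t:
            cost = np.zeros((len(stage1_t), n_d))
            for r, ti in enumerate(stage1_t):
                for c in range(n_d):
                    cost[r, c] = tracks[ti].appearance_distance(embeddings[c])
            feasible = cost <= cfg.max_dist
            m, _, _ = gated_assignment(cost, feasible)
            for r, c in m:
                matches.append((stage1_t[r], c))
            matched_t = {stage1_t[r] for r, _ in m}
            matched_d = {c for _, c in m}
            remaining_t = [i for i in remaining_t if i not in matched_t]
            remaining_d = [j for j in remaining_d if j not in matched_d]

    if remaining_t and remaining_d:
        cost = np.zeros((len(remaining_t), len(remaining_d)))
        for r, ti in enumerate(remaining_t):
            pbox = tracks[ti].predicted_box
            for c, dj in enumerate(remaining_d):
                cost[r, c] = 1.0 - iou(pbox, dets[dj].box)
        feasible = cost <= cfg.max_iou_distance
        m, _, _ = gated_assignment(cost, feasible)
        for r, c in m:
            matches.append((remaining_t[r], remaining_d[c]))
        matched_t = {remaining_t[r] for r, _ in m}
        matched_d = {remaining_d[c] for _, c in m}
        remaining_t = [i for i in remaining_t if i not in matched_t]
        remaining_d = [j for j in remaining_d if j not in matched_d]

    matches.sort()
    return matches, remaining_t, remaining_d


class SortTracker:
    """Frame-by-frame driver for the Kalman + appearance tracker.

    ``embedder`` maps a detection to a fixed-dimension appearance
    vector; pass ``None`` for IoU-only tracking.
    """

    def __init__(
        self,
        cfg: SortConfig | None = None,
        embedder: Callable[[Detection], np.ndarray] | None = None,
    ):
        self.cfg = cfg or SortConfig()
        self.embedder = embedder
        self.kf = KalmanBoxFilter()
        self.tracks: list[KalmanTrack] = []
        self._next_id = 1
        self._last_frame: int | None = None

    def step(self, frame: int, dets: Sequence[Detection]) -> list[TrackRecord]:
        if self._last_frame is not None and frame <= self._last_frame:
            raise ValueError(
                f"frames must increase: got {frame} after {self._last_frame}"
            )
        self._last_frame = frame

        for tr in self.tracks:
            tr.predict()

        embeddings = None
        if self.embedder is not None:
            embeddings = [self.embedder(d) for d in dets]

        matches, un_t, un_d = associate(self.tracks, dets, embeddings, self.cfg)

        records = []
        for ti, di in matches:
            emb = embeddings[di] if embeddings is not None else None
            self.tracks[ti].update(dets[di], emb)
            records.append(
                TrackRecord(
                    frame=frame,
                    track_id=self.tracks[ti].track_id,
                    box=dets[di].box,
                    confidence=dets[di].confidence,
                )
            )
        for ti in un_t:
            self.tracks[ti].mark_missed()
        for di in un_d:
            emb = embeddings[di] if embeddings is not None else None
            tr = KalmanTrack(self._next_id, dets[di], self.kf, self.cfg, emb)
            self._next_id += 1
            self.tracks.append(tr)
            if tr.state is TrackState.CONFIRMED:
                records.append(
                    TrackRecord(
                        frame=frame,
                        track_id=tr.track_id,
                        box=dets[di].box,
                        confidence=dets[di].confidence,
                    )
                )
        self.tracks = [t for t in self.tracks if t.state is not TrackState.DELETED]
        records.sort(key=lambda r: r.track_id)
        return records


def run_sort(
    detections: Iterable[Detection],
    cfg: SortConfig | None = None,
    embedder: Callable[[Detection], np.ndarray] | None = None,
    n_frames: int | None = None,
) -> list[TrackRecord]:
    """Track a full detection sequence; deterministic given inputs."""
    tracker = SortTracker(cfg, embedder)
    by_frame = group_by_frame(detections)
    if not by_frame and not n_frames:
        return []
    last = n_frames or max(by_frame)
    out: list[TrackRecord] = []
    for frame in range(1, last + 1):
        out.extend(tracker.step(frame, by_frame.get(frame, [])))
    out.sort(key=lambda r: (r.frame, r.track_id))
    return out
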