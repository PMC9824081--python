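"""Customised lightweight tracker: geometry-only cost matching with
periodic re-matching of new identities against recently lost tracks.

The tracker keeps, per identity, a bounded history of past boxes.  Each
frame, active tracks are matched one-to-one against the frame's
detections by minimising the combined location / aspect-ratio cost
(see :mod:`herdtrack.geometry`), gated by a maximum acceptable cost and
a minimum IoU.  Unmatched tracks become *lost*; unmatched detections
receive provisional fresh IDs immediately.  Every ``rematch_period``
frames a re-matching pass runs: identities created since the previous
re-match boundary are matched against lost tracks no older than
``max_lost_age``; a success means the provisional identity was really a
re-appearance, so its records are rewritten to the old ID (within the
in-memory buffer only) and the lost track is reactivated.  Lost tracks
older than ``max_lost_age`` are deleted and their IDs never reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .assignment import gated_assignment
from .geometry import BoundingBox, TrackHistory, match_cost
from .mot_io import Detection, TrackRecord, group_by_frame

__all__ = ["LightweightConfig", "LiteTrack", "LiteTracker", "run_lite"]


@dataclass(frozen=True)
class LightweightConfig:
    """Tuning knobs of the lightweight tracker.

    ``history_window`` is the number of past steps entering the cost;
    ``rematch_period`` the cadence (frames) of the re-matching pass;
    ``max_lost_age`` how long (frames) a lost identity stays recoverable;
    ``cost_gate`` the maximum acceptable combined cost (pixels-dominated
    units) and ``iou_gate`` the minimum box overlap for a direct match.
    ``weights`` are (w_location, w_aspect, w_mask_area).
    """

    history_window: int = 5
    rematch_period: int = 30
    max_lost_age: int = 1500
    cost_gate: float = 15.0
    iou_gate: float = 0.0
    weights: tuple[float, float, float] = (1.0, 1.0, 0.0)
    history_capacity: int = 64
    greedy: bool = False  # nearest-cost greedy instead of Hungarian

    def __post_init__(self) -> None:
        if self.rematch_period < 1:
            raise ValueError("rematch_period must be >= 1")
        if self.cost_gate < 0 or self.iou_gate < 0:
            raise ValueError("gates must be non-negative")


class TrackStatus(Enum):
    ACTIVE = "active"
    LOST = "lost"
    DELETED = "deleted"


@dataclass
class LiteTrack:
    """One persistent identity of the lightweight tracker."""

    track_id: int
    history: TrackHistory
    last_seen: int
    status: TrackStatus = TrackStatus.ACTIVE
    born: int = 0

    def mark_lost(self) -> None:
        if self.status is TrackStatus.DELETED:
            raise ValueError("deleted tracks never change state")
        self.status = TrackStatus.LOST

    def reactivate(self) -> None:
        if self.status is TrackStatus.DELETED:
            raise ValueError("deleted tracks never reactivate")
        self.status = TrackStatus.ACTIVE


def _cost_matrix(
    tracks: Sequence[LiteTrack],
    dets: Sequence[Detection],
    cfg: LightweightConfig,
    frame: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise gated costs; a pair is feasible when COST <= cost_gate
    and IoU >= iou_gate.

    Computes the windowed distances incrementally per track instead of
    rebuilding a tentative history per pair; equal to
    :func:`herdtrack.geometry.match_cost` by construction (and by
    property test).
    """
    import math

    from .geometry import centroid, iou as box_iou

    w_loc, w_ar, w_mask = cfg.weights
    cost = np.zeros((len(tracks), len(dets)))
    feasible = np.zeros_like(cost, dtype=bool)
    for i, tr in enumerate(tracks):
        hist = tr.history
        n = min(hist.window, len(hist))
        tail = hist.entries[-n:]
        cents = [centroid(b) for _, b in tail]
        ars = [b.aspect for _, b in tail]
        prev_loc = sum(
            math.hypot(x1 - x0, y1 - y0)
            for (x0, y0), (x1, y1) in zip(cents, cents[1:])
        )
        prev_ar = sum(abs(b - a) for a, b in zip(ars, ars[1:]))
        if w_mask != 0.0:
            areas = [
                (ma if ma is not None else b.area)
                for (_, b), ma in zip(hist.entries, hist.mask_areas)
            ][-n:]
            prev_mask = sum(abs(b - a) for a, b in zip(areas, areas[1:]))
            last_area = areas[-1]
        last_c = cents[-1]
        last_ar = ars[-1]
        last_box = hist.last_box
        for j, d in enumerate(dets):
            cx, cy = centroid(d.box)
            loc = (prev_loc + math.hypot(cx - last_c[0], cy - last_c[1])) / n
            ar = (prev_ar + abs(d.box.aspect - last_ar)) / n
            c = w_loc * loc + w_ar * ar
            if w_mask != 0.0:
                da = d.mask_area if d.mask_area is not None else d.box.area
                c += w_mask * (prev_mask + abs(da - last_area)) / n
            cost[i, j] = c
            feasible[i, j] = (
                c <= cfg.cost_gate
                and (cfg.iou_gate <= 0.0
                     or box_iou(last_box, d.box) >= cfg.iou_gate)
            )
    return cost, feasible


def _greedy_assignment(cost, feasible):
    """Nearest-cost-first greedy matching (ablation alternative)."""
    n_rows, n_cols = cost.shape
    order = sorted(
        ((cost[r, c], r, c) for r in range(n_rows) for c in range(n_cols)
         if feasible[r, c])
    )
    used_r, used_c, matches = set(), set(), []
    for _, r, c in order:
        if r not in used_r and c not in used_c:
            matches.append((r, c))
            used_r.add(r)
            used_c.add(c)
    matches.sort()
    return (
        matches,
        [r for r in range(n_rows) if r not in used_r],
        [c for c in range(n_cols) if c not in used_c],
    )


def match(
    tracks: Sequence[LiteTrack],
    dets: Sequence[Detection],
    cfg: LightweightConfig,
    frame: int | None = None,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Gated minimum-cost one-to-one matching of tracks to detections.

    Returns (matches, unmatched_track_indices, unmatched_det_indices);
    matches are (track_index, det_index) pairs.
    """
    if not tracks or not dets:
        return [], list(range(len(tracks))), list(range(len(dets)))
    if frame is None:
        frame = max(t.history.last_frame for t in tracks) + 1
    cost, feasible = _cost_matrix(tracks, dets, cfg, frame)
    solver = _greedy_assignment if cfg.greedy else gated_assignment
    return solver(cost, feasible)


class LiteTracker:
    """Stateful frame-by-frame driver.

    Feed frames in increasing order via :meth:`step`; call
    :meth:`finalize` for the full output, which folds in the retroactive
    ID rewrites made by re-matching.
    """

    def __init__(self, cfg: LightweightConfig | None = None):
        self.cfg = cfg or LightweightConfig()
        self.tracks: dict[int, LiteTrack] = {}
        self._next_id = 1
        self._last_frame: int | None = None
        self._records: list[TrackRecord] = []
        # ids issued since the last re-match boundary (provisional)
        self._provisional: set[int] = set()
        # provisional id -> inherited id, applied at finalize
        self._renames: dict[int, int] = {}

    # -- id plumbing -------------------------------------------------
    def _issue_id(self) -> int:
        tid = self._next_id
        self._next_id += 1
        return tid

    def _new_track(self, frame: int, det: Detection) -> LiteTrack:
        hist = TrackHistory(window=self.cfg.history_window,
                            capacity=self.cfg.history_capacity)
        hist.append(frame, det.box, det.mask_area)
        tr = LiteTrack(self._issue_id(), hist, last_seen=frame, born=frame)
        self.tracks[tr.track_id] = tr
        self._provisional.add(tr.track_id)
        return tr

    # -- stages ------------------------------------------------------
    def _active(self) -> list[LiteTrack]:
        return sorted(
            (t for t in self.tracks.values() if t.status is TrackStatus.ACTIVE),
            key=lambda t: t.track_id,
        )

    def _lost(self, frame: int) -> list[LiteTrack]:
        return sorted(
            (
                t for t in self.tracks.values()
                if t.status is TrackStatus.LOST
                and frame - t.last_seen <= self.cfg.max_lost_age
            ),
            key=lambda t: t.track_id,
        )

    def rematch(self, frame: int) -> dict[int, int]:
        """Re-match provisionally-new identities against lost tracks.

        A provisional track whose recent box extends a lost track within
        the gates inherits that track's ID; the lost track reactivates
        with the merged history and the provisional ID is retired.
        Returns {provisional_id: inherited_id}.
        """
        provisional = sorted(
            tid for tid in self._provisional
            if tid in self.tracks
            and self.tracks[tid].status is not TrackStatus.DELETED
        )
        lost = self._lost(frame)
        if not provisional or not lost:
            return {}
        # match each provisional identity at its first appearance: the
        # re-appearance box is what extends the lost trajectory
        pseudo_dets = [
            Detection(frame=max(1, frame),
                      box=self.tracks[tid].history.entries[0][1])
            for tid in provisional
        ]
        cost, feasible = _cost_matrix(lost, pseudo_dets, self.cfg, frame)
        # a reappearance must begin after the disappearance
        for li, old in enumerate(lost):
            for pi, tid in enumerate(provisional):
                if self.tracks[tid].born <= old.history.last_frame:
                    feasible[li, pi] = False
        solver = _greedy_assignment if self.cfg.greedy else gated_assignment
        matches, _, _ = solver(cost, feasible)
        renames: dict[int, int] = {}
        for li, pi in matches:
            old = lost[li]
            if old.status is TrackStatus.DELETED:
                # this lost track was itself provisional and has just been
                # merged elsewhere; follow the rename chain to its root
                tid = old.track_id
                while tid in self._renames:
                    tid = self._renames[tid]
                if tid not in self.tracks:
                    continue
                old = self.tracks[tid]
                if old.status is TrackStatus.DELETED:
                    continue
            prov = self.tracks[provisional[pi]]
            for (f, b), ma in zip(prov.history.entries,
                                  prov.history.mask_areas):
                old.history.append(f, b, ma)
            old.last_seen = prov.last_seen
            old.reactivate()
            prov.status = TrackStatus.DELETED
            del self.tracks[prov.track_id]
            renames[prov.track_id] = old.track_id
            self._renames[prov.track_id] = old.track_id
        return renames

    def prune(self, frame: int) -> None:
        """Delete lost tracks strictly older than ``max_lost_age``."""
        for t in list(self.tracks.values()):
            if (
                t.status is TrackStatus.LOST
                and frame - t.last_seen > self.cfg.max_lost_age
            ):
                t.status = TrackStatus.DELETED
                del self.tracks[t.track_id]

    def step(self, frame: int, dets: Sequence[Detection]) -> list[TrackRecord]:
        """Process one frame; returns this frame's (possibly provisional)
        track records."""
        if self._last_frame is not None and frame <= self._last_frame:
            raise ValueError(
                f"frames must increase: got {frame} after {self._last_frame}"
            )
        self._last_frame = frame

        active = self._active()
        matches, un_tracks, un_dets = match(active, dets, self.cfg, frame)

        for ti, di in matches:
            tr = active[ti]
            d = dets[di]
            tr.history.append(frame, d.box, d.mask_area)
            tr.last_seen = frame

        for ti in un_tracks:
            active[ti].mark_lost()

        new_tracks = [self._new_track(frame, dets[di]) for di in un_dets]

        if frame % self.cfg.rematch_period == 0:
            self.rematch(frame)
            self._provisional.clear()
        self.prune(frame)

        frame_records = []
        det_to_track = {di: active[ti].track_id for ti, di in matches}
        for tr, di in zip(new_tracks, un_dets):
            if tr.track_id in self._renames:
                det_to_track[di] = self._renames[tr.track_id]
            else:
                det_to_track[di] = tr.track_id
        for di in sorted(det_to_track):
            frame_records.append(
                TrackRecord(
                    frame=frame,
                    track_id=det_to_track[di],
                    box=dets[di].box,
                    confidence=dets[di].confidence,
                )
            )
        self._records.extend(frame_records)
        return frame_records

    def finalize(self) -> list[TrackRecord]:
        """All records with retroactive re-match renames applied."""
        resolve = {}
        for old, new in self._renames.items():
            while new in self._renames:
                new = self._renames[new]
            resolve[old] = new
        out = [
            TrackRecord(
                frame=r.frame,
                track_id=resolve.get(r.track_id, r.track_id),
                box=r.box,
                confidence=r.confidence,
            )
            for r in self._records
        ]
        out.sort(key=lambda r: (r.frame, r.track_id))
        return out


def run_lite(
    detections: Iterable[Detection],
    cfg: LightweightConfig | None = None,
    n_frames: int | None = None,
) -> list[TrackRecord]:
    """Track a whole detection sequence with the lightweight tracker.

    Frames absent from ``detections`` (up to ``n_frames`` if given) are
    processed as empty, so the re-match cadence and lost-track ageing
    advance in real frame time.
    """
    tracker = LiteTracker(cfg)
    by_frame = group_by_frame(detections)
    if not by_frame and not n_frames:
        return []
    last = n_frames or max(by_frame)
    for frame in range(1, last + 1):
        tracker.step(frame, by_frame.get(frame, []))
    return tracker.finalize()
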