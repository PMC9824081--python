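"""Bounding-box arithmetic and the association cost functions.

Boxes are axis-aligned, stored as ``(left, top, width, height)`` in
continuous pixel coordinates with the origin at the top-left corner
(the MOT-Challenge convention).  The tracker's matching cost combines
two windowed history statistics:

* the *location distance* — the mean Euclidean centroid displacement
  over the last ``N`` consecutive history steps, in pixels;
* the *aspect-ratio distance* — the mean absolute change of the box
  aspect ratio ``Ar = w / h`` over the same steps, dimensionless.

The two are summed raw by default (equal unit weights); optional weights
allow normalisation, and an optional mask-area term (mean absolute
change of the segmentation-mask area) is exposed with default weight 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "BoundingBox",
    "TrackHistory",
    "CostBreakdown",
    "UndefinedHistoryError",
    "iou",
    "centroid",
    "location_distance",
    "aspect_distance",
    "mask_area_distance",
    "match_cost",
]


class UndefinedHistoryError(ValueError):
    """Raised when a history statistic needs at least two entries."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box ``(left, top, width, height)``.

    Width and height must be strictly positive and all coordinates
    finite, so the aspect ratio ``w / h`` is always finite and > 0.
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"box {name} must be finite, got {v!r}")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(
                f"degenerate box: w={self.w}, h={self.h} (must be > 0)"
            )

    @property
    def aspect(self) -> float:
        """Aspect ratio ``Ar = w / h``."""
        return self.w / self.h

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def right(self) -> float:
        return self.x + self.w

    @property
    def bottom(self) -> float:
        return self.y + self.h

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.w, self.h)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    ix = min(a.right, b.right) - max(a.x, b.x)
    iy = min(a.bottom, b.bottom) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    # roundoff in the edge arithmetic can nudge the ratio past 1
    return min(max(inter / union, 0.0), 1.0)


def centroid(b: BoundingBox) -> tuple[float, float]:
    """Box centre ``(x + w/2, y + h/2)`` in pixels."""
    return (b.x + b.w / 2.0, b.y + b.h / 2.0)


@dataclass
class TrackHistory:
    """Ordered ``(frame, box)`` trail of one identity with a step window.

    ``window`` is the number of most-recent consecutive steps that enter
    the distance statistics; with fewer steps available, all are used.
    Entries must have strictly increasing frame indices.  Gaps between
    frame indices are permitted: entries are treated as consecutive
    observations regardless of how many frames separate them.
    """

    window: int = 5
    entries: list[tuple[int, BoundingBox]] = field(default_factory=list)
    mask_areas: list[float | None] = field(default_factory=list)
    capacity: int = 64

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if len(self.mask_areas) not in (0, len(self.entries)):
            raise ValueError("mask_areas must parallel entries")
        if not self.mask_areas:
            self.mask_areas = [None] * len(self.entries)
        frames = [t for t, _ in self.entries]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def append(self, frame: int, box: BoundingBox,
               mask_area: float | None = None) -> None:
        if self.entries and frame <= self.entries[-1][0]:
            raise ValueError(
                f"frame {frame} not after last frame {self.entries[-1][0]}"
            )
        self.entries.append((frame, box))
        self.mask_areas.append(mask_area)
        if len(self.entries) > self.capacity:
            del self.entries[0]
            del self.mask_areas[0]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def last_frame(self) -> int:
        return self.entries[-1][0]

    @property
    def last_box(self) -> BoundingBox:
        return self.entries[-1][1]

    def _require_steps(self) -> int:
        if len(self.entries) < 2:
            raise UndefinedHistoryError(
                "at least 2 history entries are required for a distance"
            )
        return min(self.window, len(self.entries) - 1)


def _mean_step(values: Sequence[float], n: int) -> float:
    steps = [abs(b - a) for a, b in zip(values[-n - 1:-1], values[-n:])]
    return sum(steps) / n


def location_distance(hist: TrackHistory) -> float:
    """Mean Euclidean centroid step over the last ``window`` steps (px)."""
    n = hist._require_steps()
    cents = [centroid(b) for _, b in hist.entries[-(n + 1):]]
    total = 0.0
    for (x0, y0), (x1, y1) in zip(cents, cents[1:]):
        total += math.hypot(x1 - x0, y1 - y0)
    return total / n


def aspect_distance(hist: TrackHistory) -> float:
    """Mean absolute aspect-ratio step over the last ``window`` steps."""
    n = hist._require_steps()
    ars = [b.aspect for _, b in hist.entries[-(n + 1):]]
    return _mean_step(ars, n)


def mask_area_distance(hist: TrackHistory) -> float:
    """Mean absolute mask-area step; boxes' areas stand in where the
    detector supplied no mask."""
    n = hist._require_steps()
    areas = [
        (ma if ma is not None else b.area)
        for (_, b), ma in zip(hist.entries, hist.mask_areas)
    ][-(n + 1):]
    return _mean_step(areas, n)


@dataclass(frozen=True)
class CostBreakdown:
    """Components of one track-to-detection matching cost.

    ``cost`` is the weighted sum ``w_L * Ldist + w_Ar * Ardist
    (+ w_mask * mask step)``; with the default weights (1, 1, 0) it is
    the raw sum of location and aspect-ratio distance.  ``iou`` is the
    overlap between the candidate box and the most recent history box.
    """

    location: float
    aspect: float
    mask: float
    cost: float
    iou: float


def match_cost(
    hist: TrackHistory,
    candidate: BoundingBox,
    weights: tuple[float, float] | tuple[float, float, float] = (1.0, 1.0),
    frame: int | None = None,
    mask_area: float | None = None,
) -> CostBreakdown:
    """Cost of extending ``hist`` with ``candidate`` at the next frame.

    The candidate is appended as a tentative current-frame observation,
    the windowed distances are computed, and the tentative entry is
    discarded.  ``weights`` is ``(w_L, w_Ar)`` or ``(w_L, w_Ar, w_mask)``;
    defaults give the plain unweighted sum.
    """
    w = tuple(weights)
    if len(w) == 2:
        w = (*w, 0.0)
    w_loc, w_ar, w_mask = w
    last_box = hist.last_box
    tentative_frame = hist.last_frame + 1 if frame is None else frame
    trial = TrackHistory(
        window=hist.window,
        entries=list(hist.entries),
        mask_areas=list(hist.mask_areas),
        capacity=hist.capacity + 1,
    )
    trial.append(tentative_frame, candidate, mask_area)
    loc = location_distance(trial)
    ar = aspect_distance(trial)
    mask = mask_area_distance(trial) if w_mask != 0.0 else 0.0
    return CostBreakdown(
        location=loc,
        aspect=ar,
        mask=mask,
        cost=w_loc * loc + w_ar * ar + w_mask * mask,
        iou=iou(last_box, candidate),
    )
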