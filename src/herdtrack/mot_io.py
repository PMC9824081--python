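"""Reading and writing detections and tracks in MOT-Challenge and
YOLO text dialects, plus run configuration files.

The MOT-Challenge dialect is one CSV line per record::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z

with 1-based frames and IDs; ``id`` is −1 for raw (identity-free)
detections, and the world-coordinate columns are written as −1.
YOLO label files hold one frame per file, lines
``class cx cy w h [conf]`` with coordinates normalised to the image.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .geometry import BoundingBox

__all__ = [
    "Detection",
    "TrackRecord",
    "SequenceMeta",
    "MotParseError",
    "read_mot",
    "read_mot_detections",
    "read_yolo_frames",
    "write_tracks",
    "write_detections",
    "group_by_frame",
    "load_config",
]


class MotParseError(ValueError):
    """A malformed line in a MOT/YOLO text file; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True)
class Detection:
    """One detector output: a box with confidence and optional extras."""

    frame: int
    box: BoundingBox
    confidence: float = 1.0
    mask_area: float | None = None
    class_label: str = "cattle"
    crop_ref: str | None = None

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame must be >= 1, got {self.frame}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(
                f"confidence must be in [0, 1], got {self.confidence}"
            )


@dataclass(frozen=True)
class TrackRecord:
    """One tracked box: a detection bound to a persistent identity."""

    frame: int
    track_id: int
    box: BoundingBox
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame must be >= 1, got {self.frame}")
        if self.track_id < 1:
            raise ValueError(f"track_id must be >= 1, got {self.track_id}")


@dataclass(frozen=True)
class SequenceMeta:
    """Sequence-level constants: frame rate and image geometry."""

    fps: float = 25.0
    image_width: int = 2560
    image_height: int = 2048
    n_frames: int | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("SequenceMeta fields must be positive")


def _parse_mot_line(path, lineno: int, line: str):
    parts = [p.strip() for p in line.split(",")]
    if len(parts) < 6:
        raise MotParseError(path, lineno, f"expected >= 6 fields, got {len(parts)}")
    try:
        frame = int(float(parts[0]))
        obj_id = int(float(parts[1]))
        x, y, w, h = (float(p) for p in parts[2:6])
        conf = float(parts[6]) if len(parts) > 6 else 1.0
    except ValueError as exc:
        raise MotParseError(path, lineno, f"non-numeric field: {exc}") from None
    if w <= 0 or h <= 0:
        raise MotParseError(path, lineno, f"non-positive box size w={w}, h={h}")
    if frame < 1:
        raise MotParseError(path, lineno, f"frame must be >= 1, got {frame}")
    return frame, obj_id, BoundingBox(x, y, w, h), min(max(conf, 0.0), 1.0)


def read_mot(path) -> list[TrackRecord] | list[Detection]:
    """Read a MOT-Challenge file; returns ``TrackRecord`` objects when
    every line carries an identity, ``Detection`` objects when all are
    −1, and raises on a mixture.

    Records are returned sorted by (frame, id).  Every input line
    becomes a record or raises :class:`MotParseError` — nothing is
    silently dropped.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            rows.append(_parse_mot_line(path, lineno, line))
    has_ids = [obj_id > 0 for _, obj_id, _, _ in rows]
    if rows and any(has_ids) and not all(has_ids):
        raise MotParseError(path, 0, "mixed identity and identity-free lines")
    if rows and all(has_ids):
        recs = [
            TrackRecord(frame=f, track_id=i, box=b, confidence=c)
            for f, i, b, c in rows
        ]
        recs.sort(key=lambda r: (r.frame, r.track_id))
        seen = set()
        for r in recs:
            key = (r.frame, r.track_id)
            if key in seen:
                raise MotParseError(path, 0, f"duplicate (frame, id) {key}")
            seen.add(key)
        return recs
    dets = [Detection(frame=f, box=b, confidence=c) for f, _, b, c in rows]
    dets.sort(key=lambda d: (d.frame, d.box.x, d.box.y))
    return dets


def read_mot_detections(path) -> list[Detection]:
    """Read a MOT file as raw detections, discarding any identities."""
    recs = read_mot(path)
    return [
        r if isinstance(r, Detection)
        else Detection(frame=r.frame, box=r.box, confidence=r.confidence)
        for r in recs
    ]


_YOLO_FRAME_RE = re.compile(r"(\d+)")


def read_yolo_frames(directory, meta: SequenceMeta) -> list[Detection]:
    """Read a directory of YOLO per-frame label files.

    Each ``*.txt`` file holds one frame; the frame index is the last
    integer in the file stem.  Lines are ``class cx cy w h [conf]``
    with centre-form coordinates normalised to [0, 1]; they are
    denormalised against ``meta`` and converted to corner form.
    """
    directory = Path(directory)
    dets: list[Detection] = []
    for path in sorted(directory.glob("*.txt")):
        nums = _YOLO_FRAME_RE.findall(path.stem)
        if not nums:
            raise MotParseError(path, 0, "no frame index in filename")
        frame = int(nums[-1])
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) not in (5, 6):
                    raise MotParseError(
                        path, lineno, f"expected 5 or 6 fields, got {len(parts)}"
                    )
                try:
                    cls = parts[0]
                    cx, cy, w, h = (float(p) for p in parts[1:5])
                    conf = float(parts[5]) if len(parts) == 6 else 1.0
                except ValueError as exc:
                    raise MotParseError(path, lineno, str(exc)) from None
                for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
                    if not (0.0 <= v <= 1.0):
                        raise MotParseError(
                            path, lineno,
                            f"normalised {name}={v} outside [0, 1]",
                        )
                pw = w * meta.image_width
                ph = h * meta.image_height
                box = BoundingBox(
                    cx * meta.image_width - pw / 2.0,
                    cy * meta.image_height - ph / 2.0,
                    pw,
                    ph,
                )
                dets.append(
                    Detection(frame=frame, box=box, confidence=conf,
                              class_label=cls)
                )
    dets.sort(key=lambda d: (d.frame, d.box.x, d.box.y))
    return dets


def _fmt(v: float) -> str:
    return f"{v:.6f}".rstrip("0").rstrip(".")


def write_tracks(records: Iterable[TrackRecord], path) -> None:
    """Write track records in the MOT-Challenge dialect, sorted by
    (frame, id); duplicate (frame, id) pairs are rejected."""
    recs = sorted(records, key=lambda r: (r.frame, r.track_id))
    seen = set()
    for r in recs:
        key = (r.frame, r.track_id)
        if key in seen:
            raise ValueError(f"duplicate (frame, id) {key}")
        seen.add(key)
    with open(path, "w") as fh:
        for r in recs:
            b = r.box
            fh.write(
                f"{r.frame},{r.track_id},{_fmt(b.x)},{_fmt(b.y)},"
                f"{_fmt(b.w)},{_fmt(b.h)},{_fmt(r.confidence)},-1,-1,-1\n"
            )


def write_detections(dets: Iterable[Detection], path) -> None:
    """Write identity-free detections (id column −1)."""
    ordered = sorted(dets, key=lambda d: (d.frame, d.box.x, d.box.y))
    with open(path, "w") as fh:
        for d in ordered:
            b = d.box
            fh.write(
                f"{d.frame},-1,{_fmt(b.x)},{_fmt(b.y)},"
                f"{_fmt(b.w)},{_fmt(b.h)},{_fmt(d.confidence)},-1,-1,-1\n"
            )


def group_by_frame(records):
    """Group records (detections or tracks) into {frame: [records]}."""
    frames: dict[int, list] = {}
    for r in records:
        frames.setdefault(r.frame, []).append(r)
    return dict(sorted(frames.items()))


def load_config(path) -> dict:
    """Load a flat YAML key/value run configuration.

    Recognised keys mirror the Strong-SORT parameter names
    (``MAX_DIST``, ``MAX_IOU_DISTANCE``, ``MAX_AGE``, ``N_INIT``,
    ``NN_BUDGET``) plus the lightweight-tracker keys
    (``history_window``, ``rematch_period``, ``max_lost_age``,
    ``cost_gate``, ``iou_gate``).  Unknown keys are preserved.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a flat mapping")
    return dict(data)
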