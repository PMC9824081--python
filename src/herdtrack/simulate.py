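"""Synthetic herd scenarios: ground-truth trajectories plus corrupted
detections emulating fixed-camera livestock surveillance.

The motion model is waypoint-seeking: each animal walks at its own
speed towards a random waypoint with Gaussian heading noise, picks a
new waypoint on arrival (or occasionally spontaneously — abrupt turns),
and is reflected off the arena walls.  Soft pairwise repulsion keeps
body centres from interpenetrating, as solid animals do.  Posture
changes (standing ↔ lying) flip the body box between two aspect
ratios at a configurable per-frame rate.

Detector corruption models the failure modes of box detectors on herd
footage: independent per-box misses, centroid/size localisation jitter,
heavily-overlapping pairs collapsing into one merged detection (mutual
occlusion), and Poisson background clutter.  Confidences are drawn
uniformly from [0.5, 1] — detectors on this footage emit near-1
confidences and only the ranking matters to the metrics.

A lightweight renderer draws dark per-identity-textured ellipses on a
textured ground so the appearance stage has something to embed; it can
rasterise a single window (cheap crops for the tracker) or full frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import BoundingBox, iou
from .mot_io import Detection, TrackRecord, group_by_frame

__all__ = [
    "SimConfig",
    "SimScenario",
    "simulate_herd",
    "corrupt_detections",
    "simulate",
    "render_window",
    "render_frame",
    "render_frames",
    "crop_for_box",
    "make_embedder",
    "crossing_scenario",
]


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters.

    Defaults mirror the recording conditions the package targets:
    ~20 animals free-ranging in a 2560 × 2048 px fixed camera view at
    25 fps, walking a few pixels per frame, changing posture now and
    then, with a detector that misses ~5% of boxes, jitters box edges
    by a couple of pixels, merges heavily-occluded pairs and emits a
    sprinkle of clutter.
    """

    n_cattle: int = 20
    n_frames: int = 500
    arena_width: int = 2560
    arena_height: int = 2048
    speed_scale: float = 4.0           # px/frame mean walking speed
    heading_noise: float = 0.15        # rad sd per frame
    waypoint_jump_rate: float = 0.002  # spontaneous re-targeting prob/frame
    body_width: float = 180.0          # mean standing body box width, px
    body_height: float = 110.0
    posture_change_rate: float = 0.005  # prob/frame of standing<->lying flip
    miss_rate: float = 0.05
    fp_rate: float = 0.2               # expected clutter boxes per frame
    jitter_sd: float = 2.0             # px, centroid and size jitter
    occlusion_merge_iou: float = 0.6   # >= this overlap -> merged detection
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cattle < 1 or self.n_frames < 1:
            raise ValueError("n_cattle and n_frames must be >= 1")
        if self.arena_width <= 0 or self.arena_height <= 0:
            raise ValueError("arena must be positive")
        for name in ("miss_rate", "posture_change_rate", "waypoint_jump_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        body_area = self.body_width * self.body_height * 1.4
        if self.n_cattle * body_area > 0.4 * self.arena_width * self.arena_height:
            raise ValueError("infeasible density: bodies cannot fit the arena")


@dataclass
class SimScenario:
    """A complete synthetic scenario: truth, detections, provenance."""

    gt_tracks: list[TrackRecord]
    detections: list[Detection]
    config: SimConfig
    appearance: dict[int, tuple[float, float, float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.appearance:
            self.appearance = _identity_appearance(self.config)
        self._gt_by_frame = group_by_frame(self.gt_tracks)

    def gt_frame(self, frame: int) -> list[TrackRecord]:
        return self._gt_by_frame.get(frame, [])


def _identity_appearance(cfg: SimConfig) -> dict[int, tuple]:
    """Per-identity coat parameters (tone, speckle amp, stripe period,
    phase) drawn once from the scenario seed."""
    rng = np.random.default_rng([cfg.seed, 7])
    out = {}
    for tid in range(1, cfg.n_cattle + 1):
        tone = 25.0 + 70.0 * rng.random()
        amp = 5.0 + 20.0 * rng.random()
        period = 6.0 + 30.0 * rng.random()
        phase = 2 * math.pi * rng.random()
        out[tid] = (tone, amp, period, phase)
    return out


def simulate_herd(cfg: SimConfig) -> list[TrackRecord]:
    """Ground-truth trajectories; fully deterministic given the seed."""
    rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_cattle
    aw, ah = float(cfg.arena_width), float(cfg.arena_height)

    widths = cfg.body_width * (0.85 + 0.3 * rng.random(n))
    heights = cfg.body_height * (0.85 + 0.3 * rng.random(n))
    lying = rng.random(n) < 0.2  # lying: longer, flatter silhouette
    speeds = cfg.speed_scale * (0.6 + 0.8 * rng.random(n))

    margin_x = widths.max() * 0.8
    margin_y = heights.max() * 0.8
    pos = np.column_stack([
        margin_x + (aw - 2 * margin_x) * rng.random(n),
        margin_y + (ah - 2 * margin_y) * rng.random(n),
    ])
    waypoints = np.column_stack([
        margin_x + (aw - 2 * margin_x) * rng.random(n),
        margin_y + (ah - 2 * margin_y) * rng.random(n),
    ])
    min_sep = 0.45 * float(np.mean(widths))

    records: list[TrackRecord] = []
    for frame in range(1, cfg.n_frames + 1):
        if cfg.speed_scale > 0:
            to_wp = waypoints - pos
            dist = np.linalg.norm(to_wp, axis=1)
            arrived = dist < speeds * 2
            jump = rng.random(n) < cfg.waypoint_jump_rate
            for i in np.where(arrived | jump)[0]:
                waypoints[i] = (
                    margin_x + (aw - 2 * margin_x) * rng.random(),
                    margin_y + (ah - 2 * margin_y) * rng.random(),
                )
            to_wp = waypoints - pos
            heading = np.arctan2(to_wp[:, 1], to_wp[:, 0])
            heading = heading + rng.normal(0.0, cfg.heading_noise, n)
            pos = pos + np.column_stack(
                [speeds * np.cos(heading), speeds * np.sin(heading)]
            )
            # soft repulsion: solid bodies do not interpenetrate deeply
            upper = np.triu(np.ones((n, n), dtype=bool), k=1)
            for _ in range(2):
                diff = pos[None, :, :] - pos[:, None, :]
                dist = np.sqrt((diff ** 2).sum(-1))
                ii, jj = np.where((dist < min_sep) & upper)
                if ii.size == 0:
                    break
                for i, j in zip(ii, jj):
                    d = pos[j] - pos[i]
                    r = float(np.linalg.norm(d))
                    push = (min_sep - r) / 2.0
                    u = d / r if r > 1e-9 else np.array([1.0, 0.0])
                    pos[i] -= u * push
                    pos[j] += u * push
            pos[:, 0] = np.clip(pos[:, 0], margin_x, aw - margin_x)
            pos[:, 1] = np.clip(pos[:, 1], margin_y, ah - margin_y)

        flips = rng.random(n) < cfg.posture_change_rate
        lying = np.logical_xor(lying, flips)

        for i in range(n):
            w = widths[i] * (1.35 if lying[i] else 1.0)
            h = heights[i] * (0.72 if lying[i] else 1.0)
            x = min(max(pos[i, 0] - w / 2.0, 0.0), aw - w)
            y = min(max(pos[i, 1] - h / 2.0, 0.0), ah - h)
            records.append(
                TrackRecord(
                    frame=frame,
                    track_id=i + 1,
                    box=BoundingBox(x, y, w, h),
                )
            )
    return records


def _union_box(boxes: Sequence[BoundingBox]) -> BoundingBox:
    x0 = min(b.x for b in boxes)
    y0 = min(b.y for b in boxes)
    x1 = max(b.right for b in boxes)
    y1 = max(b.bottom for b in boxes)
    return BoundingBox(x0, y0, x1 - x0, y1 - y0)


def corrupt_detections(
    gt: Sequence[TrackRecord], cfg: SimConfig
) -> list[Detection]:
    """Detector-style corruption of ground truth.

    Per frame: each box is dropped with ``miss_rate``; survivors get
    Gaussian centroid and size jitter (sd ``jitter_sd``); groups of
    surviving boxes whose pairwise IoU reaches ``occlusion_merge_iou``
    collapse into one union-box detection carrying the union area as
    ``mask_area``; Poisson(``fp_rate``) clutter boxes are added.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    aw, ah = float(cfg.arena_width), float(cfg.arena_height)
    dets: list[Detection] = []
    for frame, recs in group_by_frame(gt).items():
        kept: list[BoundingBox] = []
        for r in recs:
            if rng.random() < cfg.miss_rate:
                continue
            b = r.box
            if cfg.jitter_sd > 0:
                dx, dy = rng.normal(0.0, cfg.jitter_sd, 2)
                dw, dh = rng.normal(0.0, cfg.jitter_sd / 2.0, 2)
                w = max(b.w + dw, 2.0)
                h = max(b.h + dh, 2.0)
                b = BoundingBox(
                    min(max(b.x + dx - dw / 2.0, 0.0), aw - w),
                    min(max(b.y + dy - dh / 2.0, 0.0), ah - h),
                    w,
                    h,
                )
            kept.append(b)

        # union-find clustering of heavily-overlapping boxes
        if cfg.occlusion_merge_iou < 1.0 and len(kept) > 1:
            parent = list(range(len(kept)))

            def find(i: int) -> int:
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(kept)):
                for j in range(i + 1, len(kept)):
                    if iou(kept[i], kept[j]) >= cfg.occlusion_merge_iou:
                        parent[find(i)] = find(j)
            clusters: dict[int, list[BoundingBox]] = {}
            for i, b in enumerate(kept):
                clusters.setdefault(find(i), []).append(b)
        else:
            clusters = {i: [b] for i, b in enumerate(kept)}

        for members in clusters.values():
            if len(members) == 1:
                box, mask_area = members[0], None
            else:
                box = _union_box(members)
                mask_area = box.area
            dets.append(
                Detection(
                    frame=frame,
                    box=box,
                    confidence=0.5 + 0.5 * rng.random(),
                    mask_area=mask_area,
                )
            )

        for _ in range(rng.poisson(cfg.fp_rate)):
            w = 40.0 + 160.0 * rng.random()
            h = 30.0 + 120.0 * rng.random()
            dets.append(
                Detection(
                    frame=frame,
                    box=BoundingBox(
                        (aw - w) * rng.random(), (ah - h) * rng.random(), w, h
                    ),
                    confidence=0.5 + 0.5 * rng.random(),
                )
            )
    dets.sort(key=lambda d: (d.frame, d.box.x, d.box.y))
    return dets


def simulate(cfg: SimConfig) -> SimScenario:
    """Ground truth plus corrupted detections in one scenario object."""
    gt = simulate_herd(cfg)
    return SimScenario(gt_tracks=gt, detections=corrupt_detections(gt, cfg),
                       config=cfg)


# --------------------------------------------------------------------
# rendering


def _hash_noise(xs: np.ndarray, ys: np.ndarray, salt: int) -> np.ndarray:
    """Deterministic per-pixel value noise in [0, 1)."""
    x = xs.astype(np.int64)
    y = ys.astype(np.int64)
    h = (x * 73856093) ^ (y * 19349663) ^ (np.int64(salt) * 83492791)
    h = (h ^ (h >> 13)) * 1274126177
    return ((h >> 8) & 0xFF).astype(float) / 255.0


def render_window(
    scenario: SimScenario, frame: int, region: BoundingBox
) -> np.ndarray:
    """Rasterise one window of one frame as a grayscale array.

    Textured mid-grey ground, dark ellipses for each animal whose box
    intersects the window, drawn in identity order so higher IDs
    occlude lower ones.  Output shape (round(h), round(w)), uint8.
    """
    x0, y0 = int(math.floor(region.x)), int(math.floor(region.y))
    w, h = max(int(round(region.w)), 1), max(int(round(region.h)), 1)
    xs, ys = np.meshgrid(np.arange(x0, x0 + w), np.arange(y0, y0 + h))
    seed_salt = scenario.config.seed & 0x7FFFFFFF
    img = 150.0 + 30.0 * (_hash_noise(xs, ys, seed_salt) - 0.5)

    for rec in scenario.gt_frame(frame):
        b = rec.box
        if b.x >= x0 + w or b.right <= x0 or b.y >= y0 + h or b.bottom <= y0:
            continue
        cx, cy = b.x + b.w / 2.0, b.y + b.h / 2.0
        rx, ry = b.w / 2.0, b.h / 2.0
        mask = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
        if not mask.any():
            continue
        tone, amp, period, phase = scenario.appearance.get(
            rec.track_id, (40.0, 10.0, 16.0, 0.0)
        )
        stripes = amp * np.sin(xs / period + phase) * np.cos(ys / (period * 1.3))
        speckle = 8.0 * (_hash_noise(xs, ys, seed_salt + rec.track_id) - 0.5)
        coat = tone + stripes + speckle
        img = np.where(mask, coat, img)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_frame(scenario: SimScenario, frame: int) -> np.ndarray:
    """Full-frame rasterisation (arena-sized image)."""
    cfg = scenario.config
    return render_window(
        scenario, frame,
        BoundingBox(0.0, 0.0, float(cfg.arena_width), float(cfg.arena_height)),
    )


def render_frames(scenario: SimScenario, out_dir) -> list[Path]:
    """Write one grayscale PNG per frame; returns the paths."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in range(1, scenario.config.n_frames + 1):
        arr = render_frame(scenario, frame)
        path = out_dir / f"frame_{frame:06d}.png"
        Image.fromarray(arr).save(path)
        paths.append(path)
    return paths


def crop_for_box(
    scenario: SimScenario, frame: int, box: BoundingBox
) -> np.ndarray:
    """Rendered image content under a (detection) box."""
    return render_window(scenario, frame, box)


def make_embedder(scenario: SimScenario):
    """Detection -> appearance embedding via the rendered scene and the
    handcrafted descriptor, with a small memo cache."""
    from .reid import embed, normalize_crop

    cache: dict[tuple, np.ndarray] = {}

    def _embedder(det: Detection) -> np.ndarray:
        key = (det.frame, round(det.box.x, 1), round(det.box.y, 1),
               round(det.box.w, 1), round(det.box.h, 1))
        if key not in cache:
            crop = crop_for_box(scenario, det.frame, det.box)
            cache[key] = embed(normalize_crop(crop))
        return cache[key]

    return _embedder


def crossing_scenario(
    seed: int,
    n_frames: int = 120,
    occlusion_gap: int = 12,
    arena: tuple[int, int] = (1280, 720),
) -> SimScenario:
    """Two animals approach head-on, meet behind an occlusion gap, and
    *turn back* the way they came.

    During the gap no detections are emitted for either animal, so a
    motion-only tracker's constant-velocity prediction overshoots and
    tends to swap the identities at re-acquisition; distinct coat
    textures let an appearance stage recover the truth.
    """
    rng = np.random.default_rng([seed, 3])
    aw, ah = arena
    w0, h0 = 140.0, 90.0
    y_a = ah / 2.0 - 10.0 + rng.normal(0, 4)
    y_b = ah / 2.0 + 10.0 + rng.normal(0, 4)
    speed = 6.0 + rng.random() * 2.0
    meet_frame = n_frames // 2
    start_a = aw / 2.0 - speed * meet_frame
    start_b = aw / 2.0 + speed * meet_frame

    gt: list[TrackRecord] = []
    dets: list[Detection] = []
    gap_lo = meet_frame - occlusion_gap // 2
    gap_hi = meet_frame + occlusion_gap // 2
    for frame in range(1, n_frames + 1):
        # advance towards the meeting point, then retreat
        t = frame if frame <= meet_frame else 2 * meet_frame - frame
        x_a = start_a + speed * t
        x_b = start_b - speed * t
        for tid, (x, y) in ((1, (x_a, y_a)), (2, (x_b, y_b))):
            box = BoundingBox(x - w0 / 2.0, y - h0 / 2.0, w0, h0)
            gt.append(TrackRecord(frame=frame, track_id=tid, box=box))
            if gap_lo <= frame <= gap_hi:
                continue  # mutual occlusion: no detections
            jx, jy = rng.normal(0.0, 1.0, 2)
            dets.append(
                Detection(
                    frame=frame,
                    box=BoundingBox(box.x + jx, box.y + jy, w0, h0),
                    confidence=0.5 + 0.5 * rng.random(),
                )
            )
    cfg = SimConfig(
        n_cattle=2, n_frames=n_frames,
        arena_width=aw, arena_height=ah, seed=seed,
    )
    scenario = SimScenario(gt_tracks=gt, detections=dets, config=cfg)
    return scenario
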