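"""Appearance re-identification stage.

Three parts:

* a machine-checkable descriptor of the 10-layer re-ID CNN used for
  cattle appearance learning (for anyone wiring a deep-learning
  backend; no network is trained or run here);
* a deterministic handcrafted embedder with the same interface
  contract — a 128-dimensional, L2-normalised descriptor per
  128 × 128 crop — used by the tracker's appearance stage;
* the unsupervised threshold-based identity split that groups detector
  crops into per-animal folders for building a re-ID dataset.

The handcrafted embedder tiles the crop into a 4 × 4 grid and collects
an 8-bin intensity histogram per cell (4·4·8 = 128 dims).  It is not a
learned feature: it separates identities only insofar as their coat
texture or brightness statistics differ, which is exactly the regime
the synthetic herd renderer produces.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import BoundingBox, centroid

__all__ = [
    "LayerSpec",
    "build_reid_architecture",
    "validate_architecture",
    "REID_TRAINING_META",
    "CROP_SIZE",
    "EMBED_DIM",
    "normalize_crop",
    "embed",
    "Crop",
    "split_identities",
    "export_reid_dataset",
]

CROP_SIZE = 128
EMBED_DIM = 128

# optimisation settings the reference network was trained with,
# recorded for reproducibility of a deep-learning backend
REID_TRAINING_META = {
    "optimizer": "Adam",
    "learning_rate": 1e-5,
    "batch_size": 128,
    "epochs": 100,
    "input_size": (CROP_SIZE, CROP_SIZE),
}


@dataclass(frozen=True)
class LayerSpec:
    """One row of the re-ID CNN description.

    ``output_shape`` is (channels, height, width) for spatial layers or
    a flat ``(width,)`` for dense/normalisation layers.
    """

    index: int
    name: str
    patch: str  # "3x3/1" style patch-size/stride text, "-" if n/a
    output_shape: tuple[int, ...]


_ARCHITECTURE_ROWS: tuple[tuple[int, str, str, tuple[int, ...]], ...] = (
    (1, "Conv 1", "3x3/1", (32, 128, 128)),
    (2, "Conv 2", "3x3/1", (32, 128, 128)),
    (3, "Max Pool", "3x3/2", (32, 64, 64)),
    (4, "Residual 4", "3x3/1", (32, 64, 64)),
    (5, "Residual 5", "3x3/1", (64, 32, 32)),
    (6, "Residual 6", "3x3/2", (64, 32, 32)),
    (7, "Residual 7", "3x3/1", (128, 16, 16)),
    (8, "Dense 8", "-", (128,)),
    (9, "Batch Normalization", "3x3/1", (128,)),
    (10, "Relu", "3x3/1", (128,)),
)


def build_reid_architecture() -> list[LayerSpec]:
    """The 10-layer re-ID CNN descriptor, in order."""
    return [LayerSpec(*row) for row in _ARCHITECTURE_ROWS]


def validate_architecture(layers: Sequence[LayerSpec]) -> None:
    """Check shape chaining: flatten-aware input/output compatibility.

    Each spatial layer must consume the previous layer's output; a flat
    layer may follow either a flat layer of equal width or any spatial
    layer (a dense layer flattens).  Raises ``ValueError`` on orphan
    dimensions.
    """
    prev: tuple[int, ...] | None = None
    for layer in layers:
        shape = layer.output_shape
        if not shape or any(d <= 0 for d in shape):
            raise ValueError(f"layer {layer.index}: bad shape {shape}")
        if prev is not None and len(shape) == 1 and len(prev) == 1:
            if layer.name.startswith(("Batch", "Relu")) and shape != prev:
                raise ValueError(
                    f"layer {layer.index}: elementwise layer changes "
                    f"width {prev} -> {shape}"
                )
        if prev is not None and len(shape) == 3 and len(prev) == 3:
            ch, h, w = shape
            pch, ph, pw = prev
            if h > ph or w > pw:
                raise ValueError(
                    f"layer {layer.index}: spatial size grows {prev} -> {shape}"
                )
        prev = shape


def normalize_crop(img: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Resize an arbitrary rectangular crop to ``size``×``size``
    (nearest-neighbour, deterministic).  Accepts 2-D grayscale arrays."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("crop must be a non-empty 2-D grayscale array")
    h, w = img.shape
    rows = np.minimum((np.arange(size) * h) // size, h - 1)
    cols = np.minimum((np.arange(size) * w) // size, w - 1)
    return img[np.ix_(rows, cols)]


def embed(crop: np.ndarray) -> np.ndarray:
    """128-dim unit-norm appearance descriptor of a square crop.

    The crop is resized to 128 × 128, tiled 4 × 4, and an 8-bin
    intensity histogram (range [0, 255]) is taken per tile; the
    concatenation is L2-normalised.  Fully deterministic; affine
    intensity changes alter the vector (no photometric invariance is
    claimed).
    """
    crop = np.asarray(crop, dtype=float)
    if crop.ndim != 2 or crop.size == 0:
        raise ValueError("crop must be a non-empty 2-D grayscale array")
    if crop.shape[0] != crop.shape[1]:
        raise ValueError(f"crop must be square, got {crop.shape}")
    if crop.shape[0] != CROP_SIZE:
        crop = normalize_crop(crop)
    grid = 4
    bins = 8
    cell = CROP_SIZE // grid
    feats = np.empty(grid * grid * bins)
    k = 0
    for i in range(grid):
        for j in range(grid):
            tile = crop[i * cell:(i + 1) * cell, j * cell:(j + 1) * cell]
            hist, _ = np.histogram(tile, bins=bins, range=(0.0, 255.0))
            feats[k:k + bins] = hist
            k += bins
    norm = np.linalg.norm(feats)
    if norm == 0:
        feats[0] = 1.0
        norm = 1.0
    return feats / norm


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


@dataclass(frozen=True)
class Crop:
    """A detector crop with provenance for identity splitting."""

    image: np.ndarray
    frame: int
    box: BoundingBox
    det_index: int = 0

    def __post_init__(self) -> None:
        if np.asarray(self.image).size == 0:
            raise ValueError("empty crop")


@dataclass
class _Group:
    members: list[int] = field(default_factory=list)
    emb_sum: np.ndarray | None = None
    last_frame: int = -1
    last_centroid: tuple[float, float] = (0.0, 0.0)

    def medoid(self) -> np.ndarray:
        v = self.emb_sum / len(self.members)
        n = np.linalg.norm(v)
        return v / n if n > 0 else v


def split_identities(
    crops: Sequence[Crop],
    threshold: float,
    max_jump: float | None = None,
    frame_gap: int = 1,
) -> list[list[int]]:
    """Greedy unsupervised identity grouping of detector crops.

    Crops are visited in (frame, detection-index) order.  Each joins the
    existing group whose mean-embedding (medoid) cosine similarity is
    highest, provided the similarity is at least ``threshold``;
    otherwise it founds a new group.  When ``max_jump`` is given, a
    group seen within ``frame_gap`` frames is only eligible if the crop
    centroid moved at most ``max_jump`` pixels (spatial continuity).

    Returns groups as lists of indices into ``crops``.  ``threshold`` 0
    with non-negative features collapses everything into one group;
    a threshold above 1 yields one group per crop.
    """
    order = sorted(range(len(crops)),
                   key=lambda i: (crops[i].frame, crops[i].det_index))
    groups: list[_Group] = []
    for idx in order:
        crop = crops[idx]
        e = embed(np.asarray(crop.image))
        c = centroid(crop.box)
        best: tuple[float, _Group] | None = None
        for g in groups:
            if max_jump is not None and 0 <= crop.frame - g.last_frame <= frame_gap:
                dx = c[0] - g.last_centroid[0]
                dy = c[1] - g.last_centroid[1]
                if (dx * dx + dy * dy) ** 0.5 > max_jump:
                    continue
            sim = cosine_similarity(e, g.medoid())
            if sim >= threshold and (best is None or sim > best[0]):
                best = (sim, g)
        if best is None:
            g = _Group()
            groups.append(g)
        else:
            g = best[1]
        g.members.append(idx)
        g.emb_sum = e if g.emb_sum is None else g.emb_sum + e
        g.last_frame = crop.frame
        g.last_centroid = c
    return [g.members for g in groups]


def _split_of(path_key: str) -> str:
    digest = hashlib.md5(path_key.encode()).hexdigest()
    return "test" if int(digest, 16) % 5 == 0 else "train"


def export_reid_dataset(
    groups: Sequence[Sequence[int]],
    crops: Sequence[Crop],
    out_dir,
) -> list[tuple[str, int, str]]:
    """Write one folder per identity plus a train/test manifest.

    Crops are saved as PNG under ``out_dir/id_<k>/``; the manifest
    (``manifest.txt``, lines ``path<TAB>identity<TAB>split``) assigns
    each file to train or test by a deterministic hash of its relative
    path, giving an approximate 80/20 split.  Empty groups are skipped.
    Re-exporting over the same directory is idempotent.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, int, str]] = []
    seen_paths: set[str] = set()
    identity = 0
    for members in groups:
        if not members:
            continue
        identity += 1
        gdir = out_dir / f"id_{identity:03d}"
        gdir.mkdir(exist_ok=True)
        for idx in members:
            crop = crops[idx]
            rel = f"id_{identity:03d}/f{crop.frame:06d}_d{crop.det_index:03d}.png"
            if rel in seen_paths:
                raise ValueError(f"output path collision: {rel}")
            seen_paths.add(rel)
            arr = np.clip(np.asarray(crop.image, dtype=float), 0, 255)
            Image.fromarray(arr.astype(np.uint8)).save(out_dir / rel)
            manifest.append((rel, identity, _split_of(rel)))
    with open(out_dir / "manifest.txt", "w") as fh:
        for rel, ident, split in manifest:
            fh.write(f"{rel}\t{ident}\t{split}\n")
    return manifest
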