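"""Tile extraction, dihedral augmentation and per-channel normalization.

Pathologist ROI rectangles are divided into square, 50%-overlapping tiles
(512x512 px at full scale); each tile inherits its ROI's class.  A full-slide
grid of unlabeled tiles supplies the candidates for pseudo-labeling.  All
coordinates are 0-based with half-open rectangles [x, x+w) x [y, y+h); partial
tiles at ROI/slide edges are dropped rather than padded.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .scheme import DEFAULT_SCHEME, ClassScheme

GROUND_TRUTH = "ground_truth"
PSEUDO = "pseudo"
UNLABELED = "unlabeled"

#: Dihedral-group member tags: rotation by k*90 degrees, optionally followed
#: by a horizontal flip.  "r0" is the identity view.
D4_TAGS = ("r0", "r90", "r180", "r270", "r0f", "r90f", "r180f", "r270f")


@dataclass
class Tile:
    """One square patch of a slide with provenance and split bookkeeping."""

    slide_id: str
    x: int
    y: int
    size: int
    pixels: np.ndarray | None = None
    label: str | None = None
    provenance: str = UNLABELED
    split: str = "none"
    augmentation_tag: str = "r0"

    @property
    def key(self) -> tuple:
        """Identity of the tile: slide, position, size and augmented view."""
        return (self.slide_id, self.x, self.y, self.size, self.augmentation_tag)


class TileDataset:
    """A collection of tiles with a class scheme and per-class counts."""

    def __init__(self, tiles: Sequence[Tile], scheme: ClassScheme = DEFAULT_SCHEME):
        self.tiles = list(tiles)
        self.scheme = scheme

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self) -> Iterator[Tile]:
        return iter(self.tiles)

    def __getitem__(self, i):
        return self.tiles[i]

    @property
    def class_counts(self) -> dict[str, int]:
        """Recount of labeled tiles by class, in scheme order."""
        c = Counter(t.label for t in self.tiles if t.label is not None)
        return {lab: c.get(lab, 0) for lab in self.scheme.labels if c.get(lab, 0)}

    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.tiles], dtype=object)

    def pixel_stack(self) -> np.ndarray:
        """Stack tile pixels into (n, H, W, C); tiles must share a size."""
        return np.stack([np.asarray(t.pixels) for t in self.tiles])


def count_tiles(roi_width: int, roi_height: int, tile_size: int, stride: int) -> int:
    """Number of stride-spaced tiles fully inside a ``roi_width x roi_height`` box.

    Closed form: ``(floor((W-T)/s)+1) * (floor((H-T)/s)+1)`` when both
    dimensions are at least the tile size, else 0.
    """
    if tile_size <= 0:
        raise ValueError(f"tile_size must be positive, got {tile_size}")
    if stride <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    if roi_width < tile_size or roi_height < tile_size:
        return 0
    nx = (roi_width - tile_size) // stride + 1
    ny = (roi_height - tile_size) // stride + 1
    return nx * ny


def _positions(length: int, tile_size: int, stride: int) -> range:
    if length < tile_size:
        return range(0)
    return range(0, length - tile_size + 1, stride)


def _stride(tile_size: int, overlap: float) -> int:
    stride = round(tile_size * (1.0 - overlap))
    if stride < 1:
        raise ValueError(
            f"overlap {overlap} with tile size {tile_size} gives stride < 1"
        )
    return stride


def _rect_contains(rx, ry, rw, rh, x, y, size) -> bool:
    return x >= rx and y >= ry and x + size <= rx + rw and y + size <= ry + rh


def _rect_intersects(rx, ry, rw, rh, x, y, size) -> bool:
    return x < rx + rw and rx < x + size and y < ry + rh and ry < y + size


def extract_roi_tiles(
    slide,
    tile_size: int = 512,
    overlap: float = 0.5,
    scheme: ClassScheme = DEFAULT_SCHEME,
    split: str = "none",
) -> TileDataset:
    """Extract labeled, overlapping tiles from every ROI of a slide.

    Each tile lies fully inside a single ROI and carries that ROI's label with
    ``provenance="ground_truth"``.  A tile that fits inside two ROIs of
    different classes is an annotation conflict and raises ``ValueError``.
    Tiles are ordered by (slide_id, y, x).
    """
    stride = _stride(tile_size, overlap)
    image = slide.image
    tiles: list[Tile] = []
    for i, roi in enumerate(slide.rois):
        if (
            roi.x < 0
            or roi.y < 0
            or roi.x + roi.width > slide.width
            or roi.y + roi.height > slide.height
        ):
            raise ValueError(
                f"ROI #{i} ({roi.x},{roi.y},{roi.width},{roi.height}) "
                f"outside slide {slide.slide_id!r} ({slide.width}x{slide.height})"
            )
        if roi.label not in scheme.labels:
            raise ValueError(f"ROI #{i} on {slide.slide_id!r}: unknown label {roi.label!r}")
        for y in _positions(roi.height, tile_size, stride):
            for x in _positions(roi.width, tile_size, stride):
                ax, ay = roi.x + x, roi.y + y
                for other in slide.rois:
                    if other.label != roi.label and _rect_contains(
                        other.x, other.y, other.width, other.height, ax, ay, tile_size
                    ):
                        raise ValueError(
                            f"tile at ({ax},{ay}) on {slide.slide_id!r} fits in "
                            f"ROIs of conflicting classes "
                            f"{roi.label!r} and {other.label!r}"
                        )
                pix = None
                if image is not None:
                    pix = image[ay : ay + tile_size, ax : ax + tile_size]
                tiles.append(
                    Tile(
                        slide_id=slide.slide_id,
                        x=ax,
                        y=ay,
                        size=tile_size,
                        pixels=pix,
                        label=roi.label,
                        provenance=GROUND_TRUTH,
                        split=split,
                    )
                )
    # de-duplicate same-class tiles produced by overlapping same-label ROIs
    seen: dict[tuple, Tile] = {}
    for t in tiles:
        seen.setdefault(t.key, t)
    ordered = sorted(seen.values(), key=lambda t: (t.slide_id, t.y, t.x))
    return TileDataset(ordered, scheme)


def grid_tiles(
    slide,
    tile_size: int = 512,
    overlap: float = 0.5,
    exclude_rois: bool = False,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> TileDataset:
    """Full-slide grid of unlabeled tiles for inference/pseudo-labeling.

    With ``exclude_rois`` set, any grid tile whose rectangle intersects an
    annotated ROI is dropped, leaving only tiles outside the annotations.
    """
    stride = _stride(tile_size, overlap)
    image = slide.image
    tiles = []
    for y in _positions(slide.height, tile_size, stride):
        for x in _positions(slide.width, tile_size, stride):
            if exclude_rois and any(
                _rect_intersects(r.x, r.y, r.width, r.height, x, y, tile_size)
                for r in slide.rois
            ):
                continue
            pix = None
            if image is not None:
                pix = image[y : y + tile_size, x : x + tile_size]
            tiles.append(
                Tile(
                    slide_id=slide.slide_id,
                    x=x,
                    y=y,
                    size=tile_size,
                    pixels=pix,
                    provenance=UNLABELED,
                )
            )
    return TileDataset(tiles, scheme)


def tissue_filter(
    dataset: TileDataset,
    min_foreground_fraction: float = 0.05,
    intensity_cutoff: float = 220.0,
) -> TileDataset:
    """Drop near-blank tiles.

    A pixel counts as foreground when its channel-mean intensity is below
    ``intensity_cutoff``; a tile is retained when its foreground fraction is
    >= ``min_foreground_fraction`` (inclusive).  Threshold 0 is a pass-through.
    """
    if not 0.0 <= min_foreground_fraction <= 1.0:
        raise ValueError("min_foreground_fraction must lie in [0, 1]")
    if min_foreground_fraction == 0.0:
        return TileDataset(list(dataset.tiles), dataset.scheme)
    kept = []
    for t in dataset:
        gray = np.asarray(t.pixels, dtype=np.float64).mean(axis=2)
        frac = float((gray < intensity_cutoff).mean())
        if frac >= min_foreground_fraction:
            kept.append(t)
    return TileDataset(kept, dataset.scheme)


def d4_views(pixels: np.ndarray) -> dict[str, np.ndarray]:
    """The 8 dihedral views of a square image, keyed by ``D4_TAGS``."""
    a = np.asarray(pixels)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"dihedral augmentation needs a square tile, got {a.shape}")
    out = {}
    for k in range(4):
        rot = np.rot90(a, k)
        out[D4_TAGS[k]] = rot
        out[D4_TAGS[k] + "f"] = np.fliplr(rot)
    return out


def apply_d4(pixels: np.ndarray, tag: str) -> np.ndarray:
    """Apply one dihedral view by tag (e.g. ``"r90f"``)."""
    if tag not in D4_TAGS:
        raise ValueError(f"unknown dihedral tag {tag!r}; expected one of {D4_TAGS}")
    k = int(tag.lstrip("r").rstrip("f")) // 90
    a = np.rot90(np.asarray(pixels), k)
    return np.fliplr(a) if tag.endswith("f") else a


def materialize(dataset: TileDataset, slides: dict) -> TileDataset:
    """Fill tile pixels by cropping slide images and applying the view tag.

    ``slides`` maps slide_id to a slide record with a loadable image.  Used
    to rebuild pixel data from a tile manifest without storing per-tile
    images.
    """
    out = []
    for t in dataset:
        if t.pixels is not None:
            out.append(t)
            continue
        slide = slides[t.slide_id]
        img = slide.load_image()
        crop = img[t.y : t.y + t.size, t.x : t.x + t.size]
        out.append(replace(t, pixels=apply_d4(crop, t.augmentation_tag)))
    return TileDataset(out, dataset.scheme)


def augment_d4(tile: Tile) -> list[Tile]:
    """The 8-member dihedral orbit of a tile (identity view included).

    All views keep the source tile's label, position and provenance.  Test
    tiles are never augmented: passing one is an error.  A pixel-free tile
    (manifest row) yields 8 tag-only replicas whose views are applied when
    the pixels are materialized from the slide image.
    """
    if tile.split == "test":
        raise ValueError(
            f"tile at ({tile.x},{tile.y}) on {tile.slide_id!r} is in the test "
            "split; augmentation is applied to training data only"
        )
    if tile.pixels is None:
        return [replace(tile, augmentation_tag=tag) for tag in D4_TAGS]
    views = d4_views(tile.pixels)
    return [replace(tile, pixels=v, augmentation_tag=tag) for tag, v in views.items()]


def augment_dataset(dataset: TileDataset) -> TileDataset:
    """Replace every non-test tile by its 8-view dihedral orbit.

    Test-split tiles pass through unchanged, so ground-truth training counts
    are multiplied by exactly 8 while the test set is untouched.
    """
    out: list[Tile] = []
    for t in dataset:
        if t.split == "test":
            out.append(t)
        else:
            out.extend(augment_d4(t))
    return TileDataset(out, dataset.scheme)


@dataclass
class ChannelStats:
    """Per-channel mean/std pooled over all pixels of a tile set."""

    mean: np.ndarray
    std: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if np.any(self.std <= 0):
            raise ValueError("channel std must be positive")

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelStats":
        return cls(np.array(d["mean"]), np.array(d["std"]), d.get("source", ""))


STD_EPSILON = 1e-6


def compute_channel_stats(
    tiles: Iterable[Tile] | np.ndarray, source: str = ""
) -> ChannelStats:
    """Pooled per-channel mean and standard deviation of a tile set.

    Equivalent to flattening every pixel of every tile into one pool per
    channel.  The standard deviation is floored at ``STD_EPSILON`` so constant
    channels stay normalizable.
    """
    if isinstance(tiles, np.ndarray):
        arrays = iter([tiles.reshape(-1, tiles.shape[-1])])
    else:
        arrays = (
            np.asarray(t.pixels if isinstance(t, Tile) else t).reshape(
                -1, np.asarray(t.pixels if isinstance(t, Tile) else t).shape[-1]
            )
            for t in tiles
        )
    n = 0
    s = None
    ss = None
    for a in arrays:
        a = a.astype(np.float64)
        n += a.shape[0]
        s = a.sum(axis=0) if s is None else s + a.sum(axis=0)
        ss = (a * a).sum(axis=0) if ss is None else ss + (a * a).sum(axis=0)
    if n == 0:
        raise ValueError("cannot compute channel statistics of an empty tile set")
    mean = s / n
    var = np.maximum(ss / n - mean * mean, 0.0)
    std = np.maximum(np.sqrt(var), STD_EPSILON)
    return ChannelStats(mean=mean, std=std, source=source)


def normalize_array(pixels: np.ndarray, stats: ChannelStats) -> np.ndarray:
    a = np.asarray(pixels, dtype=np.float64)
    if a.shape[-1] != stats.mean.shape[0]:
        raise ValueError(
            f"channel mismatch: image has {a.shape[-1]} channels, "
            f"stats have {stats.mean.shape[0]}"
        )
    return (a - stats.mean) / stats.std


def denormalize_array(pixels: np.ndarray, stats: ChannelStats) -> np.ndarray:
    a = np.asarray(pixels, dtype=np.float64)
    if a.shape[-1] != stats.mean.shape[0]:
        raise ValueError("channel mismatch")
    return a * stats.std + stats.mean


def normalize_tiles(dataset: TileDataset, stats: ChannelStats) -> TileDataset:
    """Standardize every tile per channel: ``(x - mean) / std``.

    The same training-split statistics must be applied to train and test data.
    """
    out = [replace(t, pixels=normalize_array(t.pixels, stats)) for t in dataset]
    return TileDataset(out, dataset.scheme)
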