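"""Slide-level aggregation of tile probabilities into class heatmaps.

Tile-level probability vectors are projected back onto slide coordinates on
the inference stride grid: each grid cell's per-class score is the unweighted
mean of the probability vectors of all tiles covering it, which keeps every
covered cell on the probability simplex.  Overlays highlight a class in red
over the slide image, and a slide summary reads the map into per-class area
fractions and a dominant tumor call (flagged inconclusive when the top two
tumor fractions are too close to separate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import PredictionRecord
from .scheme import DEFAULT_SCHEME, ClassScheme

__all__ = [
    "HeatmapGrid",
    "accumulate_tile_scores",
    "render_overlay",
    "save_overlay_figure",
    "slide_summary",
]


@dataclass
class HeatmapGrid:
    """Per-class score grids on the stride lattice of one slide.

    ``scores`` has shape (K, ny, nx) with NaN at uncovered cells; ``coverage``
    counts the tiles contributing to each cell.
    """

    slide_id: str
    cell_size: int
    labels: tuple[str, ...]
    scores: np.ndarray
    coverage: np.ndarray

    @property
    def covered(self) -> np.ndarray:
        return self.coverage > 0


def accumulate_tile_scores(
    predictions: Sequence[PredictionRecord],
    slide_width: int,
    slide_height: int,
    stride: int,
    tile_size: int,
    labels: Sequence[str] | None = None,
    slide_id: str | None = None,
) -> HeatmapGrid:
    """Average tile probability vectors onto the stride-cell grid.

    Every tile must sit on the stride lattice (coordinates divisible by the
    stride); a tile of size T covers ``T // stride`` cells per axis.  Cell
    scores are the mean over all covering tiles; cells no tile covers are
    NaN with coverage 0, never zero-filled.
    """
    if stride <= 0 or tile_size % stride != 0:
        raise ValueError("tile_size must be a positive multiple of stride")
    if not predictions:
        raise ValueError("no predictions to accumulate")
    if labels is None:
        labels = tuple(predictions[0].probabilities.keys())
    labels = tuple(labels)
    if slide_id is None:
        slide_id = predictions[0].tile.slide_id
    nx = slide_width // stride
    ny = slide_height // stride
    k = len(labels)
    span = tile_size // stride
    sums = np.zeros((k, ny, nx))
    cover = np.zeros((ny, nx), dtype=np.int64)
    for rec in predictions:
        t = rec.tile
        if t.slide_id != slide_id:
            raise ValueError(
                f"prediction for slide {t.slide_id!r} mixed into {slide_id!r}"
            )
        if t.x % stride or t.y % stride:
            raise ValueError(
                f"tile at ({t.x},{t.y}) is off the stride-{stride} grid"
            )
        cx, cy = t.x // stride, t.y // stride
        if cx + span > nx or cy + span > ny:
            raise ValueError(f"tile at ({t.x},{t.y}) exceeds the slide grid")
        p = np.array([rec.probabilities[lab] for lab in labels])
        sums[:, cy : cy + span, cx : cx + span] += p[:, None, None]
        cover[cy : cy + span, cx : cx + span] += 1
    scores = np.full_like(sums, np.nan)
    mask = cover > 0
    scores[:, mask] = sums[:, mask] / cover[mask]
    return HeatmapGrid(
        slide_id=slide_id,
        cell_size=stride,
        labels=labels,
        scores=scores,
        coverage=cover,
    )


def _upscale(grid2d: np.ndarray, cell: int, height: int, width: int) -> np.ndarray:
    """Nearest-neighbor upscale of a cell grid to pixel resolution."""
    up = np.repeat(np.repeat(grid2d, cell, axis=0), cell, axis=1)
    out = np.zeros((height, width))
    h, w = min(height, up.shape[0]), min(width, up.shape[1])
    out[:h, :w] = up[:h, :w]
    return out


def render_overlay(
    grid: HeatmapGrid,
    slide_image: np.ndarray,
    class_label: str,
    alpha: float = 0.4,
) -> np.ndarray:
    """Alpha-blend a red intensity proportional to the class score.

    Output has the slide's dimensions; uncovered regions and zero-score
    cells are left unshaded (identity), a score-1 cell is fully saturated at
    the given alpha.
    """
    if slide_image is None:
        raise ValueError("slide image is required to render an overlay")
    if class_label not in grid.labels:
        raise KeyError(f"class {class_label!r} not in heatmap labels {grid.labels}")
    k = grid.labels.index(class_label)
    img = np.asarray(slide_image, dtype=np.float64)
    h, w = img.shape[:2]
    score = np.nan_to_num(grid.scores[k], nan=0.0)
    s = _upscale(score, grid.cell_size, h, w)[..., None] * alpha
    red = np.zeros_like(img)
    red[..., 0] = 255.0
    out = (1.0 - s) * img + s * red
    return np.clip(out, 0, 255).astype(np.uint8)


def save_overlay_figure(
    path,
    grid: HeatmapGrid,
    slide_image: np.ndarray,
    class_label: str,
    alpha: float = 0.4,
) -> None:
    """Write the overlay as a PNG figure with a color bar and legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm as mpl_cm

    blended = render_overlay(grid, slide_image, class_label, alpha)
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(blended)
    ax.set_title(f"{grid.slide_id}: {class_label} score (alpha={alpha})")
    ax.set_axis_off()
    sm = mpl_cm.ScalarMappable(cmap="Reds")
    sm.set_clim(0.0, 1.0)
    fig.colorbar(sm, ax=ax, fraction=0.04, label=f"P({class_label})")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def slide_summary(
    grid: HeatmapGrid,
    scheme: ClassScheme = DEFAULT_SCHEME,
    margin: float = 0.1,
) -> dict:
    """Read the heatmap at slide level.

    Returns per-class argmax area fractions over covered cells (they sum to
    1), the dominant tumor call, and an ``inconclusive`` flag raised when the
    two largest tumor fractions differ by less than ``margin``.  Argmax ties
    resolve to the first label in scheme order.
    """
    mask = grid.covered
    n_cov = int(mask.sum())
    if n_cov == 0:
        raise ValueError(f"slide {grid.slide_id!r} has no covered cells")
    stacked = grid.scores[:, mask]
    arg = np.argmax(stacked, axis=0)
    fractions = {
        lab: float((arg == i).sum() / n_cov) for i, lab in enumerate(grid.labels)
    }
    tumor = [(lab, fractions[lab]) for lab in grid.labels if lab in scheme.tumor_labels]
    if not tumor:
        raise ValueError("scheme defines no tumor classes present in the heatmap")
    tumor.sort(key=lambda lf: -lf[1])
    call = tumor[0][0]
    inconclusive = len(tumor) > 1 and (tumor[0][1] - tumor[1][1]) < margin
    return {
        "slide_id": grid.slide_id,
        "fractions": fractions,
        "dominant_tumor_call": call,
        "inconclusive": bool(inconclusive),
        "covered_cells": n_cov,
    }
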