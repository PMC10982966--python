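"""Serialization: cohort images + JSON annotations, TSV manifests, reports.

On-disk layout of a cohort directory::

    cohort/
      images/slide_000.png ...
      annotations.json      # {"slides": [{slide_id, diagnosis, width, height,
                            #              rois: [{x, y, width, height, label}]}]}
      manifest.tsv          # slide_id, image_path, diagnosis, width, height

Coordinates are 0-based pixels; rectangles are half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import ROIAnnotation, SlideRecord
from .tiling import ChannelStats, Tile, TileDataset
from .scheme import DEFAULT_SCHEME, ClassScheme

__all__ = [
    "save_cohort",
    "load_cohort",
    "write_tile_manifest",
    "read_tile_manifest",
    "save_channel_stats",
    "load_channel_stats",
    "save_metrics_report",
]


def save_cohort(slides: list[SlideRecord], out_dir: str | Path) -> Path:
    """Write slide PNGs, the annotation JSON and the cohort manifest TSV."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    records = []
    rows = []
    for s in slides:
        img_path = out / "images" / f"{s.slide_id}.png"
        iio.imwrite(img_path, s.load_image())
        s.image_path = str(img_path)
        records.append(
            {
                "slide_id": s.slide_id,
                "diagnosis": s.diagnosis,
                "width": s.width,
                "height": s.height,
                "rois": [
                    {
                        "x": r.x,
                        "y": r.y,
                        "width": r.width,
                        "height": r.height,
                        "label": r.label,
                    }
                    for r in s.rois
                ],
            }
        )
        rows.append(
            {
                "slide_id": s.slide_id,
                "image_path": str(img_path),
                "diagnosis": s.diagnosis,
                "width": s.width,
                "height": s.height,
            }
        )
    with open(out / "annotations.json", "w") as fh:
        json.dump({"slides": records}, fh, indent=1)
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out


def load_cohort(cohort_dir: str | Path) -> list[SlideRecord]:
    """Read a cohort directory back into slide records (images lazy)."""
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "annotations.json") as fh:
        doc = json.load(fh)
    manifest = pd.read_csv(cohort_dir / "manifest.tsv", sep="\t")
    paths = dict(zip(manifest["slide_id"], manifest["image_path"]))
    slides = []
    for rec in doc["slides"]:
        slides.append(
            SlideRecord(
                slide_id=rec["slide_id"],
                width=int(rec["width"]),
                height=int(rec["height"]),
                diagnosis=rec["diagnosis"],
                rois=[
                    ROIAnnotation(
                        x=int(r["x"]),
                        y=int(r["y"]),
                        width=int(r["width"]),
                        height=int(r["height"]),
                        label=r["label"],
                    )
                    for r in rec["rois"]
                ],
                image_path=paths.get(rec["slide_id"]),
            )
        )
    return slides


_MANIFEST_COLUMNS = [
    "tile_path",
    "slide_id",
    "x",
    "y",
    "size",
    "label",
    "provenance",
    "split",
    "augmentation_tag",
]


def write_tile_manifest(
    dataset: TileDataset,
    path: str | Path,
    tiles_dir: str | Path | None = None,
) -> Path:
    """Write a tile manifest TSV; optionally save tile pixels as PNGs."""
    path = Path(path)
    rows = []
    for i, t in enumerate(dataset):
        tile_path = ""
        if tiles_dir is not None:
            tiles_dir = Path(tiles_dir)
            tiles_dir.mkdir(parents=True, exist_ok=True)
            tile_path = str(
                tiles_dir
                / f"{t.slide_id}_x{t.x}_y{t.y}_{t.augmentation_tag}.png"
            )
            pix = np.asarray(t.pixels)
            if pix.dtype != np.uint8:
                pix = np.clip(pix, 0, 255).astype(np.uint8)
            iio.imwrite(tile_path, np.ascontiguousarray(pix))
        rows.append(
            {
                "tile_path": tile_path,
                "slide_id": t.slide_id,
                "x": t.x,
                "y": t.y,
                "size": t.size,
                "label": "" if t.label is None else t.label,
                "provenance": t.provenance,
                "split": t.split,
                "augmentation_tag": t.augmentation_tag,
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_tile_manifest(
    path: str | Path,
    scheme: ClassScheme = DEFAULT_SCHEME,
    load_pixels: bool = False,
) -> TileDataset:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    tiles = []
    for rec in df.itertuples(index=False):
        pixels = None
        if load_pixels and rec.tile_path:
            pixels = np.asarray(iio.imread(rec.tile_path))
        tiles.append(
            Tile(
                slide_id=str(rec.slide_id),
                x=int(rec.x),
                y=int(rec.y),
                size=int(rec.size),
                pixels=pixels,
                label=rec.label or None,
                provenance=rec.provenance,
                split=rec.split,
                augmentation_tag=rec.augmentation_tag,
            )
        )
    return TileDataset(tiles, scheme)


def save_channel_stats(stats: ChannelStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(stats.to_dict(), fh, indent=1)


def load_channel_stats(path: str | Path) -> ChannelStats:
    with open(path) as fh:
        return ChannelStats.from_dict(json.load(fh))


def save_metrics_report(report, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
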