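"""File-based pipeline stages tying the whole workflow together.

Each stage reads its inputs from and writes its artifacts to a run directory,
so the full driver (:func:`run_pipeline`) and the CLI subcommands executed in
order produce identical results.  Every run records a manifest with the
config snapshot, its hash, the seed, per-stage timings and tile counts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as gio
from .classifier import (
    TileClassifier,
    fit_classifier,
    load_classifier,
    predict_records,
    save_classifier,
)
from .config import RunConfig
from .evaluation import confusion_matrix, metrics_report
from .heatmap import accumulate_tile_scores, save_overlay_figure, slide_summary
from .scheme import DEFAULT_SCHEME
from .semi_supervised import PseudoLabelPolicy, merge_datasets, pseudo_label_filter
from .synthetic import SyntheticConfig, generate_cohort, split_cohort
from .tiling import (
    TileDataset,
    augment_dataset,
    extract_roi_tiles,
    grid_tiles,
    materialize,
    tissue_filter,
)

logger = logging.getLogger("gliotile")

__all__ = ["run_pipeline", "STAGES"]


def _update_manifest(run: Path, stage: str, info: dict) -> None:
    path = run / "run_manifest.json"
    doc = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    doc["stages"][stage] = info
    path.write_text(json.dumps(doc, indent=1))


def _load_slides(run: Path):
    slides = gio.load_cohort(run / "cohort")
    with open(run / "splits.json") as fh:
        splits = json.load(fh)
    by_id = {s.slide_id: s for s in slides}
    train = [by_id[i] for i in splits["train"]]
    test = [by_id[i] for i in splits["test"]]
    return by_id, train, test


def _classifier_params(cfg: RunConfig, seed_offset: int = 0) -> dict:
    t = cfg.training
    return dict(
        backbone=t.backbone,
        epochs=t.epochs,
        batch_size=t.batch_size,
        learning_rate=t.learning_rate,
        validation_fraction=t.validation_fraction,
        class_weight=t.class_weight,
        selection_metric=t.selection_metric,
        random_state=cfg.seed + seed_offset,
    )


def stage_synth(cfg: RunConfig, run: Path) -> None:
    run.mkdir(parents=True, exist_ok=True)
    (run / "config.json").write_text(json.dumps(cfg.to_dict(), indent=1))
    syn = SyntheticConfig(
        n_slides=cfg.synth.n_slides,
        block_grid=tuple(cfg.synth.block_grid),
        tile_size=cfg.synth.tile_size,
        difficulty=cfg.synth.difficulty,
        annotated_fraction=cfg.synth.annotated_fraction,
        seed=cfg.seed,
    )
    cohort = generate_cohort(syn)
    gio.save_cohort(cohort.slides, run / "cohort")
    train, test = split_cohort(cohort.slides, cfg.synth.test_fraction, cfg.seed)
    (run / "splits.json").write_text(
        json.dumps(
            {
                "train": [s.slide_id for s in train],
                "test": [s.slide_id for s in test],
                "realized_tile_shares": cohort.realized_tile_shares,
                "max_relative_share_deviation": cohort.max_relative_share_deviation,
            },
            indent=1,
        )
    )
    logger.info("synth: %d slides (%d train / %d test)", len(cohort.slides), len(train), len(test))


def stage_tile(cfg: RunConfig, run: Path) -> None:
    _, train, test = _load_slides(run)
    T, ov = cfg.synth.tile_size, cfg.tiling.overlap
    gt = TileDataset(
        [t for s in train for t in extract_roi_tiles(s, T, ov, split="train")]
    )
    if cfg.tiling.augment:
        gt = augment_dataset(gt)
    gio.write_tile_manifest(gt, run / "tiles_train.tsv")
    test_ds = TileDataset(
        [t for s in test for t in extract_roi_tiles(s, T, ov, split="test")]
    )
    gio.write_tile_manifest(test_ds, run / "tiles_test.tsv")
    logger.info(
        "tile: %d training tiles (%s), %d test tiles",
        len(gt),
        gt.class_counts,
        len(test_ds),
    )


def _fit_from_manifest(cfg: RunConfig, run: Path, manifest: str, out: str, seed_offset: int):
    by_id, _, _ = _load_slides(run)
    ds = gio.read_tile_manifest(run / manifest)
    ds = materialize(ds, by_id)
    clf = fit_classifier(ds, **_classifier_params(cfg, seed_offset))
    save_classifier(clf, run / out)
    gio.save_channel_stats(clf.channel_stats_, run / out / "channel_stats.json")
    logger.info(
        "%s: best epoch %d, validation balanced accuracy %.4f",
        out,
        clf.best_epoch_,
        clf.history_[clf.best_epoch_]["val_balanced_accuracy"],
    )
    return clf


def stage_train(cfg: RunConfig, run: Path) -> None:
    _fit_from_manifest(cfg, run, "tiles_train.tsv", "step1", seed_offset=0)


def stage_pseudo(cfg: RunConfig, run: Path) -> None:
    by_id, train, _ = _load_slides(run)
    clf = load_classifier(run / "step1")
    T, ov = cfg.synth.tile_size, cfg.tiling.overlap
    grid = TileDataset(
        [t for s in train for t in grid_tiles(s, T, ov, exclude_rois=True)]
    )
    grid = tissue_filter(grid, cfg.tiling.min_foreground_fraction)
    grid = materialize(grid, by_id)
    predictions = predict_records(clf, grid)
    policy = PseudoLabelPolicy(
        confidence_threshold=cfg.pseudo.confidence_threshold,
        enforce_diagnosis=cfg.pseudo.enforce_diagnosis,
        augment_pseudo=cfg.pseudo.augment_pseudo,
    )
    diagnoses = {s.slide_id: s.diagnosis for s in train}
    pseudo, log = pseudo_label_filter(
        predictions, diagnoses, policy, return_log=True
    )
    # pseudo-label manifest with per-record decisions
    import pandas as pd

    rows = [
        {
            "tile_path": "",
            "slide_id": rec.tile.slide_id,
            "x": rec.tile.x,
            "y": rec.tile.y,
            "predicted_label": rec.predicted_label,
            "confidence": rec.confidence,
            "retained": int(kept),
            "rejection_reason": reason,
        }
        for rec, kept, reason in log
    ]
    pd.DataFrame(rows).to_csv(run / "pseudo.tsv", sep="\t", index=False)
    gt = gio.read_tile_manifest(run / "tiles_train.tsv")
    if policy.augment_pseudo:
        pseudo = augment_dataset(materialize(pseudo, by_id))
    merged = merge_datasets(gt, pseudo)
    gio.write_tile_manifest(merged, run / "tiles_merged.tsv")
    logger.info(
        "pseudo: %d/%d tiles retained (%s); merged size %d (x%.2f)",
        len(pseudo),
        len(predictions),
        pseudo.class_counts,
        len(merged),
        len(merged) / max(len(gt), 1),
    )


def stage_retrain(cfg: RunConfig, run: Path) -> None:
    _fit_from_manifest(cfg, run, "tiles_merged.tsv", "step2", seed_offset=1)


def _evaluate_step(cfg: RunConfig, run: Path, step: str) -> None:
    by_id, _, _ = _load_slides(run)
    clf = load_classifier(run / step)
    test = materialize(gio.read_tile_manifest(run / "tiles_test.tsv"), by_id)
    y_true = [t.label for t in test]
    y_pred = clf.predict([t.pixels for t in test])
    cm = confusion_matrix(y_true, list(y_pred))
    report = metrics_report(cm)
    gio.save_metrics_report(report, run / f"metrics_{step}.json")
    cm.to_frame().to_csv(run / f"confusion_{step}.tsv", sep="\t")
    logger.info(
        "eval %s: balanced accuracy %.4f, macro F1 %.4f",
        step,
        report.balanced_accuracy,
        report.macro.f1,
    )


def stage_eval(cfg: RunConfig, run: Path) -> None:
    _evaluate_step(cfg, run, "step1")
    if (run / "step2").exists():
        _evaluate_step(cfg, run, "step2")


def stage_heatmap(cfg: RunConfig, run: Path) -> None:
    by_id, _, test = _load_slides(run)
    step = "step2" if (run / "step2").exists() else "step1"
    clf = load_classifier(run / step)
    T, ov = cfg.synth.tile_size, cfg.tiling.overlap
    stride = round(T * (1 - ov))
    out = run / "heatmaps"
    out.mkdir(exist_ok=True)
    summaries = []
    for s in test:
        grid = materialize(grid_tiles(s, T, ov), by_id)
        preds = predict_records(clf, grid)
        hm = accumulate_tile_scores(preds, s.width, s.height, stride, T)
        summary = slide_summary(hm)
        summary["true_diagnosis"] = s.diagnosis
        summaries.append(summary)
        save_overlay_figure(
            out / f"{s.slide_id}_{summary['dominant_tumor_call']}.png",
            hm,
            s.load_image(),
            summary["dominant_tumor_call"],
            alpha=cfg.heatmap.alpha,
        )
    (out / "summaries.json").write_text(json.dumps(summaries, indent=1))
    logger.info("heatmap: %d slide summaries written (%s)", len(summaries), step)


STAGES = {
    "synth": stage_synth,
    "tile": stage_tile,
    "train": stage_train,
    "pseudo": stage_pseudo,
    "retrain": stage_retrain,
    "eval": stage_eval,
    "heatmap": stage_heatmap,
}


def run_pipeline(cfg: RunConfig, run_dir: str | Path) -> Path:
    """Execute all stages in order; a stage failure halts with its name.

    With ``pseudo.enabled`` off, the pseudo/retrain stages are skipped and
    only step-1 artifacts are produced.  Heatmaps are optional likewise.
    """
    run = Path(run_dir)
    order = ["synth", "tile", "train"]
    if cfg.pseudo.enabled:
        order += ["pseudo", "retrain"]
    order += ["eval"]
    if cfg.heatmap.enabled:
        order += ["heatmap"]
    for name in order:
        t0 = time.perf_counter()
        try:
            STAGES[name](cfg, run)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        _update_manifest(
            run,
            name,
            {
                "seconds": round(time.perf_counter() - t0, 3),
                "seed": cfg.seed,
                "config_hash": cfg.config_hash,
            },
        )
    return run
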