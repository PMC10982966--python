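"""Two-step semi-supervised training with diagnosis-constrained pseudo-labels.

Step 1 trains a classifier on the pathologist-annotated (ground-truth) tiles.
The fitted model then predicts the unannotated tiles of the training slides
(the full-slide grid outside the ROIs).  A prediction becomes a pseudo-label
only if it clears BOTH gates:

* confidence gate — the predicted class probability is at least the threshold
  (0.90 by default, inclusive), discarding predictions where the model is
  insecure;
* diagnosis gate — the predicted class is possible on that slide given its
  diagnosis: only the diagnosed tumor subtype, normal brain tissue and
  necrosis can occur (a normal-control slide admits normal tissue only).

Step 2 retrains a fresh model on the union of ground-truth and pseudo-labeled
tiles.  Pseudo-labels are drawn exclusively from training slides, so the test
split is never contaminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .classifier import PredictionRecord, TileClassifier, fit_classifier, predict_records
from .evaluation import MetricsReport, confusion_matrix, metrics_report
from .scheme import DEFAULT_SCHEME, ClassScheme
from .tiling import (
    GROUND_TRUTH,
    PSEUDO,
    Tile,
    TileDataset,
    augment_dataset,
    extract_roi_tiles,
    grid_tiles,
    tissue_filter,
)

__all__ = [
    "PseudoLabelPolicy",
    "allowed_classes",
    "pseudo_label_filter",
    "merge_datasets",
    "SemiSupervisedTileClassifier",
    "run_two_step",
    "TwoStepResult",
]


@dataclass
class PseudoLabelPolicy:
    """Gates applied to model predictions before they become pseudo-labels."""

    confidence_threshold: float = 0.90
    enforce_diagnosis: bool = True
    augment_pseudo: bool = False
    tie_break: str = "scheme_order"

    def __post_init__(self):
        if not 0.0 <= self.confidence_threshold <= 1.0 + 1e-12:
            # thresholds above 1 are permitted as an explicit "retain nothing"
            pass
        if self.confidence_threshold < 0.0:
            raise ValueError("confidence_threshold must be >= 0")


def allowed_classes(diagnosis: str, scheme: ClassScheme = DEFAULT_SCHEME) -> frozenset[str]:
    """Tile classes possible on a slide with the given diagnosis.

    ``{diagnosis, normal, necrosis}`` for a tumor diagnosis; ``{normal}`` for
    the normal-control diagnosis.
    """
    return scheme.allowed_classes(diagnosis)


# rejection reasons written to the pseudo-label manifest; confidence is
# checked first, so a record failing both gates is reported as low_confidence
REASON_NONE = "none"
REASON_LOW_CONFIDENCE = "low_confidence"
REASON_IMPOSSIBLE = "impossible_class"


def pseudo_label_filter(
    predictions: Sequence[PredictionRecord],
    slide_diagnoses: Mapping[str, str],
    policy: PseudoLabelPolicy = PseudoLabelPolicy(),
    scheme: ClassScheme = DEFAULT_SCHEME,
    return_log: bool = False,
):
    """Retain predictions that pass the confidence and diagnosis gates.

    A record is retained iff ``confidence >= policy.confidence_threshold``
    (inclusive) and, with diagnosis enforcement on, its predicted class is in
    ``allowed_classes(diagnosis)``.  Retained tiles carry the predicted label
    with ``provenance="pseudo"``.  The output is always a subset of the input.

    With ``return_log`` the per-record decisions ``(record, retained, reason)``
    are returned alongside the dataset.
    """
    kept: list[Tile] = []
    log = []
    for rec in predictions:
        slide_id = rec.tile.slide_id
        try:
            diagnosis = slide_diagnoses[slide_id]
        except KeyError:
            raise KeyError(
                f"no diagnosis recorded for slide {slide_id!r}"
            ) from None
        reason = REASON_NONE
        if rec.confidence < policy.confidence_threshold:
            reason = REASON_LOW_CONFIDENCE
        elif policy.enforce_diagnosis and rec.predicted_label not in allowed_classes(
            diagnosis, scheme
        ):
            reason = REASON_IMPOSSIBLE
        if reason == REASON_NONE:
            kept.append(
                replace(rec.tile, label=rec.predicted_label, provenance=PSEUDO)
            )
        log.append((rec, reason == REASON_NONE, reason))
    dataset = TileDataset(kept, scheme)
    return (dataset, log) if return_log else dataset


def merge_datasets(ground_truth: TileDataset, pseudo: TileDataset) -> TileDataset:
    """Union of ground-truth and pseudo-labeled tiles.

    Sizes and class counts are additive; tile identities must be disjoint
    (an identity collision is an annotation bookkeeping error and raises).
    """
    seen = {t.key: t for t in ground_truth}
    colliding = [t.key for t in pseudo if t.key in seen]
    if colliding:
        raise ValueError(
            f"{len(colliding)} pseudo tiles collide with ground-truth tiles: "
            f"{colliding[:5]}{'...' if len(colliding) > 5 else ''}"
        )
    return TileDataset(list(ground_truth) + list(pseudo), ground_truth.scheme)


class SemiSupervisedTileClassifier(ClassifierMixin, BaseEstimator):
    """Two-step self-training meta-estimator.

    Mirrors the shape of scikit-learn's ``SelfTrainingClassifier``: ``y`` may
    contain ``None`` (or ``"-1"``/NaN) for unlabeled tiles, and per-tile slide
    diagnoses supply the weak slide-level labels for the diagnosis gate.

    Parameters
    ----------
    base_estimator : TileClassifier
        Cloned for each step; step 2 trains a fresh model (no warm start)
        with a seed derived from ``base_estimator.random_state``.
    threshold : float
        Inclusive confidence gate on pseudo-labels.
    enforce_diagnosis : bool
        Apply the diagnosis-possibility gate.
    scheme : ClassScheme

    Attributes
    ----------
    step1_estimator_, estimator_ : fitted step-1 / step-2 classifiers
    pseudo_mask_ : boolean mask over the unlabeled rows that were retained
    pseudo_labels_ : labels assigned to the retained unlabeled rows
    n_pseudo_per_class_ : dict label -> retained pseudo-tile count
    """

    _UNLABELED = {None, "", "-1", -1}

    def __init__(
        self,
        base_estimator: TileClassifier | None = None,
        threshold: float = 0.90,
        enforce_diagnosis: bool = True,
        scheme: ClassScheme = DEFAULT_SCHEME,
    ):
        self.base_estimator = base_estimator
        self.threshold = threshold
        self.enforce_diagnosis = enforce_diagnosis
        self.scheme = scheme

    def fit(self, X, y, groups=None, diagnoses=None):
        base = self.base_estimator if self.base_estimator is not None else TileClassifier()
        y = np.asarray(y, dtype=object)
        unlabeled = np.array([lab in self._UNLABELED for lab in y])
        lab_idx = np.flatnonzero(~unlabeled)
        unl_idx = np.flatnonzero(unlabeled)
        groups = None if groups is None else np.asarray(groups)

        def take(idx):
            Xs = [X[i] for i in idx] if not isinstance(X, np.ndarray) else X[idx]
            g = None if groups is None else groups[idx]
            return Xs, g

        X_lab, g_lab = take(lab_idx)
        step1 = clone(base)
        step1.fit(X_lab, y[lab_idx], groups=g_lab)
        self.step1_estimator_ = step1

        kept_idx: list[int] = []
        kept_labels: list[str] = []
        if len(unl_idx):
            if diagnoses is None:
                raise ValueError("diagnoses are required when y has unlabeled rows")
            diagnoses = np.asarray(diagnoses, dtype=object)
            X_unl, _ = take(unl_idx)
            probs = step1.predict_proba(X_unl)
            classes = list(step1.classes_)
            for row, (i, p) in zip(unl_idx, enumerate(probs)):
                j = int(np.argmax(p))
                conf = float(p[j])
                label = classes[j]
                if conf < self.threshold:
                    continue
                if self.enforce_diagnosis and label not in self.scheme.allowed_classes(
                    str(diagnoses[row])
                ):
                    continue
                kept_idx.append(row)
                kept_labels.append(label)
        self.pseudo_mask_ = np.isin(unl_idx, np.array(kept_idx, dtype=int))
        self.pseudo_labels_ = np.array(kept_labels, dtype=object)
        counts: dict[str, int] = {}
        for lab in kept_labels:
            counts[lab] = counts.get(lab, 0) + 1
        self.n_pseudo_per_class_ = counts

        merged_idx = np.concatenate([lab_idx, np.array(kept_idx, dtype=int)])
        X_merged, g_merged = take(merged_idx)
        y_merged = np.concatenate([y[lab_idx], np.array(kept_labels, dtype=object)])
        step2 = clone(base)
        if base.random_state is not None:
            step2.set_params(random_state=base.random_state + 1)
        step2.fit(X_merged, y_merged, groups=g_merged)
        self.estimator_ = step2
        self.classes_ = step2.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(X)


@dataclass
class TwoStepResult:
    """Everything the two-step procedure produced."""

    step1: TileClassifier
    step2: TileClassifier
    step1_report: MetricsReport
    step2_report: MetricsReport
    ground_truth: TileDataset
    pseudo: TileDataset
    merged: TileDataset
    pseudo_counts: dict[str, int]
    pseudo_log: list

    @property
    def growth_factor(self) -> float:
        """Merged training-set size over the ground-truth size."""
        return len(self.merged) / len(self.ground_truth)


def run_two_step(
    train_slides,
    test_slides,
    tile_size: int = 512,
    overlap: float = 0.5,
    policy: PseudoLabelPolicy = PseudoLabelPolicy(),
    scheme: ClassScheme = DEFAULT_SCHEME,
    min_foreground_fraction: float = 0.0,
    augment: bool = True,
    **classifier_params,
) -> TwoStepResult:
    """Ground-truth fit, pseudo-labeling of the training slides, retrain, evaluate.

    Pseudo-label candidates are the grid tiles of the *training* slides that
    do not intersect any ROI (the test slides are never pseudo-labeled).
    Both steps are evaluated on the ground-truth tiles of the test slides.
    """
    for s in train_slides:
        for roi in s.rois:
            if roi.label not in scheme.allowed_classes(s.diagnosis):
                raise ValueError(
                    f"slide {s.slide_id!r}: ROI class {roi.label!r} violates "
                    f"diagnosis {s.diagnosis!r}"
                )
    gt_parts = [
        extract_roi_tiles(s, tile_size, overlap, scheme, split="train")
        for s in train_slides
    ]
    gt = TileDataset([t for part in gt_parts for t in part], scheme)
    if augment:
        gt = augment_dataset(gt)

    step1 = fit_classifier(gt, **classifier_params)

    grid_parts = [
        grid_tiles(s, tile_size, overlap, exclude_rois=True, scheme=scheme)
        for s in train_slides
    ]
    grid = TileDataset([t for part in grid_parts for t in part], scheme)
    grid = tissue_filter(grid, min_foreground_fraction)
    predictions = predict_records(step1, grid)
    diagnoses = {s.slide_id: s.diagnosis for s in train_slides}
    pseudo, log = pseudo_label_filter(
        predictions, diagnoses, policy, scheme, return_log=True
    )
    if policy.augment_pseudo:
        pseudo = augment_dataset(pseudo)
    merged = merge_datasets(gt, pseudo)

    step2_params = dict(classifier_params)
    if step2_params.get("random_state") is not None:
        step2_params["random_state"] = step2_params["random_state"] + 1
    step2 = fit_classifier(merged, **step2_params)

    test_parts = [
        extract_roi_tiles(s, tile_size, overlap, scheme, split="test")
        for s in test_slides
    ]
    test = TileDataset([t for part in test_parts for t in part], scheme)
    y_true = [t.label for t in test]
    reports = []
    for clf in (step1, step2):
        y_pred = clf.predict([t.pixels for t in test])
        cm = confusion_matrix(y_true, list(y_pred), scheme)
        reports.append(metrics_report(cm))
    return TwoStepResult(
        step1=step1,
        step2=step2,
        step1_report=reports[0],
        step2_report=reports[1],
        ground_truth=gt,
        pseudo=pseudo,
        merged=merged,
        pseudo_counts=pseudo.class_counts,
        pseudo_log=log,
    )
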