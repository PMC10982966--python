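"""Tile classifier: class-weighted training with best-epoch selection.

The estimator follows the scikit-learn conventions (``fit`` /
``predict_proba`` / ``get_params``) and trains a small, pluggable backbone
with inverse-frequency class-weighted categorical cross-entropy.  A held-out
validation split — grouped by slide so correlated tiles never straddle the
split — selects the best-performing epoch, whose weights are kept.

The default backbone is a pooled-feature multilayer perceptron: each tile is
summarized by a coarse grid of per-channel mean colors plus per-channel
standard deviations, and a one-hidden-layer softmax network is trained on
those features with Adam.  Heavier backbones can be plugged in through the
registry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import GroupShuffleSplit, StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted

from .tiling import ChannelStats, TileDataset, compute_channel_stats

__all__ = [
    "class_weights",
    "weighted_cross_entropy",
    "PooledMLPBackbone",
    "register_backbone",
    "get_backbone",
    "ChannelNormalizer",
    "TileClassifier",
    "PredictionRecord",
    "fit_classifier",
    "predict_records",
]


def class_weights(
    class_counts: Mapping[str, int], exact: bool = False
) -> dict[str, float | Fraction]:
    """Inverse-frequency class weights ``w_c = N / (K * n_c)``.

    ``N`` is the total tile count and ``K`` the number of classes present, so
    the weights have mean 1 under the class frequencies and the total
    training weight is conserved: ``sum_c n_c * w_c = N``.  With
    ``exact=True`` the weights are returned as ``fractions.Fraction`` so the
    conservation identity holds in rational arithmetic.
    """
    zero = [c for c, n in class_counts.items() if n <= 0]
    if zero:
        raise ValueError(
            f"classes with zero tiles must be dropped explicitly: {sorted(zero)}"
        )
    if not class_counts:
        raise ValueError("class_counts is empty")
    n_total = sum(class_counts.values())
    k = len(class_counts)
    if exact:
        return {c: Fraction(n_total, k * n) for c, n in class_counts.items()}
    return {c: n_total / (k * n) for c, n in class_counts.items()}


_P_FLOOR = 1e-12


def weighted_cross_entropy(
    probabilities: np.ndarray,
    true_labels,
    weights: Mapping[str, float] | np.ndarray,
    classes: Sequence[str] | None = None,
) -> float:
    """Class-weighted categorical cross-entropy, averaged over tiles.

    Per tile the loss is ``-w_y * log(p_y)`` with the true-class probability
    clipped to ``[1e-12, 1]``; the batch loss is the mean.  Accepts a single
    probability vector or an ``(n, K)`` batch; ``true_labels`` may be label
    strings (with ``classes`` giving the column order) or column indices.
    """
    p = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    n, k = p.shape
    y = np.atleast_1d(np.asarray(true_labels))
    if y.shape[0] != n:
        raise ValueError("probabilities and true_labels disagree in length")
    if y.dtype.kind in "OU":
        if classes is None:
            raise ValueError("classes must be given when labels are strings")
        lookup = {c: i for i, c in enumerate(classes)}
        try:
            idx = np.array([lookup[lab] for lab in y])
        except KeyError as e:
            raise ValueError(f"label {e.args[0]!r} outside the class scheme") from None
    else:
        idx = y.astype(int)
        if np.any(idx < 0) or np.any(idx >= k):
            raise ValueError("label index outside the class scheme")
    if isinstance(weights, Mapping):
        if classes is None:
            raise ValueError("classes must be given with a weight mapping")
        w = np.array([float(weights[c]) for c in classes])
    else:
        w = np.asarray(weights, dtype=np.float64)
    p_true = np.clip(p[np.arange(n), idx], _P_FLOOR, 1.0)
    return float(np.mean(-w[idx] * np.log(p_true)))


# ---------------------------------------------------------------------------
# backbone registry


class PooledMLPBackbone:
    """Pooled-color features plus a one-hidden-layer softmax network.

    Features per tile: channel means over a ``pool_grid x pool_grid``
    partition of the tile (3 * grid^2 values) plus the per-channel standard
    deviation over all pixels (3 values).  The network is
    ``features -> ReLU(hidden) -> softmax`` trained with Adam.
    """

    def __init__(self, pool_grid: int = 4, hidden_units: int = 64):
        self.pool_grid = int(pool_grid)
        self.hidden_units = int(hidden_units)

    # -- features ----------------------------------------------------------
    def batch_features(self, batch: np.ndarray) -> np.ndarray:
        """Feature matrix for one same-shape ``(n, H, W, C)`` batch."""
        return self._batch_features(batch)

    def _batch_features(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        n, h, w, c = batch.shape
        g = self.pool_grid
        rows = np.linspace(0, h, g + 1).astype(int)
        cols = np.linspace(0, w, g + 1).astype(int)
        sums = np.add.reduceat(batch, rows[:-1], axis=1)
        sums = np.add.reduceat(sums, cols[:-1], axis=2)
        areas = np.outer(np.diff(rows), np.diff(cols))[None, :, :, None]
        pooled = (sums / areas).reshape(n, -1)
        stds = batch.std(axis=(1, 2)).reshape(n, -1)
        return np.concatenate([pooled, stds], axis=1)

    def extract_features(self, tiles, chunk: int = 512) -> np.ndarray:
        """Feature matrix for an ``(n, H, W, C)`` array or list of arrays."""
        if isinstance(tiles, np.ndarray) and tiles.ndim == 4:
            arrays = tiles
            out = [
                self._batch_features(arrays[i : i + chunk])
                for i in range(0, len(arrays), chunk)
            ]
            return np.concatenate(out, axis=0)
        feats = []
        buf: list[np.ndarray] = []
        shape = None
        for t in tiles:
            a = np.asarray(t)
            if shape is not None and (a.shape != shape or len(buf) >= chunk):
                feats.append(self._batch_features(np.stack(buf)))
                buf = []
            shape = a.shape
            buf.append(a)
        if buf:
            feats.append(self._batch_features(np.stack(buf)))
        if not feats:
            raise ValueError("no tiles to extract features from")
        return np.concatenate(feats, axis=0)

    @property
    def n_features(self) -> int:
        return 3 * self.pool_grid**2 + 3

    # -- network -----------------------------------------------------------
    def init_params(self, n_features: int, n_classes: int, rng) -> dict:
        h = self.hidden_units
        return {
            "W1": rng.standard_normal((n_features, h)) * np.sqrt(2.0 / n_features),
            "b1": np.zeros(h),
            "W2": rng.standard_normal((h, n_classes)) * np.sqrt(2.0 / h),
            "b2": np.zeros(n_classes),
        }

    def forward(self, params: dict, F: np.ndarray, keep: bool = False):
        z1 = F @ params["W1"] + params["b1"]
        a1 = np.maximum(z1, 0.0)
        logits = a1 @ params["W2"] + params["b2"]
        return (logits, a1) if keep else logits

    def backward(
        self, params: dict, F: np.ndarray, a1: np.ndarray, dlogits: np.ndarray
    ) -> dict:
        grads = {
            "W2": a1.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        da1 = dlogits @ params["W2"].T
        da1[a1 <= 0.0] = 0.0
        grads["W1"] = F.T @ da1
        grads["b1"] = da1.sum(axis=0)
        return grads


_BACKBONES: dict[str, type] = {"pooled-mlp": PooledMLPBackbone}


def register_backbone(name: str, factory: type) -> None:
    """Register a backbone class under a name usable by ``TileClassifier``."""
    _BACKBONES[name] = factory


def get_backbone(name: str, **kwargs):
    try:
        return _BACKBONES[name](**kwargs)
    except KeyError:
        raise KeyError(
            f"unknown backbone {name!r}; registered: {sorted(_BACKBONES)}"
        ) from None


def _iter_pixel_chunks(X, chunk: int = 512):
    """Yield same-shape ``(m, H, W, C)`` batches from an array or iterable."""
    if isinstance(X, np.ndarray) and X.ndim == 4:
        for i in range(0, len(X), chunk):
            yield X[i : i + chunk]
        return
    buf: list[np.ndarray] = []
    shape = None
    for a in X:
        a = np.asarray(a)
        if buf and (a.shape != shape or len(buf) >= chunk):
            yield np.stack(buf)
            buf = []
        shape = a.shape
        buf.append(a)
    if buf:
        yield np.stack(buf)


def _select(X, idx):
    if isinstance(X, np.ndarray) and X.ndim == 4:
        return X[idx]
    return [X[i] for i in idx]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# estimators


class ChannelNormalizer(TransformerMixin, BaseEstimator):
    """Per-channel standardization of image batches.

    Fit on the training tiles only; ``transform`` subtracts the per-channel
    mean and divides by the per-channel standard deviation (epsilon-floored),
    applied identically to train and test data.
    """

    def fit(self, X, y=None):
        stats = compute_channel_stats(np.asarray(X, dtype=np.float64))
        self.mean_ = stats.mean
        self.std_ = stats.std
        self.stats_ = stats
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        a = np.asarray(X, dtype=np.float64)
        if a.shape[-1] != self.mean_.shape[0]:
            raise ValueError(
                f"channel mismatch: got {a.shape[-1]}, fitted {self.mean_.shape[0]}"
            )
        return (a - self.mean_) / self.std_

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        return np.asarray(X, dtype=np.float64) * self.std_ + self.mean_


@dataclass
class PredictionRecord:
    """Per-tile probability vector with its argmax and confidence."""

    tile: object
    probabilities: dict[str, float]
    predicted_label: str
    confidence: float

    @classmethod
    def from_proba(cls, tile, proba: np.ndarray, classes: Sequence[str]):
        proba = np.asarray(proba, dtype=np.float64)
        j = int(np.argmax(proba))  # first maximum = class-scheme order tie-break
        return cls(
            tile=tile,
            probabilities={c: float(p) for c, p in zip(classes, proba)},
            predicted_label=classes[j],
            confidence=float(proba[j]),
        )


class TileClassifier(ClassifierMixin, BaseEstimator):
    """Class-weighted softmax tile classifier with best-epoch selection.

    Parameters
    ----------
    backbone : str
        Name of a registered backbone (default ``"pooled-mlp"``).
    backbone_params : dict, optional
        Keyword arguments for the backbone factory.
    epochs, batch_size, learning_rate
        Adam training schedule.
    validation_fraction : float in (0, 0.5]
        Share of the training tiles held out for epoch selection.  When
        ``groups`` (slide ids) are passed to ``fit`` the split is grouped so
        no slide contributes to both folds.
    class_weight : {"inverse_frequency", None}
        Loss weighting; inverse frequency uses ``w_c = N/(K n_c)`` computed
        on the training fold.
    selection_metric : {"balanced_accuracy", "accuracy"}
        Validation metric maximized for best-epoch selection (ties resolve
        to the earliest epoch).
    normalize : bool
        Standardize pixels per channel with statistics from the training
        fold before feature extraction.
    classes : sequence of str, optional
        Fixed class order for probability columns (e.g. the scheme order).
        Classes listed here but absent from ``y`` raise an error.
    random_state : int, optional
        Seed for initialization, the validation split and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray of class labels (probability column order)
    channel_stats_ : ChannelStats or None
    best_epoch_ : int, 0-based index of the selected epoch
    history_ : list of per-epoch dicts (train loss, validation metrics)
    class_weights_ : dict label -> weight used in the loss
    """

    def __init__(
        self,
        backbone: str = "pooled-mlp",
        backbone_params: dict | None = None,
        epochs: int = 10,
        batch_size: int = 64,
        learning_rate: float = 0.01,
        validation_fraction: float = 0.2,
        class_weight: str | None = "inverse_frequency",
        selection_metric: str = "balanced_accuracy",
        normalize: bool = True,
        classes: Sequence[str] | None = None,
        random_state: int | None = None,
    ):
        self.backbone = backbone
        self.backbone_params = backbone_params
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.class_weight = class_weight
        self.selection_metric = selection_metric
        self.normalize = normalize
        self.classes = classes
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _validation_split(self, y_idx, groups, n_classes, seed):
        n = len(y_idx)
        if groups is None:
            splitter = StratifiedShuffleSplit(
                n_splits=1, test_size=self.validation_fraction, random_state=seed
            )
            tr, va = next(splitter.split(np.zeros(n), y_idx))
            return tr, va
        groups = np.asarray(groups)
        fallback = None
        for t in range(20):
            gss = GroupShuffleSplit(
                n_splits=1, test_size=self.validation_fraction, random_state=seed + t
            )
            tr, va = next(gss.split(np.zeros(n), y_idx, groups))
            if len(np.unique(y_idx[tr])) == n_classes:
                if len(np.unique(y_idx[va])) == n_classes:
                    return tr, va
                if fallback is None:
                    fallback = (tr, va)
        if fallback is not None:
            return fallback
        # degenerate cohort: some class lives on a single slide, so a grouped
        # split cannot keep every class in the training fold
        warnings.warn(
            "grouped validation split impossible (a class occupies too few "
            "slides); falling back to a stratified per-tile split",
            UserWarning,
            stacklevel=3,
        )
        return self._validation_split(y_idx, None, n_classes, seed)

    @staticmethod
    def _balanced_accuracy(y_true, y_pred, n_classes) -> float:
        recalls = []
        for c in range(n_classes):
            mask = y_true == c
            if mask.any():
                recalls.append(float((y_pred[mask] == c).mean()))
        return float(np.mean(recalls))

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, groups=None):
        if not 0.0 < self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must lie in (0, 0.5]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        y = np.asarray(y)
        if self.classes is not None:
            classes = np.asarray(list(self.classes))
            missing = sorted(set(classes.tolist()) - set(y.tolist()))
            if missing:
                raise ValueError(
                    f"classes absent from the training split: {missing}"
                )
        else:
            classes = np.unique(y)
        self.classes_ = classes
        lookup = {c: i for i, c in enumerate(classes.tolist())}
        try:
            y_idx = np.array([lookup[lab] for lab in y])
        except KeyError as e:
            raise ValueError(f"label {e.args[0]!r} not in classes") from None
        k = len(classes)
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(seed)

        backbone = get_backbone(self.backbone, **(self.backbone_params or {}))
        tr, va = self._validation_split(y_idx, groups, k, seed)

        X_list = X if isinstance(X, np.ndarray) else list(X)
        if self.normalize:
            # pooled per-channel statistics of the training fold, streamed
            n_px, s, ss = 0, 0.0, 0.0
            for batch in _iter_pixel_chunks(_select(X_list, tr)):
                flat = batch.reshape(-1, batch.shape[-1]).astype(np.float64)
                n_px += flat.shape[0]
                s = s + flat.sum(axis=0)
                ss = ss + (flat * flat).sum(axis=0)
            mean = s / n_px
            std = np.maximum(np.sqrt(np.maximum(ss / n_px - mean * mean, 0.0)), 1e-6)
            stats = ChannelStats(mean=mean, std=std, source="training fold")
            self.channel_stats_ = stats
        else:
            self.channel_stats_ = None
        F = self._extract(backbone, X_list)

        counts = {classes[c]: int((y_idx[tr] == c).sum()) for c in range(k)}
        if self.class_weight == "inverse_frequency":
            wmap = class_weights(counts)
            w = np.array([float(wmap[c]) for c in classes])
        elif self.class_weight in (None, "none"):
            w = np.ones(k)
        else:
            raise ValueError(f"unknown class_weight mode {self.class_weight!r}")
        self.class_weights_ = {c: float(w[i]) for i, c in enumerate(classes.tolist())}

        params = backbone.init_params(F.shape[1], k, rng)
        m = {p: np.zeros_like(v) for p, v in params.items()}
        v2 = {p: np.zeros_like(v) for p, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        F_tr, y_tr = F[tr], y_idx[tr]
        F_va, y_va = F[va], y_idx[va]
        history = []
        best = (-np.inf, -1, None)
        for epoch in range(self.epochs):
            order = rng.permutation(len(F_tr))
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                Fb, yb = F_tr[idx], y_tr[idx]
                logits, a1 = backbone.forward(params, Fb, keep=True)
                probs = _softmax(logits)
                p_true = np.clip(probs[np.arange(len(yb)), yb], _P_FLOOR, 1.0)
                loss = float(np.mean(-w[yb] * np.log(p_true)))
                epoch_loss += loss * len(yb)
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits *= (w[yb] / len(yb))[:, None]
                grads = backbone.backward(params, Fb, a1, dlogits)
                step += 1
                for p in params:
                    m[p] = beta1 * m[p] + (1 - beta1) * grads[p]
                    v2[p] = beta2 * v2[p] + (1 - beta2) * grads[p] ** 2
                    mhat = m[p] / (1 - beta1**step)
                    vhat = v2[p] / (1 - beta2**step)
                    params[p] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            val_probs = _softmax(backbone.forward(params, F_va))
            val_pred = np.argmax(val_probs, axis=1)
            val_ba = self._balanced_accuracy(y_va, val_pred, k)
            val_acc = float((val_pred == y_va).mean())
            p_true = np.clip(val_probs[np.arange(len(y_va)), y_va], _P_FLOOR, 1.0)
            val_loss = float(np.mean(-w[y_va] * np.log(p_true)))
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": epoch_loss / len(F_tr),
                    "val_balanced_accuracy": val_ba,
                    "val_accuracy": val_acc,
                    "val_loss": val_loss,
                }
            )
            if self.selection_metric == "balanced_accuracy":
                score = val_ba
            elif self.selection_metric == "accuracy":
                score = val_acc
            else:
                raise ValueError(
                    f"unknown selection_metric {self.selection_metric!r}"
                )
            if score > best[0]:
                best = (score, epoch, {p: v.copy() for p, v in params.items()})
        self.history_ = history
        self.best_epoch_ = best[1]
        self.params_ = best[2]
        self.backbone_ = backbone
        self.n_features_in_ = F.shape[1]
        return self

    def _extract(self, backbone, X) -> np.ndarray:
        """Chunked feature extraction with per-channel normalization."""
        stats = self.channel_stats_
        feats = []
        for batch in _iter_pixel_chunks(X):
            b = batch.astype(np.float64)
            if stats is not None:
                b = (b - stats.mean) / stats.std
            feats.append(backbone.batch_features(b))
        if not feats:
            raise ValueError("no tiles to extract features from")
        return np.concatenate(feats, axis=0)

    def _features(self, X):
        return self._extract(self.backbone_, X)

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        probs = _softmax(self.backbone_.forward(self.params_, self._features(X)))
        return probs

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]


# ---------------------------------------------------------------------------
# persistence


def save_classifier(clf: TileClassifier, out_dir) -> None:
    """Persist a fitted classifier: weights (npz) + JSON training log."""
    import json
    from pathlib import Path

    check_is_fitted(clf, "params_")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", **clf.params_)
    meta = {
        "params": clf.get_params(),
        "classes": [str(c) for c in clf.classes_],
        "best_epoch": clf.best_epoch_,
        "history": clf.history_,
        "class_weights": clf.class_weights_,
        "channel_stats": (
            None if clf.channel_stats_ is None else clf.channel_stats_.to_dict()
        ),
    }
    meta["params"]["classes"] = (
        None if clf.classes is None else [str(c) for c in clf.classes]
    )
    with open(out / "training_log.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def load_classifier(run_dir) -> TileClassifier:
    import json
    from pathlib import Path

    run = Path(run_dir)
    with open(run / "training_log.json") as fh:
        meta = json.load(fh)
    params = meta["params"]
    # json round-trips numbers as str via default=str only for exotic types
    clf = TileClassifier(**params)
    clf.classes_ = np.array(meta["classes"], dtype=object)
    clf.best_epoch_ = meta["best_epoch"]
    clf.history_ = meta["history"]
    clf.class_weights_ = meta["class_weights"]
    clf.channel_stats_ = (
        None
        if meta["channel_stats"] is None
        else ChannelStats.from_dict(meta["channel_stats"])
    )
    with np.load(run / "weights.npz") as npz:
        clf.params_ = {k: npz[k] for k in npz.files}
    clf.backbone_ = get_backbone(clf.backbone, **(clf.backbone_params or {}))
    clf.n_features_in_ = clf.params_["W1"].shape[0]
    return clf


# ---------------------------------------------------------------------------
# dataset-level wrappers


def fit_classifier(train: TileDataset, **params) -> TileClassifier:
    """Fit a :class:`TileClassifier` on a labeled tile dataset.

    The probability column order is the dataset's class-scheme order and the
    validation split is grouped by slide id.
    """
    labeled = [t for t in train if t.label is not None]
    if not labeled:
        raise ValueError("training dataset has no labeled tiles")
    present = {t.label for t in labeled}
    classes = [c for c in train.scheme.labels if c in present]
    clf = TileClassifier(classes=classes, **params)
    X = [t.pixels for t in labeled]
    y = np.array([t.label for t in labeled], dtype=object)
    groups = np.array([t.slide_id for t in labeled], dtype=object)
    clf.fit(X, y, groups=groups)
    return clf


def predict_records(clf: TileClassifier, dataset: TileDataset) -> list[PredictionRecord]:
    """Per-tile probability vectors as :class:`PredictionRecord` objects."""
    if len(dataset) == 0:
        return []
    probs = clf.predict_proba([t.pixels for t in dataset])
    classes = list(clf.classes_)
    return [
        PredictionRecord.from_proba(t, p, classes) for t, p in zip(dataset, probs)
    ]
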