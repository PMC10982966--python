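import numpy as np
import pytest

from gliotile.classifier import PredictionRecord
from gliotile.scheme import DEFAULT_SCHEME
from gliotile.semi_supervised import (
    PseudoLabelPolicy,
    SemiSupervisedTileClassifier,
    allowed_classes,
    merge_datasets,
    pseudo_label_filter,
    run_two_step,
)
from gliotile.synthetic import SyntheticConfig, generate_cohort, split_cohort
from gliotile.tiling import TileDataset
from conftest import make_tile


def make_pred(slide_id, label, confidence, x=0, y=0, scheme=DEFAULT_SCHEME):
    rest = (1.0 - confidence) / (scheme.n_classes - 1)
    probs = {c: rest for c in scheme.labels}
    probs[label] = confidence
    tile = make_tile(slide_id=slide_id, x=x, y=y)
    return PredictionRecord(
        tile=tile, probabilities=probs, predicted_label=label, confidence=confidence
    )


# ------------------------------------------------------------ allowed classes
def test_allowed_classes_match_diagnosis_rule(scheme):
    assert allowed_classes("gbm", scheme) == {"gbm", "normal", "necrosis"}
    assert allowed_classes("odg", scheme) == {"odg", "normal", "necrosis"}
    assert allowed_classes("normal", scheme) == {"normal"}
    with pytest.raises(KeyError):
        allowed_classes("unknown", scheme)


# ------------------------------------------------------------------ filtering
def test_impossible_class_removed_despite_high_confidence():
    ds, log = pseudo_label_filter(
        [make_pred("s1", "odg", 0.95)], {"s1": "gbm"}, return_log=True
    )
    assert len(ds) == 0
    assert log[0][2] == "impossible_class"


def test_below_gate_removed_and_exact_threshold_retained():
    preds = [
        make_pred("s1", "gbm", 0.85, x=0),
        make_pred("s1", "necrosis", 0.90, x=32),
    ]
    ds, log = pseudo_label_filter(preds, {"s1": "gbm"}, return_log=True)
    assert [t.label for t in ds] == ["necrosis"]  # >= is inclusive
    assert log[0][2] == "low_confidence"
    assert all(t.provenance == "pseudo" for t in ds)


def test_missing_diagnosis_names_the_slide():
    with pytest.raises(KeyError, match="mystery"):
        pseudo_label_filter([make_pred("mystery", "gbm", 0.99)], {})


def _random_predictions(n, rng, scheme=DEFAULT_SCHEME):
    diagnoses = {}
    preds = []
    for i in range(n):
        sid = f"s{rng.integers(0, 25)}"
        diagnoses.setdefault(sid, str(rng.choice(list(scheme.diagnoses))))
        p = rng.dirichlet(np.ones(scheme.n_classes) * 0.5)
        j = int(np.argmax(p))
        tile = make_tile(slide_id=sid, x=int(i) * 8, size=8)
        preds.append(
            PredictionRecord(
                tile=tile,
                probabilities=dict(zip(scheme.labels, map(float, p))),
                predicted_label=scheme.labels[j],
                confidence=float(p[j]),
            )
        )
    return preds, diagnoses


def test_filter_agrees_with_brute_force_refilter():
    rng = np.random.default_rng(11)
    preds, diag = _random_predictions(800, rng)
    policy = PseudoLabelPolicy(confidence_threshold=0.5)
    ds = pseudo_label_filter(preds, diag, policy)
    expected = {
        (r.tile.slide_id, r.tile.x, r.tile.y)
        for r in preds
        if r.confidence >= 0.5
        and r.predicted_label in DEFAULT_SCHEME.allowed_classes(diag[r.tile.slide_id])
    }
    assert {(t.slide_id, t.x, t.y) for t in ds} == expected


def test_threshold_and_enforcement_monotonicity():
    rng = np.random.default_rng(12)
    preds, diag = _random_predictions(500, rng)
    sizes = [
        len(pseudo_label_filter(preds, diag, PseudoLabelPolicy(confidence_threshold=thr)))
        for thr in (0.0, 0.3, 0.6, 0.9, 1.01)
    ]
    assert sizes == sorted(sizes, reverse=True)
    assert sizes[-1] == 0  # threshold above 1 retains nothing
    on = len(pseudo_label_filter(preds, diag, PseudoLabelPolicy(0.5, enforce_diagnosis=True)))
    off = len(pseudo_label_filter(preds, diag, PseudoLabelPolicy(0.5, enforce_diagnosis=False)))
    assert on <= off


# -------------------------------------------------------------------- merging
def test_merge_with_empty_pseudo_is_identity(scheme):
    gt = TileDataset([make_tile(x=i * 16, label="gbm") for i in range(4)], scheme)
    merged = merge_datasets(gt, TileDataset([], scheme))
    assert len(merged) == 4
    assert merged.class_counts == gt.class_counts


def test_merged_sizes_and_class_counts_are_additive(scheme):
    gt = TileDataset(
        [make_tile(x=i * 16, label="gbm") for i in range(5)]
        + [make_tile(y=16, x=i * 16, label="normal") for i in range(3)],
        scheme,
    )
    pseudo = TileDataset(
        [make_tile(slide_id="s9", x=i * 16, label="normal") for i in range(7)], scheme
    )
    merged = merge_datasets(gt, pseudo)
    assert len(merged) == len(gt) + len(pseudo) == 15
    # recount oracle
    from collections import Counter

    recount = Counter(t.label for t in merged)
    assert merged.class_counts == {"gbm": 5, "normal": 10} == dict(recount)


def test_identity_collision_is_an_error(scheme):
    gt = TileDataset([make_tile(x=0, label="gbm")], scheme)
    clash = TileDataset([make_tile(x=0, label="normal")], scheme)
    with pytest.raises(ValueError, match="collide"):
        merge_datasets(gt, clash)


# ------------------------------------------------------------------- two-step
@pytest.fixture(scope="module")
def partial_cohort():
    cfg = SyntheticConfig(
        n_slides=10,
        tile_size=64,
        block_grid=(8, 6),
        difficulty=0.0,
        annotated_fraction=0.35,
        seed=21,
    )
    cohort = generate_cohort(cfg)
    train, test = split_cohort(cohort.slides, 0.25, seed=21)
    return train, test


def test_degenerate_gate_reduces_step2_to_step1(partial_cohort):
    train, test = partial_cohort
    res = run_two_step(
        train,
        test,
        tile_size=64,
        policy=PseudoLabelPolicy(confidence_threshold=1.5),
        epochs=2,
        random_state=0,
    )
    assert len(res.pseudo) == 0
    assert len(res.merged) == len(res.ground_truth)


def test_two_step_never_pseudo_labels_test_slides(partial_cohort):
    train, test = partial_cohort
    res = run_two_step(
        train, test, tile_size=64, epochs=3, random_state=1
    )
    test_ids = {s.slide_id for s in test}
    assert {t.slide_id for t in res.pseudo} & test_ids == set()
    assert all(t.provenance == "pseudo" for t in res.pseudo)
    # every retained pseudo label is possible under its slide's diagnosis
    diag = {s.slide_id: s.diagnosis for s in train}
    for t in res.pseudo:
        assert t.label in DEFAULT_SCHEME.allowed_classes(diag[t.slide_id])


def test_merged_dataset_grows_when_pseudo_tiles_are_retained(partial_cohort):
    train, test = partial_cohort
    res = run_two_step(train, test, tile_size=64, epochs=3, random_state=2)
    assert len(res.pseudo) >= 1
    assert len(res.merged) == len(res.ground_truth) + len(res.pseudo)
    assert res.growth_factor > 1.0


def test_semi_supervised_estimator_api():
    rng = np.random.default_rng(3)
    colors = {"gbm": (60, 40, 110), "normal": (250, 226, 236)}
    X, y, groups, diagnoses = [], [], [], []
    for ci, (label, color) in enumerate(colors.items()):
        for i in range(30):
            img = np.clip(np.array(color) + rng.normal(0, 8, (16, 16, 3)), 0, 255)
            X.append(img.astype(np.uint8))
            y.append(label if i < 20 else None)  # last third unlabeled
            groups.append(f"slide_{ci}_{i % 3}")
            diagnoses.append("gbm")
    from gliotile.classifier import TileClassifier

    model = SemiSupervisedTileClassifier(
        base_estimator=TileClassifier(epochs=4, random_state=0), threshold=0.8
    )
    model.fit(np.stack(X), np.array(y, dtype=object), groups=np.array(groups), diagnoses=diagnoses)
    assert set(model.n_pseudo_per_class_) <= {"gbm", "normal"}
    probs = model.predict_proba(np.stack(X[:5]))
    assert np.allclose(probs.sum(axis=1), 1.0)
    # diagnosis gate: with a normal-control diagnosis nothing tumor survives
    strict = SemiSupervisedTileClassifier(
        base_estimator=TileClassifier(epochs=2, random_state=0), threshold=0.0
    )
    strict.fit(
        np.stack(X),
        np.array(y, dtype=object),
        groups=np.array(groups),
        diagnoses=["normal"] * len(X),
    )
    assert set(strict.n_pseudo_per_class_) <= {"normal"}
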