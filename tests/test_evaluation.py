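import numpy as np
import pytest
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix as sk_confusion_matrix,
    precision_recall_fscore_support,
)

from gliotile.evaluation import (
    ConfusionMatrix,
    balanced_accuracy,
    binary_collapse,
    confusion_matrix,
    macro_metrics,
    metrics_report,
    per_class_metrics,
)
from gliotile.scheme import ClassScheme, DEFAULT_SCHEME

AB = ("a", "b")


def cm_of(counts, labels=AB):
    return ConfusionMatrix(np.array(counts), tuple(labels))


# ------------------------------------------------------------ confusion matrix
def test_perfect_predictions_are_diagonal(scheme):
    y = list(scheme.labels) * 3
    cm = confusion_matrix(y, y, scheme)
    assert np.array_equal(cm.counts, np.eye(5, dtype=int) * 3)


def test_empty_input_gives_zero_matrix(scheme):
    cm = confusion_matrix([], [], scheme)
    assert cm.counts.sum() == 0
    assert cm.counts.shape == (5, 5)


def test_matrix_matches_brute_force_tally(scheme):
    rng = np.random.default_rng(0)
    y_true = rng.choice(scheme.labels, 200)
    y_pred = rng.choice(scheme.labels, 200)
    cm = confusion_matrix(list(y_true), list(y_pred), scheme)
    for i, ti in enumerate(scheme.labels):
        for j, pj in enumerate(scheme.labels):
            assert cm.counts[i, j] == sum(
                1 for t, p in zip(y_true, y_pred) if t == ti and p == pj
            )
    assert cm.total == 200


def test_unknown_labels_and_length_mismatch_rejected(scheme):
    with pytest.raises(ValueError, match="unknown"):
        confusion_matrix(["zz"], ["gbm"], scheme)
    with pytest.raises(ValueError, match="length"):
        confusion_matrix(["gbm"], [], scheme)


# ----------------------------------------------------------- balanced accuracy
def test_diagonal_matrix_scores_one():
    assert balanced_accuracy(cm_of([[5, 0], [0, 7]])) == 1.0


def test_two_class_hand_arithmetic():
    assert balanced_accuracy(cm_of([[9, 1], [2, 3]])) == pytest.approx(0.75)


def test_equal_supports_reduce_to_plain_accuracy():
    counts = [[8, 2], [3, 7]]
    cm = cm_of(counts)
    plain = (8 + 7) / 20
    assert balanced_accuracy(cm) == pytest.approx(plain)


def test_zero_support_class_excluded_with_warning():
    cm = cm_of([[4, 0], [0, 0]])
    with pytest.warns(UserWarning, match="zero support"):
        assert balanced_accuracy(cm) == 1.0


def test_all_zero_matrix_is_an_error():
    with pytest.raises(ValueError):
        balanced_accuracy(cm_of([[0, 0], [0, 0]]))


# -------------------------------------------------------------- macro metrics
def test_macro_hand_arithmetic():
    m = macro_metrics(cm_of([[9, 1], [2, 3]]))
    assert m.precision == pytest.approx((9 / 11 + 3 / 4) / 2)
    assert m.recall == pytest.approx(0.75)
    f1_a = 2 * (9 / 11) * 0.9 / (9 / 11 + 0.9)
    f1_b = 2 * (3 / 4) * 0.6 / (3 / 4 + 0.6)
    assert m.f1 == pytest.approx((f1_a + f1_b) / 2)


def test_diagonal_macro_is_perfect():
    assert macro_metrics(cm_of([[5, 0], [0, 5]])) == (1.0, 1.0, 1.0)


def test_never_predicted_class_contributes_zero_precision():
    cm = cm_of([[0, 4], [0, 6]])  # column "a" never predicted
    with pytest.warns(UserWarning, match="never-predicted"):
        per = per_class_metrics(cm)
    assert per["a"]["precision"] == 0.0
    assert per["a"]["f1"] == 0.0


def test_macro_f1_is_mean_of_per_class_f1_not_f1_of_macro():
    cm = cm_of([[9, 1], [6, 4]])
    m = macro_metrics(cm)
    per = per_class_metrics(cm)
    assert m.f1 == pytest.approx(np.mean([per["a"]["f1"], per["b"]["f1"]]))
    harmonic = 2 * m.precision * m.recall / (m.precision + m.recall)
    assert m.f1 != pytest.approx(harmonic)


def test_metrics_match_sklearn_on_random_label_sets(scheme):
    rng = np.random.default_rng(1)
    for _ in range(30):
        y_true = list(rng.choice(scheme.labels, 120))
        # ensure every class appears as a true label
        y_true[:5] = list(scheme.labels)
        y_pred = list(rng.choice(scheme.labels, 120))
        cm = confusion_matrix(y_true, y_pred, scheme)
        assert np.array_equal(
            cm.counts, sk_confusion_matrix(y_true, y_pred, labels=list(scheme.labels))
        )
        assert balanced_accuracy(cm) == pytest.approx(
            balanced_accuracy_score(y_true, y_pred)
        )
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list(scheme.labels), average="macro", zero_division=0
        )
        m = macro_metrics(cm)
        assert (m.precision, m.recall, m.f1) == pytest.approx((p, r, f))


def test_metrics_invariant_under_class_permutation(scheme):
    rng = np.random.default_rng(2)
    y_true = list(rng.choice(scheme.labels, 100)) + list(scheme.labels)
    y_pred = list(rng.choice(scheme.labels, 105))
    base = macro_metrics(confusion_matrix(y_true, y_pred, scheme))
    ba = balanced_accuracy(confusion_matrix(y_true, y_pred, scheme))
    permuted = tuple(reversed(scheme.labels))
    other = macro_metrics(confusion_matrix(y_true, y_pred, permuted))
    ba2 = balanced_accuracy(confusion_matrix(y_true, y_pred, permuted))
    assert base == pytest.approx(other)
    assert ba == pytest.approx(ba2)


# ------------------------------------------------------------- binary collapse
def test_diagonal_collapse_has_zero_rates(scheme):
    counts = np.diag([10, 10, 10, 10, 10])
    fa, miss = binary_collapse(ConfusionMatrix(counts, scheme.labels), scheme)
    assert (fa, miss) == (0.0, 0.0)


def test_single_false_alarm_among_300_non_tumor_tiles(scheme):
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 0] = 50  # tumor correct
    counts[3, 3] = 299  # normal correct
    counts[3, 2] = 1  # one normal tile called gbm
    counts[4, 4] = 0
    cm = ConfusionMatrix(counts, scheme.labels)
    fa, miss = binary_collapse(cm, scheme)
    assert fa == pytest.approx(1 / 300)
    assert miss == 0.0


def test_subtype_swaps_leave_binary_rates_at_zero(scheme):
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 1] = 10  # ac predicted odg
    counts[1, 0] = 7  # odg predicted ac
    counts[3, 3] = 5
    cm = ConfusionMatrix(counts, scheme.labels)
    assert binary_collapse(cm, scheme) == (0.0, 0.0)


def test_collapse_agrees_with_binary_recall_oracle(scheme):
    rng = np.random.default_rng(3)
    y_true = list(rng.choice(scheme.labels, 300))
    y_pred = list(rng.choice(scheme.labels, 300))
    cm = confusion_matrix(y_true, y_pred, scheme)
    fa, miss = binary_collapse(cm, scheme)
    to_bin = lambda lab: "tumor" if lab in scheme.tumor_labels else "no_tumor"
    bt = [to_bin(t) for t in y_true]
    bp = [to_bin(p) for p in y_pred]
    n_non = sum(1 for t in bt if t == "no_tumor")
    n_tum = len(bt) - n_non
    fa_oracle = sum(1 for t, p in zip(bt, bp) if t == "no_tumor" and p == "tumor") / n_non
    miss_oracle = sum(1 for t, p in zip(bt, bp) if t == "tumor" and p == "no_tumor") / n_tum
    assert fa == pytest.approx(fa_oracle)
    assert miss == pytest.approx(miss_oracle)


def test_collapse_requires_support_on_both_sides(scheme):
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 0] = 5  # tumor only
    with pytest.raises(ValueError):
        binary_collapse(ConfusionMatrix(counts, scheme.labels), scheme)


# --------------------------------------------------------------------- report
def test_full_report_is_serializable_and_consistent(scheme):
    rng = np.random.default_rng(4)
    y_true = list(rng.choice(scheme.labels, 200)) + list(scheme.labels)
    y_pred = list(rng.choice(scheme.labels, 205))
    report = metrics_report(confusion_matrix(y_true, y_pred, scheme), scheme)
    d = report.to_dict()
    assert d["macro"]["balanced_accuracy"] == pytest.approx(report.macro.recall)
    assert 0 <= d["binary"]["false_alarm_rate"] <= 1
    assert 0 <= d["binary"]["missed_cancer_rate"] <= 1
    import json

    json.dumps(d)  # must be JSON-ready
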