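"""Metric arithmetic: confusion, PRF, AUC, CV aggregation, scoring."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonecnn import (
    ArchConfig,
    aggregate,
    build_bone_cnn,
    confusion,
    cv_aggregate,
    evaluate_model,
    normalized_score,
    per_class_prf,
    phantom_tensor_dataset,
    roc_auc,
)
from bonecnn.errors import InputError
from bonecnn.phantom import PhantomSpec

BINARY_CM = [[79, 1], [2, 71]]  # 80 normal / 73 abnormal external-validation test set


# ---------------------------------------------------------------------------
# Confusion matrix
# ---------------------------------------------------------------------------


def test_perfect_predictions_give_diagonal_matrix():
    y = np.array([0, 1, 2, 2, 1, 0])
    cm = confusion(y, y, 3)
    assert (cm.counts == np.diag([2, 2, 2])).all()
    assert cm.accuracy == 1.0


def test_binary_external_validation_confusion_arithmetic():
    """The 80/73 binary confusion implies 98.04% accuracy and the
    printed precision/recall/F1 for the abnormal class."""
    cm = confusion(
        np.repeat([0, 1], [80, 73]),
        np.concatenate([np.repeat([0, 1], [79, 1]), np.repeat([0, 1], [2, 71])]),
        2,
    )
    assert (cm.counts == np.array(BINARY_CM)).all()
    assert cm.accuracy == pytest.approx(150 / 153)
    assert round(100 * cm.accuracy, 2) == 98.04
    precision, recall, f1, support = per_class_prf(cm)
    assert round(precision[1], 3) == 0.986
    assert round(recall[1], 3) == 0.973
    assert round(f1[1], 3) == 0.979
    assert support.tolist() == [80, 73]


def test_confusion_input_validation():
    with pytest.raises(InputError):
        confusion([], [], 2)
    with pytest.raises(InputError):
        confusion([0, 1], [0], 2)
    with pytest.raises(InputError):
        confusion([0, 5], [0, 1], 2)


def test_prf_matches_sklearn_on_random_labels():
    from sklearn.metrics import precision_recall_fscore_support

    rng = np.random.default_rng(0)
    y_true = rng.integers(0, 4, 60)
    y_pred = rng.integers(0, 4, 60)
    cm = confusion(y_true, y_pred, 4)
    precision, recall, f1, support = per_class_prf(cm)
    p, r, f, s = precision_recall_fscore_support(y_true, y_pred, labels=range(4), zero_division=0)
    assert precision == pytest.approx(p)
    assert recall == pytest.approx(r)
    assert f1 == pytest.approx(f)
    assert support.tolist() == s.tolist()


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def test_nine_class_f1_table_macro_average():
    f1 = np.array([0.98, 0.93, 0.79, 0.96, 0.88, 0.92, 0.97, 0.91, 1.00])
    out = aggregate(f1, np.ones(9))
    assert out["macro_f1"] == pytest.approx(0.926, abs=1e-3)
    assert out["macro_f1"] == pytest.approx(0.92667, abs=1e-5)


def test_all_perfect_classes_aggregate_to_one():
    out = aggregate(np.ones(4), np.array([5, 1, 9, 3]))
    assert out["macro_f1"] == 1.0 and out["weighted_f1"] == 1.0


def test_support_weighting_two_class_example():
    out = aggregate(np.array([1.0, 0.0]), np.array([3, 1]))
    assert out["weighted_f1"] == pytest.approx(0.75)
    assert out["macro_f1"] == pytest.approx(0.5)


def test_macro_f1_bounded_by_class_extremes():
    rng = np.random.default_rng(1)
    for _ in range(20):
        f1 = rng.random(5)
        out = aggregate(f1, rng.integers(1, 10, 5))
        assert f1.min() <= out["macro_f1"] <= f1.max()


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _binary_auc(pos_scores, neg_scores):
    scores = np.concatenate([pos_scores, neg_scores])
    y = np.concatenate([np.ones(len(pos_scores), int), np.zeros(len(neg_scores), int)])
    two_col = np.column_stack([1 - scores, scores])
    _curves, _macro, _micro, aucs = roc_auc(two_col, y)
    return aucs[1]


def test_perfectly_separated_scores_have_auc_one():
    assert _binary_auc([0.9, 0.8], [0.4, 0.3]) == 1.0


def test_three_of_four_concordant_pairs_give_075():
    assert _binary_auc([0.9, 0.4], [0.8, 0.3]) == pytest.approx(0.75)


def test_inverted_labels_give_auc_zero():
    assert _binary_auc([0.3, 0.4], [0.8, 0.9]) == 0.0


def test_ties_count_half():
    assert _binary_auc([0.5], [0.5]) == pytest.approx(0.5)


@settings(deadline=None, derandomize=True, max_examples=80)
@given(
    scores=st.lists(st.integers(0, 5), min_size=2, max_size=12),
    labels=st.lists(st.booleans(), min_size=2, max_size=12),
)
def test_rank_auc_equals_exhaustive_pair_counting(scores, labels):
    """The rank statistic must equal brute-force counting of concordant
    pairs (half credit for ties) on every small input."""
    n = min(len(scores), len(labels))
    scores, labels = np.array(scores[:n], float), np.array(labels[:n], bool)
    if labels.all() or not labels.any():
        return
    pos, neg = scores[labels], scores[~labels]
    brute = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    brute /= len(pos) * len(neg)
    assert _binary_auc(pos, neg) == pytest.approx(brute, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.random((20, 3))
    y = rng.integers(0, 3, 20)
    if len(np.unique(y)) < 3:
        return
    _c, macro1, micro1, aucs1 = roc_auc(scores, y)
    transformed = np.exp(3.0 * scores)  # strictly monotone
    _c, macro2, micro2, aucs2 = roc_auc(transformed, y)
    assert aucs1 == pytest.approx(aucs2, abs=1e-12)
    assert macro1 == pytest.approx(macro2) and micro1 == pytest.approx(micro2)


def test_auc_matches_sklearn_one_vs_rest():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    scores = rng.random((40, 3))
    scores /= scores.sum(axis=1, keepdims=True)
    y = rng.integers(0, 3, 40)
    _c, macro, _micro, aucs = roc_auc(scores, y)
    for c in range(3):
        expected = roc_auc_score((y == c).astype(int), scores[:, c])
        assert aucs[c] == pytest.approx(expected, abs=1e-12)
    assert macro == pytest.approx(np.mean(aucs))


def test_micro_auc_perfect_and_degraded():
    y = np.array([0, 1, 2, 0, 1, 2])
    perfect = np.eye(3)[y]
    _c, macro, micro, _a = roc_auc(perfect + 1e-9, y)
    assert micro == 1.0 and macro == 1.0
    flipped = perfect.copy()
    flipped[:, 0] = 1 - flipped[:, 0]  # invert one class's scores
    _c, macro_f, _m, _a = roc_auc(flipped, y)
    assert macro_f < 1.0


def test_degenerate_class_excluded_with_warning():
    scores = np.random.default_rng(0).random((6, 3))
    y = np.array([0, 0, 1, 1, 0, 1])  # class 2 has no positives
    with pytest.warns(UserWarning, match="class 2"):
        _c, macro, _micro, aucs = roc_auc(scores, y)
    assert np.isnan(aucs[2])
    assert not np.isnan(macro)


def test_roc_curve_endpoints_and_monotonicity():
    rng = np.random.default_rng(2)
    scores = rng.random((30, 2))
    y = rng.integers(0, 2, 30)
    curves, _m, _mi, _a = roc_auc(scores, y)
    for curve in curves.values():
        curve.validate()


# ---------------------------------------------------------------------------
# CV aggregation and normalised score
# ---------------------------------------------------------------------------


def test_fold_table_means():
    rows = [
        {"accuracy": a, "cross_entropy": c}
        for a, c in zip([97.2, 97.4, 96.9, 97.4, 97.1], [0.082, 0.079, 0.085, 0.081, 0.083])
    ]
    out = cv_aggregate(rows)
    assert out["accuracy"][0] == pytest.approx(97.2)
    assert out["cross_entropy"][0] == pytest.approx(0.082)
    assert out["accuracy"][1] == pytest.approx(np.std([97.2, 97.4, 96.9, 97.4, 97.1], ddof=1))


def test_identical_folds_have_zero_sd():
    out = cv_aggregate([{"m": 1.5}] * 4)
    assert out["m"] == (1.5, 0.0)


def test_normalized_score_reference_and_weighting():
    assert normalized_score(0.9, 5e6, 0.9, 5e6) == 1.0
    assert normalized_score(0.45, 5e6, 0.9, 5e6, weight=1.0) == pytest.approx(0.5)
    score = normalized_score(0.9890 * 0.9, 1.0 / 0.2405, 0.9, 1.0, weight=0.5)
    assert score == pytest.approx(0.6148, abs=1e-4)


# ---------------------------------------------------------------------------
# Whole-model evaluation
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def untrained_eval():
    spec = PhantomSpec(image_size=32, seed=13)
    x, y = phantom_tensor_dataset(6, spec)
    model = build_bone_cnn(ArchConfig(input_size=32), seed=3)
    return evaluate_model(model, x, y), y


def test_untrained_model_scores_near_chance(untrained_eval):
    report, y = untrained_eval
    n = len(y)
    # binomial 99% interval around p = 1/9
    p = 1 / 9
    sd = np.sqrt(p * (1 - p) / n)
    assert report.accuracy <= p + 2.576 * sd + 1e-9


def test_report_internal_consistency(untrained_eval):
    report, y = untrained_eval
    assert report.top1_error == pytest.approx(1 - report.accuracy)
    assert report.support.sum() == len(y)
    assert report.macro_f1 == pytest.approx(report.f1.mean())
    assert report.confusion.total == len(y)
    assert min(report.f1) <= report.macro_f1 <= max(report.f1)


def test_constant_predictor_recall_pattern():
    class AlwaysZero:
        class config:
            num_classes = 3

        def predict_proba(self, x):
            out = np.zeros((len(x), 3))
            out[:, 0] = 1.0
            return out

    x = np.zeros((9, 1))
    y = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
    with pytest.warns(UserWarning):
        report = evaluate_model(AlwaysZero(), x, y)
    assert report.recall[0] == 1.0
    assert report.recall[1] == 0.0 and report.recall[2] == 0.0
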