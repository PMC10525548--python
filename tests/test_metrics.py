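"""Token accuracy, F1, BLEU-1 and confusion-matrix metric derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medcap.corpus import CaptionTriple
from medcap.errors import ValidationError
from medcap.metrics import (UNDEFINED, SlotConfusion, bleu1,
                            build_slot_confusion, confusion_metrics, f1_score,
                            metric_table, round2, token_accuracy)


class TestTokenAccuracy:
    def test_identical_sequences(self):
        assert token_accuracy([["a", "b"]], [["a", "b"]]) == 1.0

    def test_fully_disjoint_sequences(self):
        assert token_accuracy([["x", "y"]], [["a", "b"]]) == 0.0

    def test_partial_match_counts_positions(self):
        got = token_accuracy([["ct", "lung", "tumor"]], [["ct", "chest", "tumor"]])
        assert got == pytest.approx(2 / 3)

    def test_short_prediction_is_padded_with_misses(self):
        assert token_accuracy([["ct"]], [["ct", "chest", "tumor"]]) == pytest.approx(1 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            token_accuracy([], [])


class TestF1:
    def test_harmonic_mean_of_equals(self):
        assert f1_score(0.5, 0.5) == pytest.approx(0.5)

    def test_published_ct_row_value(self):
        # precision 108/152, sensitivity 108/123 -> 0.79 at 2 decimals
        assert round2(f1_score(108 / 152, 108 / 123)) == 0.79

    def test_undefined_when_both_zero_or_either_undefined(self):
        assert f1_score(0.0, 0.0) is UNDEFINED
        assert f1_score(UNDEFINED, 0.5) is UNDEFINED
        assert f1_score(0.5, UNDEFINED) is UNDEFINED


class TestBleu1:
    def test_perfect_prediction(self):
        assert bleu1([["a", "b", "c"]], [["a", "b", "c"]]) == 1.0

    def test_two_of_three_unigrams(self):
        assert bleu1([["ct", "lung", "tumor"]], [["ct", "chest", "tumor"]]) == pytest.approx(2 / 3)

    def test_corpus_level_pooling(self):
        preds = [["a", "b", "c"], ["d", "e", "f"]]
        refs = [["a", "b", "c"], ["d", "e", "x"]]
        assert bleu1(preds, refs) == pytest.approx(5 / 6)

    def test_count_clipping_of_repeats(self):
        assert bleu1([["a", "a", "a"]], [["a", "b"]]) == pytest.approx(1 / 3)

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValidationError):
            bleu1([[]], [["a"]])

    def test_coincides_with_token_accuracy_on_aligned_slots(self, rng):
        # equal-length order-free captions: both reduce to matched/total
        words = np.array(["u", "v", "w"])
        refs = [list(words[rng.integers(0, 3, size=3)]) for _ in range(50)]
        # per-position corruption keeps alignment
        preds = [[w if rng.random() < 0.7 else "zz" for w in r] for r in refs]
        assert bleu1(preds, refs) == pytest.approx(token_accuracy(preds, refs))


class TestSlotConfusion:
    def test_hand_counted_matrix(self):
        truths = [("A", "x", "p")] * 2 + [("B", "x", "p")]
        preds = [("A", "x", "p"), ("B", "x", "p"), ("B", "x", "p")]
        conf = build_slot_confusion(preds, truths, "exam_type")
        assert conf.labels == ("A", "B")
        np.testing.assert_array_equal(conf.counts, [[1, 1], [0, 1]])

    def test_empty_inputs_give_empty_matrix(self):
        conf = build_slot_confusion([], [], "body_part")
        assert conf.counts.shape == (0, 0)

    def test_perfect_predictions_are_diagonal(self):
        triples = [CaptionTriple("ct", "chest", "tumor"),
                   CaptionTriple("mri", "bone", "cyst")] * 3
        conf = build_slot_confusion(triples, triples, "problem")
        assert (conf.counts - np.diag(np.diag(conf.counts)) == 0).all()

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            SlotConfusion(("a",), np.zeros((1, 2), dtype=int))


def brute_force_metrics(counts):
    """Independent per-class 2x2 tabulation by explicit enumeration."""
    n = counts.shape[0]
    total = counts.sum()
    rows = []
    for c in range(n):
        tp = counts[c, c]
        fn = sum(counts[c, j] for j in range(n) if j != c)
        fp = sum(counts[i, c] for i in range(n) if i != c)
        tn = total - tp - fn - fp
        rows.append((tp, fp, tn, fn))
    return rows


class TestConfusionMetrics:
    def test_identity_matrix_gives_perfect_rates(self):
        conf = SlotConfusion(("a", "b"), 5 * np.eye(2, dtype=int))
        for row in confusion_metrics(conf):
            assert row.TPR == row.TNR == row.PPV == row.NPV == row.ACC == row.F1 == 1.0

    def test_matches_brute_force_on_500_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            n = rng.integers(2, 7)
            counts = rng.integers(0, 20, size=(n, n))
            conf = SlotConfusion(tuple(f"c{i}" for i in range(n)), counts)
            got = confusion_metrics(conf)
            for row, (tp, fp, tn, fn) in zip(got, brute_force_metrics(counts)):
                assert (row.TP, row.FP, row.TN, row.FN) == (tp, fp, tn, fn)
                assert row.P == tp + fn and row.N == fp + tn
                assert row.P + row.N == counts.sum()
                if tp + fn:
                    assert row.TPR == pytest.approx(tp / (tp + fn))
                if tp + fp == 0:
                    assert row.PPV is UNDEFINED
                    assert row.F1 is UNDEFINED
                elif tp == 0:
                    assert row.PPV == 0.0 and row.F1 is UNDEFINED

    def test_per_class_sums(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 9, size=(5, 5))
        rows = confusion_metrics(SlotConfusion(tuple("abcde"), counts))
        assert sum(r.TP for r in rows) == np.trace(counts)
        assert sum(r.P for r in rows) == counts.sum()

    def test_formatted_rates_round_half_up_with_dashes(self):
        conf = SlotConfusion(("a", "b"), np.array([[108, 15], [44, 117]]))
        table = metric_table(conf)
        assert table.loc[0, "TPR"] == "0.88"  # 108/123 = 0.878 rounds up
        empty = SlotConfusion(("a", "b"), np.array([[0, 5], [0, 7]]))
        t2 = metric_table(empty)
        assert t2.loc[0, "PPV"] == "-" and t2.loc[0, "F1"] == "-"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(2, 5), st.integers(0, 10_000))
def test_metric_identities_hold_for_random_matrices(n, seed):
    counts = np.random.default_rng(seed).integers(0, 30, size=(n, n))
    for row in confusion_metrics(SlotConfusion(tuple(f"c{i}" for i in range(n)), counts)):
        assert row.P == row.TP + row.FN
        assert row.N == row.FP + row.TN
        if counts.sum():
            assert row.ACC == pytest.approx((row.TP + row.TN) / counts.sum())


def test_against_sklearn_multilabel_reduction():
    """Independent oracle: sklearn's one-vs-rest confusion tabulation."""
    sklearn = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(11)
    y_true = rng.integers(0, 4, size=200)
    y_pred = rng.integers(0, 4, size=200)
    counts = sklearn.confusion_matrix(y_true, y_pred, labels=range(4))
    ours = confusion_metrics(SlotConfusion(("0", "1", "2", "3"), counts))
    mcm = sklearn.multilabel_confusion_matrix(y_true, y_pred, labels=range(4))
    for row, m in zip(ours, mcm):
        ((tn, fp), (fn, tp)) = m
        assert (row.TP, row.FP, row.TN, row.FN) == (tp, fp, tn, fn)
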