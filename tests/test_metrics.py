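"""Scoring: one-vs-all P/R/F1, majority-voting events, validation orchestration."""

import numpy as np
import pytest

from gazevents.errors import ValidationError
from gazevents.metrics import (apply_label_merge, confusion_matrix, event_counts,
                               event_level_scores, majority_label, run_validation,
                               sample_level_scores, weighted_average_f1)
from gazevents.sampling import segment_events


class TestSampleLevelScores:
    def test_worked_example(self):
        scores = sample_level_scores([1, 1, 1, 3, 3], [1, 1, 3, 3, 3])
        assert scores[1].precision == pytest.approx(1.0)
        assert scores[1].recall == pytest.approx(2 / 3)
        assert scores[1].f1 == pytest.approx(0.8)
        assert scores[3].precision == pytest.approx(2 / 3)
        assert scores[3].recall == pytest.approx(1.0)
        assert scores[3].f1 == pytest.approx(0.8)

    def test_perfect_prediction(self):
        scores = sample_level_scores([1, 2, 3, 4], [1, 2, 3, 4])
        assert all(s.f1 == 1.0 for s in scores.values())

    def test_absent_class_scores_zero_with_zero_weight(self):
        scores = sample_level_scores([1, 1], [1, 1], classes=[1, 2])
        assert scores[2].f1 == 0.0
        assert scores[2].weight == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            sample_level_scores([1, 1], [1])


class TestEventLevelScores:
    def test_majority_matches_event(self):
        segs = segment_events([1, 1, 1])
        counts, _ = event_counts(segs, np.array([1, 3, 1]))
        assert counts[1] == (1, 0, 0)

    def test_event_scoring_more_lenient_than_sample(self):
        gt = [1, 1, 1, 3, 3]
        pred = [1, 1, 3, 3, 3]
        ev = event_level_scores(segment_events(gt), np.array(pred))
        assert ev[1].f1 == 1.0 and ev[3].f1 == 1.0
        sm = sample_level_scores(gt, pred)
        assert sm[1].f1 == pytest.approx(0.8)

    def test_tie_broken_by_earliest_occurrence(self):
        # span [1, 3]: tie between 1 and 3, 1 occurs first -> FN for 3, FP for 1
        segs = segment_events([3, 3])
        counts, _ = event_counts(segs, np.array([1, 3]))
        assert counts[3] == (0, 0, 1)
        assert counts[1] == (0, 1, 0)
        assert majority_label(np.array([3, 1, 3, 1])) == 3

    def test_out_of_range_segment_rejected(self):
        segs = segment_events([1, 1, 1])
        with pytest.raises(ValidationError):
            event_counts(segs, np.array([1, 1]))


class TestWeightedAverage:
    def test_equal_f1s(self):
        scores = sample_level_scores([1, 1, 1, 3, 3], [1, 1, 3, 3, 3])
        assert weighted_average_f1(scores) == pytest.approx(0.8)

    def test_single_class_is_its_own_f1(self):
        scores = sample_level_scores([1, 1, 1], [1, 1, 3], classes=[1])
        assert weighted_average_f1(scores) == pytest.approx(scores[1].f1)

    def test_explicit_weights(self):
        scores = sample_level_scores([1, 1, 1, 2], [1, 1, 1, 1])
        assert weighted_average_f1(scores, {1: 0.75, 2: 0.25}) == pytest.approx(
            0.75 * scores[1].f1)

    def test_negative_weight_rejected(self):
        scores = sample_level_scores([1, 2], [1, 2])
        with pytest.raises(ValidationError):
            weighted_average_f1(scores, {1: -0.5, 2: 1.5})


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(1, 4), min_size=1, max_size=40))
def test_majority_label_is_a_true_mode(span):
    span = np.asarray(span)
    winner = majority_label(span)
    counts = {v: int(np.sum(span == v)) for v in set(span.tolist())}
    assert counts[winner] == max(counts.values())
    # among tied classes the winner appears earliest in the span
    tied = [v for v, c in counts.items() if c == counts[winner]]
    firsts = {v: int(np.flatnonzero(span == v)[0]) for v in tied}
    assert firsts[winner] == min(firsts.values())


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4)),
                min_size=1, max_size=60))
def test_weighted_f1_bounded_by_extremes(pairs):
    gt = np.array([g for g, _ in pairs])
    pred = np.array([p for _, p in pairs])
    scores = sample_level_scores(gt, pred)
    wf1 = weighted_average_f1(scores)
    f1s = [s.f1 for s in scores.values() if s.weight > 0]
    assert min(f1s) - 1e-12 <= wf1 <= max(f1s) + 1e-12


def test_f1_identity_of_both_printed_forms():
    """2PR/(P+R) equals TP/(TP+(FP+FN)/2) for any positive counts."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        tp, fp, fn = rng.integers(1, 100, 3)
        p = tp / (tp + fp)
        r = tp / (tp + fn)
        f1_pr = 2 * p * r / (p + r)
        f1_counts = tp / (tp + (fp + fn) / 2)
        assert abs(f1_pr - f1_counts) < 1e-12


def _brute_force_counts(gt, pred, cls):
    """Literal one-vs-all enumeration, independent of the implementation."""
    tp = sum(1 for g, p in zip(gt, pred) if g == cls and p == cls)
    fp = sum(1 for g, p in zip(gt, pred) if g != cls and p == cls)
    fn = sum(1 for g, p in zip(gt, pred) if g == cls and p != cls)
    return tp, fp, fn


def _brute_force_event_pairs(labels, cuts, pred):
    pairs = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i] and not cuts[j + 1]:
            j += 1
        span = list(pred[i:j + 1])
        best = max(set(span), key=lambda v: (span.count(v), -span.index(v)))
        pairs.append((labels[i], best))
        i = j + 1
    return pairs


def test_scores_match_brute_force_enumerator():
    rng = np.random.default_rng(1)
    from gazevents.metrics import sample_counts
    for _ in range(300):
        n = int(rng.integers(2, 50))
        gt = rng.integers(1, 5, n)
        pred = rng.integers(1, 5, n)
        cuts = rng.random(n) < 0.1
        cuts[0] = False
        for cls in (1, 2, 3, 4):
            assert sample_counts(gt, pred, classes=[cls])[cls] == \
                _brute_force_counts(gt, pred, cls)
        segs = segment_events(gt, cuts)
        got, _ = event_counts(segs, pred, classes=[1, 2, 3, 4])
        expect_pairs = _brute_force_event_pairs(list(gt), list(cuts), list(pred))
        for cls in (1, 2, 3, 4):
            tp = sum(1 for g, p in expect_pairs if g == cls and p == cls)
            fp = sum(1 for g, p in expect_pairs if g != cls and p == cls)
            fn = sum(1 for g, p in expect_pairs if g == cls and p != cls)
            assert got[cls] == (tp, fp, fn)


def test_confusion_row_sums_equal_class_counts():
    rng = np.random.default_rng(2)
    gt = rng.integers(1, 5, 200)
    pred = rng.integers(1, 5, 200)
    M = confusion_matrix(gt, pred, [1, 2, 3, 4])
    for i, c in enumerate([1, 2, 3, 4]):
        assert M[i].sum() == np.sum(gt == c)


class TestRunValidation:
    def test_loo_reproducible_bit_identically(self, small_dataset):
        r1 = run_validation(small_dataset, "loo", seed=0)
        r2 = run_validation(small_dataset, "loo", seed=0)
        assert r1.to_dict() == r2.to_dict()

    def test_split_report_structure(self, small_dataset):
        rep = run_validation(small_dataset, "split", seed=0)
        assert set(rep.classes) == {1, 2, 3, 4}
        assert 0 <= rep.weighted_event_f1 <= 1
        assert len(rep.importances) == 1
        np.testing.assert_allclose(rep.importances[0].sum(), 1.0, atol=1e-9)
        # confusion row sums equal pooled ground-truth counts in the test set
        assert rep.confusion_sample.sum() == sum(
            s.tp + s.fn for s in rep.sample_scores.values())

    def test_label_merge_reduces_class_set(self, small_dataset):
        rep = run_validation(small_dataset, "loo", seed=0, label_merge={4: 1})
        assert rep.classes == [1, 2, 3]

    def test_loo_needs_two_recordings(self, small_dataset):
        with pytest.raises(ValidationError):
            run_validation(small_dataset[:1], "loo", seed=0)

    def test_merge_helper(self, small_dataset):
        merged = apply_label_merge(small_dataset, {4: 1})
        assert not any((m.label == 4).any() for m in merged)
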