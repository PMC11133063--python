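"""Event segmentation, within-event extraction, balancing and splitting."""

import numpy as np
import pytest

from gazevents.errors import BalancingError
from gazevents.features import FeatureMatrix
from gazevents.sampling import (balance_loo_train, head_trim_balance,
                                pooled_class_counts, segment_events,
                                split_train_test, take_rows, within_event_extract)
from conftest import random_labeled_recording


def _mat(labels, cuts=None):
    labels = np.asarray(labels, int)
    n = labels.size
    cuts = np.zeros(n, bool) if cuts is None else np.asarray(cuts, bool)
    return FeatureMatrix(np.arange(n) * 0.01, np.random.default_rng(0).random((n, 6)),
                         labels, cuts, "m")


class TestSegmentEvents:
    def test_label_changes_delimit_segments(self):
        segs = segment_events([1, 1, 3, 3, 1])
        assert [(s.label, s.start_idx, s.end_idx) for s in segs] == \
            [(1, 0, 1), (3, 2, 3), (1, 4, 4)]

    def test_cut_flag_splits_same_label_run(self):
        cuts = np.array([False, False, True, False])
        segs = segment_events([1, 1, 1, 1], cuts)
        assert [(s.start_idx, s.end_idx) for s in segs] == [(0, 1), (2, 3)]

    def test_single_sample(self):
        assert len(segment_events([2])) == 1

    def test_segments_tile_the_recording(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels, cuts = random_labeled_recording(rng)
            segs = segment_events(labels, cuts)
            covered = [i for s in segs for i in range(s.start_idx, s.end_idx + 1)]
            assert covered == list(range(labels.size))


class TestWithinEventExtract:
    def test_quota_preserves_events(self):
        labels = np.array([1, 1, 1, 1, 3, 3, 1, 1, 1, 1])
        cuts = np.zeros(10, bool)
        split = within_event_extract([labels], [cuts], {1: 6}, seed=0)
        kept = split.kept[0]
        assert (labels[kept] == 1).sum() == 2
        assert (labels[kept] == 3).sum() == 2
        kept_mat = take_rows(_mat(labels), kept)
        assert len(segment_events(kept_mat.label, kept_mat.cut_before)) == 3

    def test_zero_quota_is_identity(self):
        labels, cuts = np.array([1, 1, 2, 2]), np.zeros(4, bool)
        split = within_event_extract([labels], [cuts], {1: 0}, seed=0)
        assert split.extracted[0].size == 0
        assert split.kept[0].tolist() == [0, 1, 2, 3]

    def test_seed_determinism_and_variation(self):
        rng = np.random.default_rng(1)
        labels, cuts = random_labeled_recording(rng, n_runs=20, min_len=6)
        quota = {1: 20, 2: 15}
        a = within_event_extract([labels], [cuts], quota, seed=7)
        b = within_event_extract([labels], [cuts], quota, seed=7)
        c = within_event_extract([labels], [cuts], quota, seed=8)
        assert a.extracted[0].tolist() == b.extracted[0].tolist()
        assert a.extracted[0].tolist() != c.extracted[0].tolist()
        assert (labels[c.extracted[0]] == 1).sum() == (labels[a.extracted[0]] == 1).sum()

    def test_infeasible_quota_names_class(self):
        labels = np.array([1, 1, 1, 2, 2, 2])
        with pytest.raises(BalancingError, match="class 1"):
            within_event_extract([labels], [np.zeros(6, bool)], {1: 3}, seed=0)

    def test_extracted_and_kept_partition_indices(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            labels, cuts = random_labeled_recording(rng, n_runs=15, min_len=5)
            split = within_event_extract([labels], [cuts], {1: 5}, seed=seed)
            merged = np.sort(np.r_[split.kept[0], split.extracted[0]])
            assert merged.tolist() == list(range(labels.size))
            assert np.all(np.diff(split.kept[0]) > 0)
            assert np.all(np.diff(split.extracted[0]) > 0)


class TestBalanceLooTrain:
    def test_counts_balanced_to_minimum(self):
        rng = np.random.default_rng(3)
        mats = []
        for _ in range(4):
            labels = np.r_[np.ones(250, int), np.full(25, 3),
                           np.ones(250, int) * 2]
            order_cuts = np.zeros(labels.size, bool)
            order_cuts[250] = order_cuts[275] = True
            mats.append(_mat(labels, order_cuts))
        balanced = balance_loo_train(mats, seed=0)
        counts = pooled_class_counts(balanced)
        assert max(counts.values()) - min(counts.values()) <= len(mats)
        assert min(counts.values()) == 100  # 4 recordings x 25 rarest-class samples

    def test_event_counts_unchanged(self):
        rng = np.random.default_rng(4)
        mats = [_mat(*random_labeled_recording(rng, n_runs=14, min_len=6))
                for _ in range(3)]
        n_before = [len(segment_events(m.label, m.cut_before)) for m in mats]
        balanced = balance_loo_train(mats, seed=0)
        n_after = [len(segment_events(m.label, m.cut_before)) for m in balanced]
        assert n_before == n_after

    def test_already_balanced_unchanged(self):
        mats = [_mat([1] * 10 + [2] * 10)]
        out = balance_loo_train(mats, seed=0)
        assert len(out[0]) == 20

    def test_single_class_warns_and_passes_through(self, caplog):
        mats = [_mat([1] * 10)]
        out = balance_loo_train(mats, seed=0)
        assert len(out[0]) == 10


class TestSplitTrainTest:
    def test_single_class_fraction(self):
        mats = [_mat([1] * 100)]
        train, test = split_train_test(mats, 0.20, seed=0)
        assert len(test[0]) == 20
        assert len(train[0]) == 80
        assert np.all(np.diff(test[0].t) > 0)

    def test_two_class_head_trim_then_extract(self):
        labels = np.r_[np.ones(150, int), np.full(50, 2)]
        cuts = np.zeros(200, bool)
        train, test = split_train_test([_mat(labels, cuts)], 0.20, seed=0)
        counts_total = pooled_class_counts([train[0]])
        for c, n in pooled_class_counts([test[0]]).items():
            counts_total[c] = counts_total.get(c, 0) + n
        assert counts_total == {1: 50, 2: 50}
        assert pooled_class_counts([test[0]]) == {1: 10, 2: 10}

    def test_same_seed_identical_split(self):
        rng = np.random.default_rng(5)
        mats = [_mat(*random_labeled_recording(rng, n_runs=16, min_len=6))
                for _ in range(2)]
        t1 = split_train_test(mats, 0.2, seed=3)
        t2 = split_train_test(mats, 0.2, seed=3)
        for a, b in zip(t1[1], t2[1]):
            assert a.t.tolist() == b.t.tolist()

    def test_split_manifest_matches_split(self, tmp_path):
        import pandas as pd
        from gazevents.sampling import write_split_manifest
        rng = np.random.default_rng(6)
        mats = [_mat(*random_labeled_recording(rng, n_runs=16, min_len=6))
                for _ in range(2)]
        train, test = split_train_test(mats, 0.2, seed=1)
        write_split_manifest(tmp_path / "m.csv", mats, 0.2, seed=1)
        df = pd.read_csv(tmp_path / "m.csv")
        assert len(df) == sum(len(m) for m in mats)
        assert set(df["assignment"]) <= {"train", "test", "removed"}
        assert (df["assignment"] == "test").sum() == sum(len(t) for t in test)
        assert (df["assignment"] == "train").sum() == sum(len(t) for t in train)

    def test_head_trim_sets_cut_flags(self):
        labels = np.r_[np.ones(6, int), np.full(3, 2), np.ones(4, int)]
        trimmed = head_trim_balance([_mat(labels)])[0]
        counts = pooled_class_counts([trimmed])
        assert counts[1] == counts[2] == 3
        # trimming consumed the whole first class-1 event plus one sample of the
        # last one; the deletion boundary is flagged so events cannot merge
        assert trimmed.cut_before[trimmed.label == 1][0]
        segs = segment_events(trimmed.label, trimmed.cut_before)
        assert [s.label for s in segs] == [2, 1]
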