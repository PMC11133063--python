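"""Sample- and event-level scoring plus the two validation procedures.

Scoring is one-vs-all per class.  Precision = TP/(TP+FP) and recall =
TP/(TP+FN) (0 when the denominator is 0); F1 is computed as
``TP / (TP + (FP+FN)/2)``, which is algebraically identical to
``2PR/(P+R)``.  Sample-level scores compare each timestamp; event-level
scores first match every ground-truth event to the most frequent predicted
class within its span (majority voting — a deliberately more lenient
scheme that does not punish broken prediction continuity), counting one
TP/FN/FP per event.  Weighted averages use the relative frequency of each
class in the test set (sample frequencies for the sample level, event
frequencies for the event level).

Validation regimes:

* leave-one-out — each recording is held out in turn, the remaining
  recordings are class-balanced and used for training, and the *unbalanced*
  held-out recording is scored; TP/FP/FN counts are pooled across folds
  before the final scores (robust to folds where a class is absent).
* train-test split — all recordings are head-trim balanced, a 20% per-class
  test subset is extracted within events, and the remaining 80% trains a
  single model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .features import FEATURE_NAMES, FeatureMatrix
from .model import feature_importances, predict_labels, train_classifier
from .sampling import EventSegment, balance_loo_train, segment_events, split_train_test


@dataclass
class ClassScores:
    """One-vs-all counts and derived scores for a single class."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    weight: float = 0.0


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = tp / (tp + (fp + fn) / 2.0) if tp + fp + fn > 0 else 0.0
    return p, r, f1


def _scores_from_counts(counts: dict[int, tuple[int, int, int]],
                        weights: dict[int, float]) -> dict[int, ClassScores]:
    out = {}
    for c in sorted(counts):
        tp, fp, fn = counts[c]
        p, r, f1 = _prf(tp, fp, fn)
        out[c] = ClassScores(tp, fp, fn, p, r, f1, weights.get(c, 0.0))
    return out


def sample_counts(gt: np.ndarray, pred: np.ndarray,
                  classes=None) -> dict[int, tuple[int, int, int]]:
    """One-vs-all (TP, FP, FN) per class at the sample level."""
    gt = np.asarray(gt, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if gt.shape != pred.shape:
        raise ValidationError(f"gt has {gt.size} labels, pred has {pred.size}")
    if gt.size == 0:
        raise ValidationError("empty label sequences")
    if classes is None:
        classes = np.union1d(np.unique(gt), np.unique(pred))
    return {int(c): (int(np.sum((gt == c) & (pred == c))),
                     int(np.sum((gt != c) & (pred == c))),
                     int(np.sum((gt == c) & (pred != c))))
            for c in classes}


def sample_level_scores(gt: np.ndarray, pred: np.ndarray,
                        classes=None) -> dict[int, ClassScores]:
    """Per-class one-vs-all precision/recall/F1 over individual samples.

    Class weights are the relative sample frequencies in ``gt``; a class
    absent from both sequences scores 0 with zero weight.
    """
    counts = sample_counts(gt, pred, classes)
    gt = np.asarray(gt, dtype=int)
    weights = {c: float(np.mean(gt == c)) for c in counts}
    return _scores_from_counts(counts, weights)


def majority_label(span: np.ndarray) -> int:
    """Most frequent label in a span; ties go to the tied class seen earliest."""
    span = np.asarray(span, dtype=int)
    vals, counts = np.unique(span, return_counts=True)
    best = counts.max()
    tied = vals[counts == best]
    if len(tied) == 1:
        return int(tied[0])
    first_pos = {int(v): int(np.flatnonzero(span == v)[0]) for v in tied}
    return min(first_pos, key=first_pos.get)


def event_counts(gt_segments: list[EventSegment], pred: np.ndarray,
                 classes=None) -> tuple[dict[int, tuple[int, int, int]], dict]:
    """Majority-voting event matching: per-class (TP, FP, FN) and confusion pairs.

    Each ground-truth event whose predicted mode equals its label is one TP
    for that class; otherwise one FN for the event's label and one FP for
    the mode class.
    """
    pred = np.asarray(pred, dtype=int)
    pairs = []
    for seg in gt_segments:
        if seg.start_idx < 0 or seg.end_idx >= pred.size:
            raise ValidationError(
                f"segment [{seg.start_idx}, {seg.end_idx}] out of range 0..{pred.size - 1}")
        pairs.append((seg.label, majority_label(pred[seg.start_idx:seg.end_idx + 1])))
    if classes is None:
        classes = sorted({g for g, _ in pairs} | {p for _, p in pairs})
    counts = {}
    for c in classes:
        tp = sum(1 for g, p in pairs if g == c and p == c)
        fn = sum(1 for g, p in pairs if g == c and p != c)
        fp = sum(1 for g, p in pairs if g != c and p == c)
        counts[int(c)] = (tp, fp, fn)
    confusion = {}
    for g, p in pairs:
        confusion[(g, p)] = confusion.get((g, p), 0) + 1
    return counts, confusion


def event_level_scores(gt_segments: list[EventSegment], pred: np.ndarray,
                       classes=None) -> dict[int, ClassScores]:
    """Per-class event-level P/R/F1 with majority-voting event matching.

    Class weights are relative ground-truth event frequencies.
    """
    counts, _ = event_counts(gt_segments, pred, classes)
    n_events = len(gt_segments)
    weights = {c: sum(1 for s in gt_segments if s.label == c) / n_events
               for c in counts} if n_events else {}
    return _scores_from_counts(counts, weights)


def weighted_average_f1(scores: dict[int, ClassScores],
                        weights: dict[int, float] | None = None) -> float:
    """Frequency-weighted mean of the per-class F1 scores."""
    if weights is None:
        weights = {c: s.weight for c, s in scores.items()}
    for c, w in weights.items():
        if w < 0:
            raise ValidationError(f"negative weight for class {c}")
    return float(sum(weights.get(c, 0.0) * s.f1 for c, s in scores.items()))


def confusion_matrix(gt: np.ndarray, pred: np.ndarray, classes) -> np.ndarray:
    """Raw-count confusion matrix; rows = ground truth, columns = prediction."""
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for g, p in zip(np.asarray(gt, int), np.asarray(pred, int)):
        if g in idx and p in idx:
            M[idx[g], idx[p]] += 1
    return M


@dataclass
class EvaluationReport:
    """Scores, confusions and importances of one validation run."""

    mode: str
    seed: int
    classes: list[int]
    sample_scores: dict[int, ClassScores]
    event_scores: dict[int, ClassScores]
    weighted_sample_f1: float
    weighted_event_f1: float
    confusion_sample: np.ndarray
    confusion_event: np.ndarray
    importances: list[np.ndarray] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    @property
    def mean_importances(self) -> np.ndarray:
        return np.mean(np.vstack(self.importances), axis=0)

    def to_dict(self) -> dict:
        def scores_dict(scores):
            return {str(c): {"tp": s.tp, "fp": s.fp, "fn": s.fn,
                             "precision": s.precision, "recall": s.recall,
                             "f1": s.f1, "weight": s.weight}
                    for c, s in scores.items()}
        return {
            "mode": self.mode,
            "seed": self.seed,
            "classes": self.classes,
            "sample_scores": scores_dict(self.sample_scores),
            "event_scores": scores_dict(self.event_scores),
            "weighted_sample_f1": self.weighted_sample_f1,
            "weighted_event_f1": self.weighted_event_f1,
            "confusion_sample": self.confusion_sample.tolist(),
            "confusion_event": self.confusion_event.tolist(),
            "confusion_sample_normalized": _row_normalize(self.confusion_sample),
            "confusion_event_normalized": _row_normalize(self.confusion_event),
            "feature_order": list(FEATURE_NAMES),
            "importances": [imp.tolist() for imp in self.importances],
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _row_normalize(M: np.ndarray) -> list:
    M = np.asarray(M, dtype=float)
    sums = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, M / sums, 0.0)
    return out.tolist()


def apply_label_merge(mats: list[FeatureMatrix],
                      merge: dict[int, int] | None) -> list[FeatureMatrix]:
    """Map labels before validation (e.g. {4: 1} folds following into fixation)."""
    if not merge:
        return mats
    out = []
    for m in mats:
        new = np.array([merge.get(int(l), int(l)) for l in m.label])
        out.append(FeatureMatrix(m.t, m.features, new, m.cut_before, m.recording_id))
    return out


def _fold_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def run_validation(mats: list[FeatureMatrix], mode: str, seed: int,
                   test_fraction: float = 0.20,
                   label_merge: dict[int, int] | None = None,
                   hyperparameters: dict | None = None) -> EvaluationReport:
    """Run leave-one-out (``mode='loo'``) or train-test split (``mode='split'``).

    Counts are pooled across folds/recordings before scores are computed;
    the report carries per-fold feature importances.
    """
    if mode not in ("loo", "split"):
        raise ValidationError(f"mode must be 'loo' or 'split', got {mode!r}")
    mats = apply_label_merge(mats, label_merge)
    if mode == "loo" and len(mats) < 2:
        raise ValidationError("leave-one-out needs at least 2 recordings")

    all_classes = sorted({int(c) for m in mats for c in np.unique(m.label)})
    s_counts = {c: [0, 0, 0] for c in all_classes}
    e_counts = {c: [0, 0, 0] for c in all_classes}
    gt_samples: list[np.ndarray] = []
    gt_event_labels: list[int] = []
    conf_s = np.zeros((len(all_classes), len(all_classes)), dtype=int)
    conf_e = np.zeros((len(all_classes), len(all_classes)), dtype=int)
    cls_idx = {c: i for i, c in enumerate(all_classes)}
    importances = []

    def accumulate(test_mat: FeatureMatrix, pred: np.ndarray):
        sc = sample_counts(test_mat.label, pred, classes=all_classes)
        segs = segment_events(test_mat.label, test_mat.cut_before, test_mat.recording_id)
        ec, conf_pairs = event_counts(segs, pred, classes=all_classes)
        for c in all_classes:
            for k in range(3):
                s_counts[c][k] += sc[c][k]
                e_counts[c][k] += ec[c][k]
        conf_s_local = confusion_matrix(test_mat.label, pred, all_classes)
        conf_s[:, :] += conf_s_local
        for (g, p), n in conf_pairs.items():
            if g in cls_idx and p in cls_idx:
                conf_e[cls_idx[g], cls_idx[p]] += n
        gt_samples.append(test_mat.label)
        gt_event_labels.extend(s.label for s in segs)

    if mode == "loo":
        fold_seeds = _fold_seeds(seed, len(mats))
        for i, test_mat in enumerate(mats):
            train_mats = [m for j, m in enumerate(mats) if j != i]
            balanced = balance_loo_train(train_mats, fold_seeds[i])
            model = train_classifier(balanced, fold_seeds[i],
                                     hyperparameters=hyperparameters)
            pred, _ = predict_labels(model, test_mat)
            importances.append(feature_importances(model))
            accumulate(test_mat, pred)
        notes = {"n_folds": len(mats),
                 "aggregation": "counts pooled across folds"}
    else:
        train_mats, test_mats = split_train_test(mats, test_fraction, seed)
        model = train_classifier([m for m in train_mats if len(m)], seed,
                                 hyperparameters=hyperparameters)
        importances.append(feature_importances(model))
        for test_mat in test_mats:
            if len(test_mat) == 0:
                continue
            pred, _ = predict_labels(model, test_mat)
            accumulate(test_mat, pred)
        notes = {"test_fraction": test_fraction,
                 "balancing": "head-trim on all recordings before the split"}

    gt_all = np.concatenate(gt_samples)
    w_s = {c: float(np.mean(gt_all == c)) for c in all_classes}
    n_events = len(gt_event_labels)
    w_e = {c: gt_event_labels.count(c) / n_events for c in all_classes}
    sample_scores = _scores_from_counts({c: tuple(v) for c, v in s_counts.items()}, w_s)
    event_scores = _scores_from_counts({c: tuple(v) for c, v in e_counts.items()}, w_e)
    return EvaluationReport(
        mode=mode, seed=seed, classes=all_classes,
        sample_scores=sample_scores, event_scores=event_scores,
        weighted_sample_f1=weighted_average_f1(sample_scores),
        weighted_event_f1=weighted_average_f1(event_scores),
        confusion_sample=conf_s, confusion_event=conf_e,
        importances=importances, notes=notes,
    )
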