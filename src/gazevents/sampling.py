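"""Event segmentation, within-event sample extraction, balancing and splitting.

The within-event random sample extractor removes (or subsets) samples from
the *interior* of events so that the number and order of events is
preserved: every event keeps at least one sample, and extraction never
touches event boundaries unless a class quota is otherwise infeasible
(interior-first relaxation, logged).  A class-specific extraction ratio
(quota / pooled class count) is applied consistently across recordings,
with largest-remainder rounding so the pooled total hits the quota exactly.

Two regimes build on it:

* ``balance_loo_train`` — undersample every class down to the rarest class
  across the pooled training recordings (used by leave-one-out validation;
  the held-out recording stays unbalanced).
* ``split_train_test`` — first equalize class counts by trimming whole
  samples from the *beginning* of each recording (marking every deletion
  boundary with a cut flag so remaining events cannot merge), then extract
  a per-class test fraction with the within-event extractor, keeping the
  original sample order in the test sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import BalancingError, ValidationError
from .features import FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class EventSegment:
    """Maximal run of identical labels bounded by label change, cut flag or edge."""

    label: int
    start_idx: int
    end_idx: int  # inclusive
    recording_id: str = ""

    def __len__(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass
class SampleSplit:
    """Partition of every recording's sample indices into kept and extracted."""

    kept: list[np.ndarray]
    extracted: list[np.ndarray]
    mode: str  # "removal" | "subset"


def segment_events(labels: np.ndarray, cuts: np.ndarray | None = None,
                   recording_id: str = "") -> list[EventSegment]:
    """Split a label sequence into maximal same-label runs, also at cut flags."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        return []
    if cuts is None:
        cuts = np.zeros(labels.size, dtype=bool)
    cuts = np.asarray(cuts, dtype=bool)
    new_seg = np.r_[True, (labels[1:] != labels[:-1]) | cuts[1:]]
    starts = np.flatnonzero(new_seg)
    ends = np.r_[starts[1:] - 1, labels.size - 1]
    return [EventSegment(int(labels[s]), int(s), int(e), recording_id)
            for s, e in zip(starts, ends)]


def segment_ids(labels: np.ndarray, cuts: np.ndarray | None = None) -> np.ndarray:
    """Per-sample index of the event segment each sample belongs to."""
    labels = np.asarray(labels, dtype=int)
    if cuts is None:
        cuts = np.zeros(labels.size, dtype=bool)
    cuts = np.asarray(cuts, dtype=bool)
    new_seg = np.r_[False, (labels[1:] != labels[:-1]) | cuts[1:]]
    return np.cumsum(new_seg)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``weights`` summing exactly to ``total``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        out = np.zeros(len(weights), dtype=int)
        out[: total] = 1  # degenerate; caller guards against this
        return out
    ideal = weights / weights.sum() * total
    base = np.floor(ideal).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    base[order[:rem]] += 1
    return base


def within_event_extract(labels_list: list[np.ndarray], cuts_list: list[np.ndarray],
                         quota: dict[int, int], seed: int,
                         mode: str = "removal") -> SampleSplit:
    """Extract per-class sample quotas from event interiors across recordings.

    Boundary samples (first/last of a segment) are only drawn when the
    interior pool cannot meet the class quota; the first sample of every
    segment is never extracted, so each event survives.  All randomness
    flows from one generator seeded with ``seed``.
    """
    if mode not in ("removal", "subset"):
        raise ValidationError(f"mode must be 'removal' or 'subset', got {mode!r}")
    rng = np.random.default_rng(seed)
    n_rec = len(labels_list)
    labels_list = [np.asarray(l, dtype=int) for l in labels_list]
    seg_lists = [segment_events(l, c) for l, c in zip(labels_list, cuts_list)]
    # per recording: interior pool and relaxation pool (segment-last samples)
    interior, relaxed = [], []
    for segs in seg_lists:
        imask, bmask = [], []
        for seg in segs:
            if len(seg) >= 3:
                imask.extend(range(seg.start_idx + 1, seg.end_idx))
            if len(seg) >= 2:
                bmask.append(seg.end_idx)
        interior.append(np.asarray(imask, dtype=int))
        relaxed.append(np.asarray(bmask, dtype=int))
    extracted = [[] for _ in range(n_rec)]
    relaxation_used = False
    for cls in sorted(quota):
        q = int(quota[cls])
        if q == 0:
            continue
        if q < 0:
            raise ValidationError(f"negative quota for class {cls}")
        counts = np.array([(l == cls).sum() for l in labels_list], dtype=float)
        cap_i = np.array([(labels_list[r][interior[r]] == cls).sum() for r in range(n_rec)])
        cap_b = np.array([(labels_list[r][relaxed[r]] == cls).sum() for r in range(n_rec)])
        cap = cap_i + cap_b
        if q > cap.sum():
            raise BalancingError(
                f"class {cls}: quota {q} exceeds extractable capacity {int(cap.sum())} "
                f"(events must each retain one sample)")
        if counts.sum() == 0:
            raise BalancingError(f"class {cls}: no samples present")
        target = _largest_remainder(counts, q)
        # waterfill overflow beyond per-recording capacity
        while True:
            over = np.maximum(target - cap, 0)
            if over.sum() == 0:
                break
            target = np.minimum(target, cap)
            spare = cap - target
            give = _largest_remainder(spare, int(over.sum()))
            target = target + np.minimum(give, spare)
        for r in range(n_rec):
            n_want = int(target[r])
            if n_want == 0:
                continue
            pool_i = interior[r][labels_list[r][interior[r]] == cls]
            n_i = min(n_want, len(pool_i))
            chosen = list(rng.choice(pool_i, size=n_i, replace=False)) if n_i else []
            if n_want > n_i:
                relaxation_used = True
                pool_b = relaxed[r][labels_list[r][relaxed[r]] == cls]
                extra = rng.choice(pool_b, size=n_want - n_i, replace=False)
                chosen.extend(extra.tolist())
            extracted[r].extend(int(i) for i in chosen)
    if relaxation_used:
        log.warning("within-event extraction: interior pools insufficient; "
                    "segment-boundary samples were drawn (events still preserved)")
    kept_out, extr_out = [], []
    for r in range(n_rec):
        ex = np.asarray(sorted(set(extracted[r])), dtype=int)
        mask = np.ones(labels_list[r].size, dtype=bool)
        mask[ex] = False
        kept_out.append(np.flatnonzero(mask))
        extr_out.append(ex)
    return SampleSplit(kept=kept_out, extracted=extr_out, mode=mode)


def write_split_manifest(path, mats: list[FeatureMatrix],
                         test_fraction: float = 0.20, seed: int = 0) -> None:
    """Write the full train/test/removed assignment of a split for auditing.

    Re-derives the (deterministic, seeded) head-trim + within-event split and
    writes one CSV row per original sample:
    ``recording_id, sample_index, assignment`` with assignment in
    {train, test, removed}.
    """
    import pandas as pd

    balanced = head_trim_balance(mats)
    counts = pooled_class_counts(balanced)
    quota = {c: int(round(test_fraction * n)) for c, n in counts.items() if n > 0}
    split = within_event_extract([m.label for m in balanced],
                                 [m.cut_before for m in balanced],
                                 quota, seed, mode="subset")
    rows = []
    for m, bal, kept, extracted in zip(mats, balanced, split.kept, split.extracted):
        # indices of the balanced matrix within the original one (head trim
        # removes a prefix of each class; match by timestamp)
        orig_idx = {t: i for i, t in enumerate(m.t)}
        bal_orig = np.array([orig_idx[t] for t in bal.t], dtype=int)
        assignment = np.full(len(m), "removed", dtype=object)
        assignment[bal_orig[kept]] = "train"
        assignment[bal_orig[extracted]] = "test"
        rows.append(pd.DataFrame({"recording_id": m.recording_id,
                                  "sample_index": np.arange(len(m)),
                                  "assignment": assignment}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def take_rows(mat: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    """Row-subset a feature matrix, recomputing cut flags from event identity.

    A row gets ``cut_before = True`` exactly when it comes from a different
    original event segment than the previous selected row, so events never
    merge and interior removals never split an event.
    """
    idx = np.asarray(idx, dtype=int)
    seg = segment_ids(mat.label, mat.cut_before)
    new_cuts = np.zeros(idx.size, dtype=bool)
    if idx.size > 1:
        new_cuts[1:] = seg[idx[1:]] != seg[idx[:-1]]
    return mat.take(idx, new_cuts)


def pooled_class_counts(mats: list[FeatureMatrix]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for m in mats:
        vals, cnts = np.unique(m.label, return_counts=True)
        for v, c in zip(vals, cnts):
            counts[int(v)] = counts.get(int(v), 0) + int(c)
    return counts


def balance_loo_train(mats: list[FeatureMatrix], seed: int) -> list[FeatureMatrix]:
    """Undersample pooled training recordings to the rarest class's count.

    Performed by the within-event extractor in removal mode, so per-recording
    event counts are unchanged.  A single-class input is returned unchanged
    with a warning.
    """
    counts = pooled_class_counts(mats)
    present = {c: n for c, n in counts.items() if n > 0}
    if len(present) < 2:
        log.warning("balance_loo_train: only %d class(es) present; nothing to balance",
                    len(present))
        return mats
    m_min = min(present.values())
    quota = {c: n - m_min for c, n in present.items() if n > m_min}
    if not quota:
        return mats
    split = within_event_extract([m.label for m in mats],
                                 [m.cut_before for m in mats],
                                 quota, seed, mode="removal")
    return [take_rows(m, k) for m, k in zip(mats, split.kept)]


def head_trim_balance(mats: list[FeatureMatrix]) -> list[FeatureMatrix]:
    """Equalize pooled class counts by deleting samples from recording starts.

    For each surplus class the first occurrences in each recording are
    removed (allocated across recordings by largest remainder); every
    deletion boundary sets a cut flag on the next retained sample so that
    same-class events cannot attach to each other.  Deterministic.
    """
    counts = pooled_class_counts(mats)
    present = {c: n for c, n in counts.items() if n > 0}
    if len(present) < 2:
        return mats
    m_min = min(present.values())
    out = []
    removal_sets = [set() for _ in mats]
    for cls, n in present.items():
        surplus = n - m_min
        if surplus == 0:
            continue
        per_rec = np.array([(m.label == cls).sum() for m in mats], dtype=float)
        alloc = _largest_remainder(per_rec, surplus)
        # cap and redistribute if any recording lacks enough samples
        while np.any(alloc > per_rec):
            over = np.maximum(alloc - per_rec, 0).sum()
            alloc = np.minimum(alloc, per_rec.astype(int))
            spare = per_rec.astype(int) - alloc
            give = _largest_remainder(spare, int(over))
            alloc = alloc + np.minimum(give, spare)
        for r, m in enumerate(mats):
            k = int(alloc[r])
            if k:
                removal_sets[r].update(np.flatnonzero(m.label == cls)[:k].tolist())
    for r, m in enumerate(mats):
        if not removal_sets[r]:
            out.append(m)
            continue
        removed = np.asarray(sorted(removal_sets[r]), dtype=int)
        mask = np.ones(len(m), dtype=bool)
        mask[removed] = False
        keep = np.flatnonzero(mask)
        new_cuts = m.cut_before[keep].copy()
        new_cuts[1:] |= np.diff(keep) > 1
        new_cuts[0] = False
        out.append(m.take(keep, new_cuts))
    return out


def split_train_test(mats: list[FeatureMatrix], test_fraction: float = 0.20,
                     seed: int = 0) -> tuple[list[FeatureMatrix], list[FeatureMatrix]]:
    """Head-trim balance, then extract a per-class test fraction within events.

    Returns (train, test) lists of per-recording feature matrices with
    disjoint, exhaustive sample sets; test samples keep their original order.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    balanced = head_trim_balance(mats)
    counts = pooled_class_counts(balanced)
    quota = {c: int(round(test_fraction * n)) for c, n in counts.items() if n > 0}
    split = within_event_extract([m.label for m in balanced],
                                 [m.cut_before for m in balanced],
                                 quota, seed, mode="subset")
    train = [take_rows(m, k) for m, k in zip(balanced, split.kept)]
    test = [take_rows(m, e) for m, e in zip(balanced, split.extracted)]
    return train, test
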