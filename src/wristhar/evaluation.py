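"""Evaluation of supervised classifiers: confusion matrices, merging of
confusable classes, two-level classification, and model selection.

A single wrist sensor cannot tell apart some activities (e.g. near-identical
walking variants), so classifier specificity is measured by merging: if more
than half of an actual class's windows are predicted as one other class, the
two classes are combined (transitively, via union-find), the classifier is
refitted on the merged labels, and the final confusion matrix is reported.
Mean accuracy is the mean of per-actual-class recall — the mean of the trace
of the column-normalized confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifiers import (
    ClassifierBank,
    HMMClassifier,
    fit_classifier_bank,
    fit_hmm,
    gmm_classify,
    viterbi_decode,
)

DEFAULT_MERGE_THRESHOLD = 0.5

#: A labeled window sequence: (feature matrix n x d, label vector n).
Sequence = tuple[np.ndarray, np.ndarray]


class ZeroSupportWarning(UserWarning):
    """An actual class had no test windows; it stays unmerged."""


@dataclass
class ConfusionMatrix:
    """Counts with predicted classes as rows and actual classes as columns."""

    counts: np.ndarray
    class_ids: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.class_ids)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over class_ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def column_normalized(self) -> np.ndarray:
        colsum = self.counts.sum(axis=0)
        out = np.zeros_like(self.counts)
        nz = colsum > 0
        out[:, nz] = self.counts[:, nz] / colsum[nz]
        return out

    def per_class_recall(self) -> dict[int, float]:
        norm = self.column_normalized()
        return {cid: float(norm[i, i]) for i, cid in enumerate(self.class_ids)
                if self.counts[:, i].sum() > 0}


def confusion_matrix(
    actual: np.ndarray, predicted: np.ndarray, class_ids: list[int]
) -> ConfusionMatrix:
    """Build counts[predicted, actual] over the given class order."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    if len(actual) == 0:
        raise ValueError("cannot build a confusion matrix from no windows")
    index = {cid: i for i, cid in enumerate(class_ids)}
    counts = np.zeros((len(class_ids), len(class_ids)))
    for a, p in zip(actual, predicted):
        if int(a) not in index or int(p) not in index:
            raise ValueError(f"label outside class order: actual={a}, predicted={p}")
        counts[index[int(p)], index[int(a)]] += 1
    return ConfusionMatrix(counts=counts, class_ids=list(class_ids))


def mean_accuracy(cm: ConfusionMatrix) -> float:
    """Mean per-actual-class recall (trace of the column-normalized matrix).

    Class-weighted, so comparable across class counts; classes without test
    support are excluded.
    """
    recalls = cm.per_class_recall()
    if not recalls:
        raise ValueError("no class has any support")
    return float(np.mean(list(recalls.values())))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Window-weighted accuracy: trace over total count.

    Unlike :func:`mean_accuracy` this is provably non-decreasing under any
    class merge on fixed predictions (merging only moves off-diagonal mass
    onto the diagonal), so the merge diagnostics are defined on it.
    """
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

@dataclass
class MergeMap:
    """Maps each original class id to its merged-group id (the group minimum)."""

    mapping: dict[int, int]

    def __post_init__(self) -> None:
        groups: dict[int, list[int]] = {}
        for cid, gid in sorted(self.mapping.items()):
            groups.setdefault(gid, []).append(cid)
        self.groups = groups

    @property
    def group_ids(self) -> list[int]:
        return sorted(self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def is_identity(self) -> bool:
        return all(len(m) == 1 for m in self.groups.values())

    def apply(self, labels: np.ndarray) -> np.ndarray:
        return np.array([self.mapping[int(c)] for c in np.asarray(labels)])


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller id as the representative
            lo, hi = min(ra, rb), max(ra, rb)
            self.parent[hi] = lo


def find_merges(
    cm: ConfusionMatrix, threshold: float = DEFAULT_MERGE_THRESHOLD
) -> MergeMap:
    """Merge classes whose confusion exceeds the threshold.

    For each actual class (column), if strictly more than ``threshold`` of
    its windows are predicted as one *other* class, the two classes are
    unioned; unions close transitively, and the rule is re-applied to the
    collapsed matrix until no further merge fires, so the returned map is a
    fixed point (re-running on the merged matrix is the identity).  Classes
    with no test support stay singleton (with a warning).
    """
    mapping = {cid: cid for cid in cm.class_ids}
    current = cm
    while True:
        uf = _UnionFind(current.class_ids)
        colsum = current.counts.sum(axis=0)
        changed = False
        for a, cid in enumerate(current.class_ids):
            if colsum[a] == 0:
                warnings.warn(
                    f"class {cid} has no test windows; left unmerged",
                    ZeroSupportWarning,
                )
                continue
            frac = current.counts[:, a] / colsum[a]
            for p, pid in enumerate(current.class_ids):
                if pid != cid and frac[p] > threshold:
                    uf.union(cid, pid)
                    changed = True
        if not changed:
            break
        # collapse this round's unions (representative = group minimum)
        groups: dict[int, list[int]] = {}
        for cid in current.class_ids:
            groups.setdefault(uf.find(cid), []).append(cid)
        step = {cid: min(members)
                for members in groups.values() for cid in members}
        mapping = {orig: step[g] for orig, g in mapping.items()}
        current = merge_confusion(current, MergeMap(mapping=step))
    return MergeMap(mapping=mapping)


def merge_confusion(cm: ConfusionMatrix, merge: MergeMap) -> ConfusionMatrix:
    """Collapse a confusion matrix's rows and columns onto merged groups."""
    gids = merge.group_ids
    gindex = {g: i for i, g in enumerate(gids)}
    out = np.zeros((len(gids), len(gids)))
    for i, pid in enumerate(cm.class_ids):
        for j, aid in enumerate(cm.class_ids):
            out[gindex[merge.mapping[pid]], gindex[merge.mapping[aid]]] += cm.counts[i, j]
    return ConfusionMatrix(counts=out, class_ids=gids)


# ---------------------------------------------------------------------------
# Two-level classification
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Final (post-merge) evaluation of one classifier configuration."""

    confusion: ConfusionMatrix
    per_class_accuracy: dict[int, float]
    mean_accuracy: float
    overall_accuracy: float
    n_final_classes: int
    merge_map: MergeMap
    level1_confusion: ConfusionMatrix
    kind: str = "gmm"
    dim: int | None = None


def _fit_and_predict(
    train_seqs: list[Sequence],
    test_seqs: list[Sequence],
    kind: str,
    n_components: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the requested classifier on training sequences, predict test windows."""
    x_train = np.vstack([x for x, _ in train_seqs])
    y_train = np.concatenate([y for _, y in train_seqs])
    by_class = {int(c): x_train[y_train == c] for c in np.unique(y_train)}
    bank = fit_classifier_bank(by_class, n_components=n_components, seed=seed)
    if kind == "gmm":
        preds = [gmm_classify(x, bank) for x, _ in test_seqs]
    elif kind == "hmm":
        hmm = fit_hmm(bank, [y for _, y in train_seqs])
        preds = [viterbi_decode(x, hmm) for x, _ in test_seqs]
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    actual = np.concatenate([y for _, y in test_seqs])
    return actual, np.concatenate(preds)


def two_level_classification(
    train_seqs: list[Sequence],
    test_seqs: list[Sequence],
    kind: str = "hmm",
    n_components: int = 2,
    seed: int = 0,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    dim: int | None = None,
) -> EvaluationReport:
    """Classify, merge confusable classes, refit on merged labels, re-evaluate.

    ``dim`` optionally truncates the feature space to its first ``dim``
    columns (the leading principal components, when features are PCA scores).
    """
    if dim is not None:
        train_seqs = [(x[:, :dim], y) for x, y in train_seqs]
        test_seqs = [(x[:, :dim], y) for x, y in test_seqs]
    class_ids = sorted({int(c) for _, y in train_seqs for c in np.unique(y)})
    actual, predicted = _fit_and_predict(
        train_seqs, test_seqs, kind, n_components, seed
    )
    cm1 = confusion_matrix(actual, predicted, class_ids)
    merge = find_merges(cm1, threshold=merge_threshold)
    if merge.is_identity:
        cm2 = cm1
    else:
        train2 = [(x, merge.apply(y)) for x, y in train_seqs]
        test2 = [(x, merge.apply(y)) for x, y in test_seqs]
        actual2, predicted2 = _fit_and_predict(
            train2, test2, kind, n_components, seed
        )
        cm2 = confusion_matrix(actual2, predicted2, merge.group_ids)
    return EvaluationReport(
        confusion=cm2,
        per_class_accuracy=cm2.per_class_recall(),
        mean_accuracy=mean_accuracy(cm2),
        overall_accuracy=overall_accuracy(cm2),
        n_final_classes=merge.n_groups,
        merge_map=merge,
        level1_confusion=cm1,
        kind=kind,
        dim=dim,
    )


# ---------------------------------------------------------------------------
# Merge-convergence diagnostic
# ---------------------------------------------------------------------------

def merge_convergence_curve(
    actual: np.ndarray, predicted: np.ndarray, class_ids: list[int] | None = None
) -> np.ndarray:
    """Accuracy after greedily merging one class pair at a time (no refit).

    At each step the pair with the largest mutual off-diagonal confusion
    mass is merged (labels relabeled, predictions fixed) and the
    window-weighted accuracy recorded, until one class remains; the last
    value is 1.0 and the curve is non-decreasing.  A steeply converging
    curve indicates confusions concentrated among few class pairs.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if class_ids is None:
        class_ids = sorted({int(c) for c in np.concatenate([actual, predicted])})
    if len(class_ids) < 2:
        raise ValueError("need at least 2 classes")
    cm = confusion_matrix(actual, predicted, class_ids)
    curve = []
    while len(cm.class_ids) > 1:
        counts = cm.counts
        k = len(cm.class_ids)
        best, best_mass = None, -1.0
        for i in range(k):
            for j in range(i + 1, k):
                mass = counts[i, j] + counts[j, i]
                if mass > best_mass:
                    best, best_mass = (i, j), mass
        i, j = best
        mapping = {cid: cid for cid in cm.class_ids}
        mapping[cm.class_ids[j]] = cm.class_ids[i]
        cm = merge_confusion(cm, MergeMap(mapping=mapping))
        curve.append(overall_accuracy(cm))
    return np.array(curve)


# ---------------------------------------------------------------------------
# Model selection across feature dimensions
# ---------------------------------------------------------------------------

def model_selection(
    train_seqs: list[Sequence],
    test_seqs: list[Sequence],
    dims: range | list[int] = range(2, 11),
    kinds: tuple[str, ...] = ("gmm", "hmm"),
    n_components: int = 2,
    seed: int = 0,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
) -> tuple[tuple[str, int], dict[tuple[str, int], EvaluationReport]]:
    """Evaluate every (classifier kind, feature dimension) configuration.

    Features must carry at least ``max(dims)`` columns (leading principal
    components first).  Configurations are ranked by mean accuracy, then by
    more final classes (higher specificity), then by smaller dimension.
    """
    d_avail = train_seqs[0][0].shape[1]
    if max(dims) > d_avail:
        raise ValueError("feature matrix has fewer columns than max(dims)")
    reports: dict[tuple[str, int], EvaluationReport] = {}
    for kind in kinds:
        for dim in dims:
            reports[(kind, dim)] = two_level_classification(
                train_seqs, test_seqs, kind=kind, n_components=n_components,
                seed=seed, merge_threshold=merge_threshold, dim=dim,
            )
    best = min(
        reports,
        key=lambda key: (
            -reports[key].mean_accuracy,
            -reports[key].n_final_classes,
            key[1],
        ),
    )
    return best, reports
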