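"""Sequential forward selection (SFS) of feature groups.

A greedy wrapper: starting from the empty set, repeatedly add the feature
group whose inclusion maximizes cross-validated accuracy of a wrapped
classifier, until no group improves accuracy or ``max_k`` groups are chosen.
Selection operates on named groups (feature family by signal, e.g. the
"modified" wavelet coefficients of R) rather than single scalars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import fit_classifier_bank, gmm_classify
from .features import feature_groups, feature_registry


@dataclass
class SelectionTrace:
    """Chosen group names, in selection order, with accuracy after each."""

    chosen: list[str]
    accuracies: list[float]

    def __post_init__(self) -> None:
        if len(self.chosen) != len(self.accuracies):
            raise ValueError("chosen and accuracies must be parallel")
        for a in self.accuracies:
            if not 0.0 <= a <= 1.0:
                raise ValueError("accuracies must lie in [0, 1]")


def registry_group_indices() -> dict[str, list[int]]:
    """Column indices of every registry feature group (registry order)."""
    names = feature_registry()
    index = {n: i for i, n in enumerate(names)}
    return {g: [index[n] for n in members] for g, members in feature_groups().items()}


def default_classifier_factory(n_components: int = 1, seed: int = 0) -> Callable:
    """A GMM-bank classifier factory for wrapping inside SFS."""

    def fit_predict(x_train, y_train, x_test):
        by_class = {int(c): x_train[y_train == c] for c in np.unique(y_train)}
        bank = fit_classifier_bank(by_class, n_components=n_components, seed=seed)
        return gmm_classify(x_test, bank)

    return fit_predict


def _cv_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    cols: list[int],
    fit_predict: Callable,
    cv_folds: int,
    seed: int,
) -> float:
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    correct = total = 0
    for train_idx, test_idx in skf.split(x, y):
        pred = fit_predict(x[train_idx][:, cols], y[train_idx], x[test_idx][:, cols])
        correct += int(np.sum(pred == y[test_idx]))
        total += len(test_idx)
    return correct / total


def sequential_forward_selection(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    groups: dict[str, Sequence[int]] | None = None,
    classifier_factory: Callable | None = None,
    max_k: int | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionTrace:
    """Greedy forward selection of feature groups by cross-validated accuracy.

    ``groups`` maps group names to column indices of ``feature_matrix``
    (defaults to the registry's family-by-signal groups).  At each step the
    group with the highest stratified-CV accuracy when added is chosen (ties
    broken by group insertion order); selection stops when no group strictly
    improves accuracy, or after ``max_k`` groups.  Deterministic given
    ``seed``.
    """
    x = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    y = np.asarray(labels)
    if groups is None:
        groups = registry_group_indices()
    if not groups:
        raise ValueError("need at least one candidate group")
    fit_predict = classifier_factory or default_classifier_factory(seed=seed)
    if max_k is None:
        max_k = len(groups)

    chosen: list[str] = []
    chosen_cols: list[int] = []
    accuracies: list[float] = []
    best_so_far = -np.inf
    remaining = list(groups)
    while remaining and len(chosen) < max_k:
        step_best, step_acc = None, -np.inf
        for g in remaining:
            cols = chosen_cols + list(groups[g])
            acc = _cv_accuracy(x, y, cols, fit_predict, cv_folds, seed)
            if acc > step_acc:  # strict: ties keep the earlier group
                step_best, step_acc = g, acc
        if step_acc <= best_so_far:
            break
        chosen.append(step_best)
        chosen_cols += list(groups[step_best])
        accuracies.append(step_acc)
        best_so_far = step_acc
        remaining.remove(step_best)
    return SelectionTrace(chosen=chosen, accuracies=accuracies)
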