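"""Glue for the lab-phase feature space.

The classification feature space is built in two fitted stages: the
Kolmogorov-Smirnov wavelet-coefficient selector (20 positions of the
3-level Haar decomposition of R) and a PCA over those 20 coefficients whose
leading components (10 by default) are the classification features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import (
    CoefficientSelector,
    PCAProjection,
    apply_pca,
    fit_coefficient_selector,
    fit_pca,
    modified_wavelet_features,
)
from .signal_io import Window


@dataclass
class FeatureSpace:
    """Fitted selector + PCA mapping windows to classification features."""

    selector: CoefficientSelector
    pca: PCAProjection

    def transform(self, windows: list[Window]) -> np.ndarray:
        """Windows -> n x k matrix of wavelet-PCA scores."""
        wav = np.vstack([
            modified_wavelet_features(w, self.selector) for w in windows
        ])
        return apply_pca(self.pca, wav)


def fit_feature_space(
    train_windows: list[Window],
    n_coeffs: int = 20,
    pca_dims: int = 10,
) -> FeatureSpace:
    """Fit selector and PCA on labeled training windows only."""
    by_class: dict[int, list[Window]] = {}
    for w in train_windows:
        if w.class_id is None:
            raise ValueError("training windows must be labeled")
        by_class.setdefault(w.class_id, []).append(w)
    selector = fit_coefficient_selector(by_class, n_coeffs=n_coeffs)
    wav = np.vstack([modified_wavelet_features(w, selector) for w in train_windows])
    pca = fit_pca(wav, pca_dims)
    return FeatureSpace(selector=selector, pca=pca)


def windows_to_sequences(
    windows: list[Window], space: FeatureSpace
) -> tuple[np.ndarray, np.ndarray]:
    """One session's windows -> (feature matrix, label vector) sequence."""
    x = space.transform(windows)
    y = np.array([w.class_id for w in windows])
    return x, y
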