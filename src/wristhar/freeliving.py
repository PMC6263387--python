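"""Unsupervised identification of free-living activities from lab models.

A free-living session is a window sequence with no labels.  The pipeline:

1. estimate how many distinct activities K were performed, by fitting
   Gaussian mixtures over a range of K and selecting by BIC (the raw
   maximized log-likelihood is monotone in K and is recorded alongside);
2. temporally smooth the mixture's window assignments with an HMM whose
   states are the K clusters (transitions from the hard assignments,
   add-one smoothed; Viterbi decoding);
3. match every cluster to the laboratory activity class whose mixture
   means are nearest in feature space (Gaussian model matching);
4. read the matched classes' MET values off the activity dictionary to
   produce a per-window intensity timeline (light < 3.0 MET, moderate
   3.0-5.9, vigorous >= 6.0) and session summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import (
    ClassifierBank,
    GaussianComponent,
    HMMClassifier,
    MixtureModel,
    fit_class_mixture,
    viterbi_decode,
)
from .synthetic_data import intensity_for_met

#: Intensity codes used on timelines: light=1, moderate=2, vigorous=3.
INTENSITY_CODES = {"L": 1, "M": 2, "V": 3}

#: Observed free-living activity-type labels mapped to intensity codes.
OBSERVED_TYPE_INTENSITY = {
    "sitting": 1, "reclining": 1, "standing": 1, "squatting": 1,
    "walking": 2, "jogging": 3,
}


@dataclass
class SessionModel:
    """The unsupervised mixture model of one free-living session."""

    K: int
    mixture: MixtureModel
    cluster_models: list[MixtureModel]
    n_windows: int
    scores: dict[int, dict[str, float]] = field(default_factory=dict)
    assignments: np.ndarray | None = None  # 1-based cluster ids per window

    @property
    def dim(self) -> int:
        return self.mixture.dim


def _n_params(k: int, d: int) -> int:
    # weights (k-1) + means (k d) + full covariances (k d(d+1)/2)
    return (k - 1) + k * d + k * d * (d + 1) // 2


def estimate_num_activities(
    features: np.ndarray,
    k_range: range | list[int] = range(1, 9),
    seed: int = 0,
    n_components_per_cluster: int = 1,
) -> SessionModel:
    """Estimate the number of activities in a session by mixture fitting.

    Fits an LBG-initialized EM mixture for every candidate K and keeps the
    K minimizing BIC; per-K log-likelihoods and BIC scores are retained in
    ``scores``.  Each selected cluster is additionally available as its own
    (by default single-Gaussian) model for downstream matching.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n, d = features.shape
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    if n < max(k_range) * 10:
        raise ValueError("need at least 10 windows per candidate cluster")
    scores: dict[int, dict[str, float]] = {}
    fits: dict[int, MixtureModel] = {}
    for k in k_range:
        mix = fit_class_mixture(features, n_components=k, seed=seed)
        ll = float(mix.log_density(features).sum())
        bic = -2.0 * ll + _n_params(len(mix.components), d) * np.log(n)
        scores[k] = {"loglik": ll, "bic": float(bic)}
        fits[k] = mix
    best_k = min(k_range, key=lambda k: scores[k]["bic"])
    mixture = fits[best_k]
    cluster_models = _cluster_models(
        mixture, features, n_components_per_cluster, seed
    )
    return SessionModel(
        K=len(mixture.components),
        mixture=mixture,
        cluster_models=cluster_models,
        n_windows=n,
        scores=scores,
    )


def _hard_assignments(mixture: MixtureModel, features: np.ndarray) -> np.ndarray:
    """1-based maximum-responsibility component per window."""
    from .classifiers import _gauss_logpdf

    log_r = np.vstack([
        np.log(c.weight) + _gauss_logpdf(features, c.mean, c.cov)
        for c in mixture.components
    ])
    return np.argmax(log_r, axis=0) + 1


def _cluster_models(
    mixture: MixtureModel,
    features: np.ndarray,
    n_components_per_cluster: int,
    seed: int,
) -> list[MixtureModel]:
    if n_components_per_cluster == 1:
        return [
            MixtureModel([GaussianComponent(1.0, c.mean, c.cov)])
            for c in mixture.components
        ]
    assign = _hard_assignments(mixture, features)
    models = []
    for j, comp in enumerate(mixture.components, start=1):
        pts = features[assign == j]
        if len(pts) > features.shape[1] * n_components_per_cluster:
            models.append(fit_class_mixture(
                pts, n_components=n_components_per_cluster, seed=seed + j
            ))
        else:
            models.append(MixtureModel([GaussianComponent(1.0, comp.mean, comp.cov)]))
    return models


def cluster_session(
    features: np.ndarray,
    session: SessionModel,
    seed: int = 0,
) -> SessionModel:
    """Assign windows to the session's K clusters with temporal smoothing.

    An HMM over the K mixture components (emissions = the component
    Gaussians, transitions = add-one-smoothed bigrams of the hard
    maximum-responsibility labels) is decoded by Viterbi; the decoded path
    becomes the session's per-window cluster assignments (1-based).
    """
    from .classifiers import estimate_transitions

    features = np.atleast_2d(np.asarray(features, dtype=float))
    raw = _hard_assignments(session.mixture, features)
    states = list(range(1, session.K + 1))
    if session.K == 1:
        session.assignments = raw
        return session
    transition, initial = estimate_transitions([raw], states)
    hmm = HMMClassifier(
        states=states,
        transition=transition,
        initial=initial,
        emissions={
            j: MixtureModel([GaussianComponent(1.0, c.mean, c.cov)])
            for j, c in enumerate(session.mixture.components, start=1)
        },
    )
    session.assignments = viterbi_decode(features, hmm)
    return session


@dataclass
class MatchResult:
    """Per-cluster lab-class match: cluster j -> matched_class[j-1]."""

    matched_class: np.ndarray  # lab class id per cluster
    distance: np.ndarray       # Euclidean mean-to-mean distance per cluster

    def __post_init__(self) -> None:
        self.matched_class = np.asarray(self.matched_class, dtype=int)
        self.distance = np.asarray(self.distance, dtype=float)
        if np.any(self.distance < 0):
            raise ValueError("distances must be non-negative")


def match_models(session: SessionModel, lab_bank: ClassifierBank) -> MatchResult:
    """Match every session cluster to its nearest laboratory class.

    The distance between a cluster and a lab class is the minimum Euclidean
    distance between any of the cluster's component means and any of the
    class's component means; each cluster takes the arg-min class (ties to
    the lower class id).  Several clusters may match the same class.
    """
    if session.dim != lab_bank.dim:
        raise ValueError("session and lab bank dimensions differ")
    class_ids = lab_bank.class_ids
    matched, dists = [], []
    for cluster in session.cluster_models:
        cmeans = cluster.means
        best_cid, best_d = None, np.inf
        for cid in class_ids:  # ascending: ties keep the lower id
            lmeans = lab_bank.models[cid].means
            d = np.linalg.norm(
                cmeans[:, None, :] - lmeans[None, :, :], axis=2
            ).min()
            if d < best_d:
                best_cid, best_d = cid, d
        matched.append(best_cid)
        dists.append(best_d)
    return MatchResult(matched_class=np.array(matched), distance=np.array(dists))


@dataclass
class IntensityTimeline:
    """Per-window matched class, MET value, and intensity code (1/2/3)."""

    class_ids: np.ndarray
    met: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.class_ids = np.asarray(self.class_ids, dtype=int)
        self.met = np.asarray(self.met, dtype=float)
        self.codes = np.asarray(self.codes, dtype=int)
        if not (len(self.class_ids) == len(self.met) == len(self.codes)):
            raise ValueError("timeline tracks must have equal length")


def met_timeline(
    assignments: np.ndarray,
    match: MatchResult,
    dictionary: pd.DataFrame,
) -> IntensityTimeline:
    """Translate cluster assignments into a MET / intensity timeline.

    ``assignments`` are 1-based cluster ids; each window inherits the MET of
    its cluster's matched lab class, and the intensity code from the MET
    bands (light < 3.0 -> 1, moderate 3.0-5.9 -> 2, vigorous >= 6.0 -> 3).
    """
    assignments = np.asarray(assignments, dtype=int)
    class_ids = match.matched_class[assignments - 1]
    mets, codes = [], []
    for cid in class_ids:
        if cid not in dictionary.index:
            raise KeyError(f"class {cid} missing from activity dictionary")
        met = float(dictionary.loc[cid, "met"])
        mets.append(met)
        codes.append(INTENSITY_CODES[intensity_for_met(met)])
    return IntensityTimeline(
        class_ids=class_ids, met=np.array(mets), codes=np.array(codes)
    )


def observed_intensity_codes(type_labels: list[str]) -> np.ndarray:
    """Map observed activity-type labels to intensity codes (1/2/3)."""
    try:
        return np.array([OBSERVED_TYPE_INTENSITY[t] for t in type_labels])
    except KeyError as exc:
        raise KeyError(f"unknown observed activity type {exc}") from exc


def intensity_correlation(
    estimated: np.ndarray, observed: np.ndarray, method: str = "pearson"
) -> float:
    """Correlation between estimated and observed per-window intensity codes.

    Pearson by default (Spearman via ``method="spearman"``).  Returns NaN
    when either side has zero variance (correlation undefined).
    """
    est = np.asarray(estimated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if len(est) != len(obs):
        raise ValueError("sequences must have equal length")
    if len(est) < 2:
        raise ValueError("need at least 2 windows")
    if est.std() == 0 or obs.std() == 0:
        return float("nan")
    if method == "spearman":
        from scipy.stats import spearmanr

        return float(spearmanr(est, obs).statistic)
    if method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    return float(np.corrcoef(est, obs)[0, 1])


@dataclass
class SessionSummary:
    """Percent of observed session time per matched class and intensity."""

    class_percent: dict[int, float]
    intensity_percent: dict[str, float]
    total_time_s: float


def session_summary(
    timeline: IntensityTimeline, window_s: float = 10.0
) -> SessionSummary:
    """Summarize a timeline as percentages of observed window time."""
    n = len(timeline.class_ids)
    if n == 0:
        raise ValueError("timeline is empty")
    class_percent = {
        int(cid): 100.0 * np.sum(timeline.class_ids == cid) / n
        for cid in np.unique(timeline.class_ids)
    }
    code_names = {v: k for k, v in INTENSITY_CODES.items()}
    intensity_percent = {
        code_names[int(c)]: 100.0 * np.sum(timeline.codes == c) / n
        for c in np.unique(timeline.codes)
    }
    return SessionSummary(
        class_percent=class_percent,
        intensity_percent=intensity_percent,
        total_time_s=n * window_s,
    )
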