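"""Gaussian mixture and hidden Markov classifiers for activity windows.

Each activity class is modeled by a full-covariance Gaussian mixture fitted
with expectation-maximization, initialized by Linde-Buzo-Gray (LBG) splitting
k-means.  The supervised classifiers are:

* GMM: per-window maximum a-posteriori class under the per-class mixtures
  (static; each window independent);
* HMM: one hidden state per class, that class's mixture as the emission
  density, transitions estimated from training label sequences, and the
  most-likely state path decoded by the Viterbi algorithm (dynamic; exploits
  temporal continuity of activities).

EM and Viterbi are implemented here in log-domain NumPy; their correctness
is pinned by brute-force and library oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

DEFAULT_N_COMPONENTS = 2
DEFAULT_COV_FLOOR = 1e-6
DEFAULT_EM_TOL = 1e-6
DEFAULT_EM_MAX_ITER = 200
LBG_EPS_SCALE = 0.01


class ComponentPrunedWarning(UserWarning):
    """An EM mixture component lost all responsibility mass and was pruned."""


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    """Symmetrize and clip eigenvalues at the regularization floor."""
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _gauss_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate normal log-density of rows of x (Cholesky-based)."""
    x = np.atleast_2d(x)
    d = x.shape[1]
    chol = np.linalg.cholesky(cov)
    dev = np.linalg.solve(chol, (x - mean).T)
    maha = np.sum(dev**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


@dataclass
class GaussianComponent:
    """One weighted Gaussian in a mixture."""

    weight: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if not (0.0 < self.weight <= 1.0 + 1e-12):
            raise ValueError("weight must be in (0, 1]")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")


@dataclass
class MixtureModel:
    """A Gaussian mixture modeling one activity class in feature space."""

    components: list[GaussianComponent]
    class_id: int | None = None

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")

    @property
    def dim(self) -> int:
        return len(self.components[0].mean)

    @property
    def means(self) -> np.ndarray:
        return np.vstack([c.mean for c in self.components])

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Mixture log-density at the rows of x."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        parts = np.vstack([
            np.log(c.weight) + _gauss_logpdf(x, c.mean, c.cov)
            for c in self.components
        ])
        return logsumexp(parts, axis=0)


# ---------------------------------------------------------------------------
# LBG initialization and EM
# ---------------------------------------------------------------------------

def _lloyd(data: np.ndarray, centroids: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Plain Lloyd k-means refinement; empty clusters keep their centroid."""
    for _ in range(max_iter):
        d2 = ((data[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        new = centroids.copy()
        for j in range(len(centroids)):
            pts = data[assign == j]
            if len(pts):
                new[j] = pts.mean(axis=0)
        if np.allclose(new, centroids, atol=1e-12):
            break
        centroids = new
    return centroids


def lbg_init(
    data: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    eps_scale: float = LBG_EPS_SCALE,
    cov_floor: float = DEFAULT_COV_FLOOR,
) -> list[GaussianComponent]:
    """Linde-Buzo-Gray splitting initialization for a k-component mixture.

    Starting from the global mean, centroids are repeatedly split by a
    +/- epsilon perturbation (epsilon = ``eps_scale`` times the per-dimension
    standard deviation) and refined by k-means until k centroids exist.
    When a full doubling would overshoot k, only the highest-distortion
    centroids are split.  Initial weights are cluster occupancies;
    covariances are within-cluster covariances (floored).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = data.shape
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n data points")
    rng = np.random.default_rng(seed)
    eps = eps_scale * np.maximum(data.std(axis=0), 1e-12)
    centroids = data.mean(axis=0, keepdims=True)
    while len(centroids) < k:
        d2 = ((data[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        distortion = np.array([
            d2[assign == j, j].sum() for j in range(len(centroids))
        ])
        n_split = min(k - len(centroids), len(centroids))
        split_idx = np.argsort(-distortion)[:n_split]
        keep = np.delete(centroids, split_idx, axis=0)
        jitter = rng.normal(0.0, 1.0, size=(n_split, d)) * eps
        centroids = np.vstack([
            keep, centroids[split_idx] + jitter, centroids[split_idx] - jitter
        ])
        centroids = _lloyd(data, centroids)
    d2 = ((data[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    comps = []
    for j in range(k):
        pts = data[assign == j]
        weight = max(len(pts), 1) / n
        mean = pts.mean(axis=0) if len(pts) else centroids[j]
        cov = np.cov(pts, rowvar=False) if len(pts) > d else np.eye(d)
        comps.append(GaussianComponent(
            weight=weight, mean=mean, cov=_floor_cov(np.atleast_2d(cov), cov_floor)
        ))
    total = sum(c.weight for c in comps)
    for c in comps:
        c.weight /= total
    return comps


def em_fit(
    data: np.ndarray,
    init: list[GaussianComponent],
    tol: float = DEFAULT_EM_TOL,
    max_iter: int = DEFAULT_EM_MAX_ITER,
    cov_floor: float = DEFAULT_COV_FLOOR,
    class_id: int | None = None,
) -> MixtureModel:
    """Fit a full-covariance Gaussian mixture by expectation-maximization.

    The per-iteration mean log-likelihood is asserted non-decreasing (up to
    floating-point slack); iteration stops when the relative improvement
    falls below ``tol`` or at ``max_iter``.  Components whose responsibility
    mass collapses are pruned with a warning.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = data.shape
    weights = np.array([c.weight for c in init], dtype=float)
    means = np.vstack([c.mean for c in init]).astype(float)
    covs = np.stack([c.cov for c in init]).astype(float)
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step
        log_r = np.vstack([
            np.log(weights[j]) + _gauss_logpdf(data, means[j], covs[j])
            for j in range(len(weights))
        ])
        norm = logsumexp(log_r, axis=0)
        ll = float(norm.mean())
        assert ll >= prev_ll - 1e-8, "EM log-likelihood decreased"
        if np.isfinite(prev_ll) and ll - prev_ll < tol * max(abs(prev_ll), 1.0):
            prev_ll = ll
            break
        prev_ll = ll
        resp = np.exp(log_r - norm)
        # M step (prune collapsed components)
        mass = resp.sum(axis=1)
        keep = mass > max(d + 1, 2) * 1e-10
        if not np.all(keep):
            warnings.warn(
                "pruning mixture component(s) with no responsibility mass",
                ComponentPrunedWarning,
            )
            resp, mass = resp[keep], mass[keep]
            weights, means, covs = weights[keep], means[keep], covs[keep]
        weights = mass / n
        weights /= weights.sum()
        means = (resp @ data) / mass[:, None]
        for j in range(len(weights)):
            dev = data - means[j]
            cov = (resp[j][:, None] * dev).T @ dev / mass[j]
            covs[j] = _floor_cov(cov, cov_floor)
    comps = [
        GaussianComponent(weight=float(w), mean=m, cov=c)
        for w, m, c in zip(weights, means, covs)
    ]
    total = sum(c.weight for c in comps)
    for c in comps:
        c.weight /= total
    return MixtureModel(components=comps, class_id=class_id)


def fit_class_mixture(
    data: np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
    seed: int = 0,
    class_id: int | None = None,
    tol: float = DEFAULT_EM_TOL,
    max_iter: int = DEFAULT_EM_MAX_ITER,
    cov_floor: float = DEFAULT_COV_FLOOR,
) -> MixtureModel:
    """LBG-initialized EM fit of one class's mixture (components capped at n)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    k = min(n_components, len(data))
    init = lbg_init(data, k, seed=seed, cov_floor=cov_floor)
    return em_fit(data, init, tol=tol, max_iter=max_iter,
                  cov_floor=cov_floor, class_id=class_id)


# ---------------------------------------------------------------------------
# Supervised GMM classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifierBank:
    """Per-class mixtures plus class priors; the GMM classifier."""

    models: dict[int, MixtureModel]
    priors: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("bank must contain at least one class model")
        if not self.priors:
            p = 1.0 / len(self.models)
            self.priors = {cid: p for cid in self.models}
        total = sum(self.priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        dims = {m.dim for m in self.models.values()}
        if len(dims) != 1:
            raise ValueError("all class models must share one dimension")

    @property
    def class_ids(self) -> list[int]:
        return sorted(self.models)

    @property
    def dim(self) -> int:
        return next(iter(self.models.values())).dim

    def log_joint(self, x: np.ndarray) -> np.ndarray:
        """n x n_classes matrix of log prior + mixture log-density."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.dim:
            raise ValueError("dimension mismatch")
        return np.column_stack([
            np.log(self.priors[cid]) + self.models[cid].log_density(x)
            for cid in self.class_ids
        ])


def fit_classifier_bank(
    features_by_class: dict[int, np.ndarray],
    n_components: int = DEFAULT_N_COMPONENTS,
    seed: int = 0,
    **em_kwargs,
) -> ClassifierBank:
    """Fit one mixture per class; priors proportional to class window counts."""
    models, counts = {}, {}
    for i, (cid, mat) in enumerate(sorted(features_by_class.items())):
        models[cid] = fit_class_mixture(
            mat, n_components=n_components, seed=seed + i, class_id=cid, **em_kwargs
        )
        counts[cid] = len(mat)
    total = sum(counts.values())
    priors = {cid: counts[cid] / total for cid in models}
    return ClassifierBank(models=models, priors=priors)


def gmm_classify(vectors: np.ndarray, bank: ClassifierBank) -> np.ndarray:
    """MAP class per vector; ties resolved toward the lower class id."""
    lj = bank.log_joint(vectors)
    ids = np.array(bank.class_ids)
    return ids[np.argmax(lj, axis=1)]  # argmax takes the first (lowest id) on ties


# ---------------------------------------------------------------------------
# HMM with mixture emissions
# ---------------------------------------------------------------------------

@dataclass
class HMMClassifier:
    """States are activity classes; emissions are the class mixtures."""

    states: list[int]
    transition: np.ndarray  # rows sum to 1
    initial: np.ndarray
    emissions: dict[int, MixtureModel]

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        k = len(self.states)
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    @property
    def dim(self) -> int:
        return next(iter(self.emissions.values())).dim


def estimate_transitions(
    label_sequences: list[np.ndarray], states: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Add-one-smoothed bigram transition matrix and initial distribution.

    Counts consecutive window-label pairs within each sequence; Laplace
    smoothing keeps unseen transitions possible when decoding new sessions.
    """
    if not label_sequences:
        raise ValueError("need at least one label sequence")
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((k, k))
    starts = np.zeros(k)
    for seq in label_sequences:
        seq = np.asarray(seq)
        if len(seq) == 0:
            continue
        for s in seq:
            if int(s) not in index:
                raise ValueError(f"unknown label {s}")
        starts[index[int(seq[0])]] += 1
        for a, b in zip(seq[:-1], seq[1:]):
            counts[index[int(a)], index[int(b)]] += 1
    transition = (counts + 1.0) / (counts + 1.0).sum(axis=1, keepdims=True)
    initial = (starts + 1.0) / (starts + 1.0).sum()
    return transition, initial


def fit_hmm(
    bank: ClassifierBank, label_sequences: list[np.ndarray]
) -> HMMClassifier:
    """Couple the bank's mixtures to transitions estimated from label runs."""
    states = bank.class_ids
    transition, initial = estimate_transitions(label_sequences, states)
    return HMMClassifier(
        states=states, transition=transition, initial=initial,
        emissions={cid: bank.models[cid] for cid in states},
    )


def viterbi_decode(vectors: np.ndarray, hmm: HMMClassifier) -> np.ndarray:
    """Most-likely state path for a window sequence (log-domain Viterbi).

    Ties at every maximization step resolve toward the lower state id
    (states are kept sorted, and argmax takes the first maximizer).
    """
    x = np.atleast_2d(np.asarray(vectors, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("sequence must be non-empty")
    if x.shape[1] != hmm.dim:
        raise ValueError("dimension mismatch")
    states = hmm.states
    k = len(states)
    log_b = np.column_stack([
        hmm.emissions[s].log_density(x) for s in states
    ])  # T x k
    log_a = np.log(hmm.transition)
    t_len = x.shape[0]
    delta = np.log(hmm.initial) + log_b[0]
    back = np.zeros((t_len, k), dtype=int)
    for t in range(1, t_len):
        scores = delta[:, None] + log_a  # prev x next
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(k)] + log_b[t]
    path = np.zeros(t_len, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return np.array([states[i] for i in path])
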