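"""Window features: time/frequency statistics, Haar wavelet coefficients with
Kolmogorov-Smirnov selection, and PCA projections.

The discriminative core of the pipeline is the "modified" wavelet feature: a
3-level orthonormal Haar decomposition of the resultant signal R yields 1000
coefficients per 10 s window, and the 20 positions whose within-class
distribution deviates most from a moment-matched Gaussian (largest
Kolmogorov-Smirnov statistic, a sign of multimodality) are selected on
training data.  A PCA fitted on those 20 coefficients defines the feature
space in which activity classes are modeled.

A full 130-feature registry (time-domain statistics, spectral summaries,
per-signal principal-component scores, selected wavelet coefficients, subband
energies, axis correlations) is exposed for wrapper feature selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from sklearn.decomposition import PCA

from .signal_io import Window

WAVELET = "haar"
WAVELET_LEVEL = 3
WAVELET_MODE = "periodization"

#: Subband layout of the flat coefficient vector for a 1000-sample window.
SUBBANDS = (("A3", 0, 125), ("D3", 125, 250), ("D2", 250, 500), ("D1", 500, 1000))

N_SELECTED_COEFFS = 20
PEAK_PROMINENCE_FRACTION = 0.05


class NotFittedError(RuntimeError):
    """An estimator was applied before being fitted."""


class ConstantSignalWarning(UserWarning):
    """A window signal was (numerically) constant; higher moments set to 0."""


# ---------------------------------------------------------------------------
# Wavelet decomposition
# ---------------------------------------------------------------------------

@dataclass
class WaveletDecomposition:
    """Flat 3-level orthonormal Haar coefficients, ordered [A3, D3, D2, D1]."""

    coefficients: np.ndarray
    level: int = WAVELET_LEVEL

    def subband(self, name: str) -> np.ndarray:
        for nm, lo, hi in _subbands_for(len(self.coefficients)):
            if nm == name:
                return self.coefficients[lo:hi]
        raise KeyError(name)


def _subbands_for(n: int) -> tuple[tuple[str, int, int], ...]:
    n8 = n // 8
    return (
        ("A3", 0, n8),
        ("D3", n8, 2 * n8),
        ("D2", 2 * n8, 4 * n8),
        ("D1", 4 * n8, n),
    )


def haar_decompose(sig: np.ndarray) -> WaveletDecomposition:
    """3-level orthonormal Haar decomposition of a signal.

    The periodized orthonormal filter bank preserves energy exactly
    (Parseval) and is perfectly invertible; the flat coefficient vector has
    the input's length, ordered approximation-first: [A3, D3, D2, D1].
    """
    sig = np.asarray(sig, dtype=float)
    if sig.ndim != 1 or len(sig) == 0 or len(sig) % 8 != 0:
        raise ValueError("signal length must be a positive multiple of 8")
    coeffs = pywt.wavedec(sig, WAVELET, mode=WAVELET_MODE, level=WAVELET_LEVEL)
    return WaveletDecomposition(coefficients=np.concatenate(coeffs))


def haar_reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Invert :func:`haar_decompose` (exact up to floating-point roundoff)."""
    n = len(decomp.coefficients)
    parts = [decomp.coefficients[lo:hi] for _, lo, hi in _subbands_for(n)]
    return pywt.waverec(parts, WAVELET, mode=WAVELET_MODE)


def coefficients_to_signal(coefficients: np.ndarray) -> np.ndarray:
    """Build the time-domain signal whose Haar decomposition is ``coefficients``."""
    return haar_reconstruct(WaveletDecomposition(np.asarray(coefficients, float)))


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov statistic and coefficient selection
# ---------------------------------------------------------------------------

def ks_statistic_columns(values: np.ndarray) -> np.ndarray:
    """KS distance to a moment-matched normal, column-wise over a matrix.

    For each column, compares the empirical CDF with the CDF of a Gaussian
    sharing the column's mean and variance:  D = sup_x |F_n(x) - G(x)|,
    evaluated just before and at every sample point.  Columns with zero
    variance get D = 0 by convention.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    n, p = v.shape
    if n < 2:
        raise ValueError("need at least 2 values per column")
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    out = np.zeros(p)
    ok = sd > 0
    if np.any(ok):
        xs = np.sort(v[:, ok], axis=0)
        g = sp_stats.norm.cdf((xs - mean[ok]) / sd[ok])
        i = np.arange(1, n + 1)[:, None] / n
        im1 = np.arange(0, n)[:, None] / n
        d = np.maximum(i - g, g - im1)
        out[ok] = np.clip(d.max(axis=0), 0.0, 1.0)
    return out


def ks_statistic(values: np.ndarray) -> float:
    """KS distance of a sample to the normal with the sample's mean/variance."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    return float(ks_statistic_columns(values[:, None])[0])


@dataclass
class CoefficientSelector:
    """The selected wavelet-coefficient positions and their KS scores.

    ``positions`` are sorted indices into the flat [A3, D3, D2, D1]
    coefficient vector; ``ks_scores`` are the per-position maxima of the
    within-class KS statistics (parallel to ``positions``).
    """

    positions: np.ndarray
    ks_scores: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.ks_scores = np.asarray(self.ks_scores, dtype=float)
        if len(np.unique(self.positions)) != len(self.positions):
            raise ValueError("positions must be distinct")
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.ks_scores = self.ks_scores[order]


def select_positions(
    coeff_matrices_by_class: dict[int, np.ndarray],
    n_coeffs: int = N_SELECTED_COEFFS,
) -> CoefficientSelector:
    """Rank coefficient positions by within-class deviation from normality.

    For every position, the KS statistic of that coefficient's values is
    computed within each class; the position's score is its maximum over
    classes (a coefficient is kept if it is strongly non-Gaussian for any
    single activity).  The ``n_coeffs`` top-scoring positions are returned,
    ties broken toward the lower position index.
    """
    if len(coeff_matrices_by_class) < 2:
        raise ValueError("need at least 2 classes to fit the selector")
    scores = None
    for class_id, mat in coeff_matrices_by_class.items():
        mat = np.asarray(mat, dtype=float)
        if mat.shape[0] < 8:
            raise ValueError(f"class {class_id} has fewer than 8 windows")
        d = ks_statistic_columns(mat)
        scores = d if scores is None else np.maximum(scores, d)
    # stable sort on (-score, position) => ties go to the lower index
    order = np.lexsort((np.arange(len(scores)), -scores))
    chosen = order[:n_coeffs]
    return CoefficientSelector(positions=chosen, ks_scores=scores[chosen])


def fit_coefficient_selector(
    windows_by_class: dict[int, list[Window]],
    n_coeffs: int = N_SELECTED_COEFFS,
    signal: str = "r",
) -> CoefficientSelector:
    """Fit the wavelet-coefficient selector on labeled training windows.

    Decomposes the chosen signal (the resultant R by default) of every
    window and delegates to :func:`select_positions`.
    """
    mats = {
        cid: np.vstack([haar_decompose(w.signal(signal)).coefficients for w in ws])
        for cid, ws in windows_by_class.items()
    }
    return select_positions(mats, n_coeffs=n_coeffs)


def modified_wavelet_features(
    window: Window, selector: CoefficientSelector, signal: str = "r"
) -> np.ndarray:
    """The window's Haar coefficients at the selector's positions."""
    decomp = haar_decompose(window.signal(signal))
    return decomp.coefficients[selector.positions]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAProjection:
    """An affine projection onto the top-k principal axes of training data."""

    mean: np.ndarray
    components: np.ndarray  # k x d, orthonormal rows, decreasing variance
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)

    @property
    def k(self) -> int:
        return self.components.shape[0]


def fit_pca(matrix: np.ndarray, k: int) -> PCAProjection:
    """Fit a k-component PCA (centered, components by decreasing variance)."""
    matrix = np.asarray(matrix, dtype=float)
    if k > matrix.shape[1]:
        raise ValueError("k cannot exceed the input dimension")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(matrix)
    return PCAProjection(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
    )


def apply_pca(projection: PCAProjection | None, vectors: np.ndarray) -> np.ndarray:
    """Project vectors (n x d or d,) onto the fitted principal axes."""
    if projection is None:
        raise NotFittedError("PCA projection has not been fitted")
    v = np.asarray(vectors, dtype=float)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[None, :]
    if v.shape[1] != projection.mean.shape[0]:
        raise ValueError("dimension mismatch")
    out = (v - projection.mean) @ projection.components.T
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Scalar feature families
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must be parallel")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _moments(sig: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(sig.mean())
    sd = float(sig.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            "constant signal: skewness/kurtosis set to 0", ConstantSignalWarning,
            stacklevel=3,
        )
        return mean, 0.0, 0.0, 0.0
    z = (sig - mean) / sig.std(ddof=0)  # standardized 3rd/4th moments
    return mean, sd, float(np.mean(z**3)), float(np.mean(z**4))


def time_domain_features(window: Window) -> FeatureVector:
    """Per-signal moments and energies, plus low-percentile squared sums.

    For each of x, y, z, r: mean, standard deviation (n-1 denominator),
    skewness and kurtosis (standardized third/fourth moments; 0 for constant
    signals), energy (sum of squares) and RMS.  For y and z additionally the
    sum of squared samples lying below the signal's 25th and 5th percentiles.
    """
    names: list[str] = []
    vals: list[float] = []
    for s in Window.SIGNALS:
        sig = window.signal(s)
        mean, sd, skew, kurt = _moments(sig)
        energy = float(np.sum(sig**2))
        rms = float(np.sqrt(np.mean(sig**2)))
        names += [f"time:{s}:{stat}" for stat in
                  ("mean", "sd", "skew", "kurt", "energy", "rms")]
        vals += [mean, sd, skew, kurt, energy, rms]
    for s in ("y", "z"):
        sig = window.signal(s)
        for pct in (25, 5):
            thresh = np.percentile(sig, pct)
            below = sig[sig < thresh]
            names.append(f"time:{s}:sqsum_p{pct:02d}")
            vals.append(float(np.sum(below**2)))
    return FeatureVector(np.array(vals), names)


def _spectrum(sig: np.ndarray, sample_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    mag = np.abs(np.fft.rfft(sig)) / len(sig)
    freqs = np.fft.rfftfreq(len(sig), d=1.0 / sample_rate_hz)
    return freqs, mag


def freq_domain_features(
    window: Window,
    sample_rate_hz: float = 100.0,
    peak_prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
) -> FeatureVector:
    """Sub-5 Hz spectral summaries per signal.

    From the DFT magnitude spectrum of the 1000-sample window (0.1 Hz bins):
    the maximum magnitude over [1, 5] Hz, the sum of magnitudes over (0, 5) Hz
    (0 Hz bin excluded), and the number of spectral peaks below 5 Hz with
    prominence above ``peak_prominence_fraction`` of the band maximum.
    """
    if sample_rate_hz <= 10:
        raise ValueError("sample_rate_hz must exceed 10 Hz")
    names: list[str] = []
    vals: list[float] = []
    for s in Window.SIGNALS:
        freqs, mag = _spectrum(window.signal(s), sample_rate_hz)
        band_1_5 = (freqs >= 1.0 - 1e-9) & (freqs <= 5.0 + 1e-9)
        band_0_5 = (freqs > 0) & (freqs < 5.0 - 1e-9)
        max_mag = float(mag[band_1_5].max()) if band_1_5.any() else 0.0
        sum_mag = float(mag[band_0_5].sum())
        band = mag[band_0_5]
        band_max = band.max() if band.size else 0.0
        if band_max > 0:
            peaks, _ = sp_signal.find_peaks(
                band, prominence=peak_prominence_fraction * band_max
            )
            n_peaks = float(len(peaks))
        else:
            n_peaks = 0.0
        names += [f"freq:{s}:{stat}" for stat in ("maxmag_1_5", "summag_0_5", "npeaks")]
        vals += [max_mag, sum_mag, n_peaks]
    return FeatureVector(np.array(vals), names)


def _extra_time_features(window: Window) -> FeatureVector:
    """Robust range/dispersion statistics, spectral shape, and axis coupling."""
    names: list[str] = []
    vals: list[float] = []
    for s in Window.SIGNALS:
        sig = window.signal(s)
        q75, q50, q25 = np.percentile(sig, [75, 50, 25])
        names += [f"extra:{s}:{stat}" for stat in ("min", "max", "median", "iqr", "mad")]
        vals += [float(sig.min()), float(sig.max()), float(q50),
                 float(q75 - q25), float(np.median(np.abs(sig - q50)))]
    for s in Window.SIGNALS:
        freqs, mag = _spectrum(window.signal(s), 100.0)
        nz = mag[1:]
        dom = float(freqs[1:][np.argmax(nz)]) if nz.size else 0.0
        p = nz / nz.sum() if nz.sum() > 0 else None
        ent = float(-np.sum(p * np.log(p, where=p > 0, out=np.zeros_like(p)))) if p is not None else 0.0
        names += [f"extra:{s}:domfreq", f"extra:{s}:specent"]
        vals += [dom, ent]
    for s in Window.SIGNALS:
        sig = window.signal(s)
        centered = sig - sig.mean()
        mcr = float(np.sum(np.diff(np.signbit(centered)) != 0)) / len(sig)
        names.append(f"extra:{s}:mcr")
        vals.append(mcr)
    for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
        sa, sb = window.signal(a), window.signal(b)
        if sa.std() == 0 or sb.std() == 0:
            corr = 0.0
        else:
            corr = float(np.corrcoef(sa, sb)[0, 1])
        names.append(f"corr:{a}{b}")
        vals.append(corr)
    for s in ("x", "y", "z"):
        sig = window.signal(s)
        names.append(f"extra:{s}:jerk")
        vals.append(float(np.mean(np.abs(np.diff(sig)))))
    return FeatureVector(np.array(vals), names)


def _subband_energy_features(window: Window) -> FeatureVector:
    names: list[str] = []
    vals: list[float] = []
    for s in Window.SIGNALS:
        decomp = haar_decompose(window.signal(s))
        for band, _, _ in SUBBANDS:
            names.append(f"wenergy:{s}:{band}")
            vals.append(float(np.sum(decomp.subband(band) ** 2)))
    return FeatureVector(np.array(vals), names)


# ---------------------------------------------------------------------------
# Per-signal window PCA ("principal component features")
# ---------------------------------------------------------------------------

def fit_signal_pcas(
    windows: list[Window], n_components: int = 4
) -> dict[str, PCAProjection]:
    """Fit, per signal, a PCA over raw training windows (rows = windows)."""
    pcas = {}
    for s in Window.SIGNALS:
        mat = np.vstack([w.signal(s) for w in windows])
        pcas[s] = fit_pca(mat, n_components)
    return pcas


def pc_features(
    window: Window, signal_pcas: dict[str, PCAProjection]
) -> FeatureVector:
    """First principal-component scores of each raw signal in the window."""
    names: list[str] = []
    vals: list[float] = []
    for s in Window.SIGNALS:
        scores = apply_pca(signal_pcas[s], window.signal(s))
        for i, v in enumerate(scores, start=1):
            names.append(f"pc:{s}:{i}")
            vals.append(float(v))
    return FeatureVector(np.array(vals), names)


# ---------------------------------------------------------------------------
# Full registry and extractor
# ---------------------------------------------------------------------------

def feature_registry() -> list[str]:
    """The canonical, versioned 130-name feature registry (fixed order)."""
    names: list[str] = []
    for s in Window.SIGNALS:
        names += [f"time:{s}:{stat}" for stat in
                  ("mean", "sd", "skew", "kurt", "energy", "rms")]
    for s in ("y", "z"):
        names += [f"time:{s}:sqsum_p25", f"time:{s}:sqsum_p05"]
    for s in Window.SIGNALS:
        names += [f"freq:{s}:{stat}" for stat in ("maxmag_1_5", "summag_0_5", "npeaks")]
    for s in Window.SIGNALS:
        names += [f"pc:{s}:{i}" for i in range(1, 5)]
    names += [f"wavelet:r:{i:02d}" for i in range(N_SELECTED_COEFFS)]
    for s in Window.SIGNALS:
        names += [f"wenergy:{s}:{band}" for band, _, _ in SUBBANDS]
    for s in Window.SIGNALS:
        names += [f"extra:{s}:{stat}" for stat in ("min", "max", "median", "iqr", "mad")]
    for s in Window.SIGNALS:
        names += [f"extra:{s}:domfreq", f"extra:{s}:specent"]
    names += [f"extra:{s}:mcr" for s in Window.SIGNALS]
    names += ["corr:xy", "corr:xz", "corr:yz"]
    names += [f"extra:{s}:jerk" for s in ("x", "y", "z")]
    return names


def feature_groups() -> dict[str, list[str]]:
    """Registry names grouped at family-by-signal granularity (for SFS)."""
    groups: dict[str, list[str]] = {}
    for name in feature_registry():
        fam = name.split(":")
        key = f"{fam[0]}:{fam[1]}" if fam[0] != "corr" else "corr"
        groups.setdefault(key, []).append(name)
    return groups


class FeatureExtractor:
    """Fits the data-dependent featurizers and extracts the full registry.

    ``fit`` learns the wavelet-coefficient selector (on R) and the per-signal
    window PCAs from labeled training windows; ``transform`` then maps any
    window to the 130-vector in registry order.
    """

    def __init__(self, n_wavelet_coeffs: int = N_SELECTED_COEFFS):
        self.n_wavelet_coeffs = n_wavelet_coeffs
        self.selector: CoefficientSelector | None = None
        self.signal_pcas: dict[str, PCAProjection] | None = None

    def fit(self, windows: list[Window]) -> "FeatureExtractor":
        by_class: dict[int, list[Window]] = {}
        for w in windows:
            if w.class_id is None:
                raise ValueError("training windows must be labeled")
            by_class.setdefault(w.class_id, []).append(w)
        self.selector = fit_coefficient_selector(
            by_class, n_coeffs=self.n_wavelet_coeffs
        )
        self.signal_pcas = fit_signal_pcas(windows)
        return self

    def transform_window(self, window: Window) -> FeatureVector:
        if self.selector is None or self.signal_pcas is None:
            raise NotFittedError("FeatureExtractor must be fitted first")
        parts = [
            time_domain_features(window),
            freq_domain_features(window),
            pc_features(window, self.signal_pcas),
            FeatureVector(
                modified_wavelet_features(window, self.selector),
                [f"wavelet:r:{i:02d}" for i in range(self.n_wavelet_coeffs)],
            ),
            _subband_energy_features(window),
            _extra_time_features(window),
        ]
        merged = {}
        for p in parts:
            merged.update(p.as_dict())
        names = feature_registry()
        return FeatureVector(np.array([merged[n] for n in names]), names)

    def transform(self, windows: list[Window]) -> np.ndarray:
        """Feature matrix (n_windows x 130) in registry order."""
        return np.vstack([self.transform_window(w).values for w in windows])
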