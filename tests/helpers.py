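"""Shared test utilities and independent oracle implementations.

Oracles here are deliberately written from first principles (direct
filter-bank recursion, exhaustive enumeration, brute-force formulas) and
never call the code paths they check.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from wristhar.signal_io import LabelTrack, Window, segment_windows
from wristhar.synthetic_data import default_profiles, simulate_activity


def make_window(x, y=None, z=None, class_id=None, index=0) -> Window:
    """Build a Window from axis signals, computing the resultant column."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    z = np.zeros_like(x) if z is None else np.asarray(z, dtype=float)
    r = np.sqrt(x**2 + y**2 + z**2)
    return Window(index=index, samples=np.column_stack([x, y, z, r]),
                  class_id=class_id)


def haar_filter_bank_oracle(sig: np.ndarray, levels: int = 3) -> np.ndarray:
    """Textbook orthonormal Haar analysis: pairwise sums/differences over
    the approximation branch, repeated ``levels`` times.  Returns the flat
    [A_L, D_L, ..., D_1] vector."""
    a = np.asarray(sig, dtype=float)
    details = []
    for _ in range(levels):
        s = (a[0::2] + a[1::2]) / np.sqrt(2.0)
        d = (a[0::2] - a[1::2]) / np.sqrt(2.0)
        details.append(d)
        a = s
    return np.concatenate([a] + details[::-1])


def ks_brute_force(values: np.ndarray) -> float:
    """Sup over sample points of |ECDF - fitted normal CDF|, by enumeration."""
    from scipy.stats import norm

    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    mean, sd = v.mean(), v.std(ddof=1)
    if sd == 0:
        return 0.0
    best = 0.0
    for x in v:
        ecdf_at = np.sum(v <= x) / n
        ecdf_before = np.sum(v < x) / n
        g = norm.cdf(x, loc=mean, scale=sd)
        best = max(best, abs(ecdf_at - g), abs(ecdf_before - g))
    return best


def viterbi_brute_force(log_pi, log_a, log_b) -> np.ndarray:
    """Exhaustive max over all state sequences; ties to lexicographically
    smallest path (matching lower-state-id tie-breaking)."""
    t_len, k = log_b.shape
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(k), repeat=t_len):
        score = log_pi[path[0]] + log_b[0, path[0]]
        for t in range(1, t_len):
            score += log_a[path[t - 1], path[t]] + log_b[t, path[t]]
        if score > best_score + 1e-12:
            best_path, best_score = path, score
    return np.array(best_path)


def lab6_profiles():
    """Six activity profiles: 2 stationary, 3 walking-like (one pair of
    exact duplicates: class 14 copies class 10), 1 running-like."""
    profiles = default_profiles()
    profiles[14] = dataclasses.replace(profiles[10], class_id=14)
    ids = [1, 2, 10, 14, 9, 20]
    return profiles, ids


def make_lab_windows(profiles, ids, seed, n_bouts=6, windows_per_bout=20):
    """Simulate multi-bout labeled training data (bouts emulate participants)."""
    windows = []
    k = 0
    for cid in ids:
        for _ in range(n_bouts):
            rec = simulate_activity(
                profiles[cid], windows_per_bout * 10.0, seed=seed * 10_000 + k
            )
            k += 1
            windows += segment_windows(
                rec, LabelTrack([(0.0, rec.duration_s, cid)])
            )
    return windows
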