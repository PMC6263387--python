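"""Feature extraction: Haar decomposition, KS selection, PCA, registry."""

import numpy as np
import pytest
from helpers import haar_filter_bank_oracle, ks_brute_force, make_window
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from wristhar.features import (
    ConstantSignalWarning,
    FeatureExtractor,
    NotFittedError,
    apply_pca,
    coefficients_to_signal,
    feature_groups,
    feature_registry,
    fit_coefficient_selector,
    fit_pca,
    fit_signal_pcas,
    freq_domain_features,
    haar_decompose,
    haar_reconstruct,
    ks_statistic,
    modified_wavelet_features,
    pc_features,
    select_positions,
    time_domain_features,
)


class TestHaar:
    def test_constant_signal_annihilated(self):
        decomp = haar_decompose(np.full(1000, 3.0))
        assert np.abs(decomp.coefficients[125:]).max() == 0.0
        # approximation carries all the mass: c * 2^(3/2)
        np.testing.assert_allclose(decomp.coefficients[:125], 3.0 * 2**1.5)

    def test_parseval_energy(self, rng):
        sig = rng.normal(size=1000)
        decomp = haar_decompose(sig)
        assert np.sum(decomp.coefficients**2) == pytest.approx(
            np.sum(sig**2), abs=1e-9
        )

    def test_perfect_reconstruction(self, rng):
        sig = rng.normal(size=1000)
        np.testing.assert_allclose(
            haar_reconstruct(haar_decompose(sig)), sig, atol=1e-9
        )

    def test_matches_filter_bank_oracle(self, rng):
        """Coefficient-for-coefficient agreement with a textbook recursion."""
        for _ in range(20):
            sig = rng.normal(size=1000)
            np.testing.assert_allclose(
                haar_decompose(sig).coefficients,
                haar_filter_bank_oracle(sig),
                atol=1e-10,
            )

    def test_subband_layout(self, rng):
        decomp = haar_decompose(rng.normal(size=1000))
        assert len(decomp.subband("A3")) == 125
        assert len(decomp.subband("D3")) == 125
        assert len(decomp.subband("D2")) == 250
        assert len(decomp.subband("D1")) == 500

    @pytest.mark.parametrize("n", [0, 999, 1001, 12])
    def test_bad_length_rejected(self, n):
        with pytest.raises(ValueError):
            haar_decompose(np.zeros(n))

    def test_coefficients_to_signal_inverts(self, rng):
        coeffs = rng.normal(size=1000)
        np.testing.assert_allclose(
            haar_decompose(coefficients_to_signal(coeffs)).coefficients,
            coeffs, atol=1e-10,
        )


class TestKsStatistic:
    def test_two_point_hand_value(self):
        # (-1, 1): fitted N(0, sqrt(2)); sup at the jump points
        expected = max(0.5 - norm.cdf(-1 / np.sqrt(2)),
                       norm.cdf(1 / np.sqrt(2)) - 0.5)
        assert ks_statistic(np.array([-1.0, 1.0])) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_samples(self, rng):
        for _ in range(200):
            n = int(rng.integers(8, 51))
            v = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=n)
            assert ks_statistic(v) == pytest.approx(ks_brute_force(v), abs=1e-12)

    def test_large_normal_sample_small_statistic(self):
        v = np.random.default_rng(0).normal(size=10_000)
        assert ks_statistic(v) < 0.02

    def test_bimodal_sample_large_statistic(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(-3, 0.3, 500), rng.normal(3, 0.3, 500)])
        assert ks_statistic(v) > 0.15

    def test_zero_variance_defined_as_zero(self):
        assert ks_statistic(np.full(10, 2.5)) == 0.0

    @given(st.lists(st.floats(-50, 50), min_size=8, max_size=40, unique=True))
    def test_statistic_in_unit_interval(self, values):
        d = ks_statistic(np.array(values))
        assert 0.0 <= d <= 1.0


class TestCoefficientSelector:
    def _coeff_classes(self, rng, n_windows=30, n_pos=200):
        return {
            1: rng.normal(size=(n_windows, n_pos)),
            2: rng.normal(size=(n_windows, n_pos)),
        }

    def test_planted_bimodal_position_ranks_first(self, rng):
        mats = self._coeff_classes(rng)
        planted = 57
        half = 15
        mats[1][:half, planted] = rng.normal(-3, 0.2, half)
        mats[1][half:, planted] = rng.normal(3, 0.2, half)
        sel = select_positions(mats, n_coeffs=5)
        top = sel.positions[np.argmax(sel.ks_scores)]
        assert top == planted

    def test_exactly_20_positions_on_pure_noise(self, rng):
        sel = select_positions(self._coeff_classes(rng, n_pos=1000), n_coeffs=20)
        assert len(sel.positions) == 20
        assert len(np.unique(sel.positions)) == 20
        assert np.all(np.diff(sel.positions) > 0)  # sorted

    def test_scores_in_unit_interval(self, rng):
        sel = select_positions(self._coeff_classes(rng), n_coeffs=20)
        assert np.all((sel.ks_scores >= 0) & (sel.ks_scores <= 1))

    def test_deterministic_refit(self, rng):
        mats = self._coeff_classes(rng)
        a = select_positions(mats, n_coeffs=10)
        b = select_positions(mats, n_coeffs=10)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_needs_two_classes_and_eight_windows(self, rng):
        with pytest.raises(ValueError):
            select_positions({1: rng.normal(size=(30, 50))})
        with pytest.raises(ValueError):
            select_positions({1: rng.normal(size=(5, 50)),
                              2: rng.normal(size=(30, 50))})

    def test_fit_on_windows_selects_from_resultant(self, rng):
        """End-to-end fit on signal windows returns valid flat positions."""
        windows = {}
        for cid in (1, 2):
            ws = []
            for i in range(10):
                x = rng.normal(scale=0.1 * cid, size=1000) + 1.0
                ws.append(make_window(x, class_id=cid, index=i))
            windows[cid] = ws
        sel = fit_coefficient_selector(windows, n_coeffs=20)
        assert len(sel.positions) == 20
        assert sel.positions.max() < 1000
        feats = modified_wavelet_features(windows[1][0], sel)
        assert feats.shape == (20,)


class TestTimeDomainFeatures:
    def test_constant_window(self):
        with pytest.warns(ConstantSignalWarning):
            fv = time_domain_features(make_window(np.full(1000, 2.0)))
        d = fv.as_dict()
        assert d["time:x:mean"] == 2.0
        assert d["time:x:sd"] == 0.0
        assert d["time:x:skew"] == 0.0
        assert d["time:x:kurt"] == 0.0
        assert d["time:x:energy"] == pytest.approx(1000 * 4.0)

    def test_moments_match_direct_formula(self):
        base = np.arange(1, 11, dtype=float)
        x = np.tile(base, 100)
        fv = time_domain_features(make_window(x, np.ones(1000), np.ones(1000)))
        d = fv.as_dict()
        z = (x - x.mean()) / x.std()
        assert d["time:x:mean"] == pytest.approx(x.mean())
        assert d["time:x:sd"] == pytest.approx(x.std(ddof=1))
        assert d["time:x:skew"] == pytest.approx(np.mean(z**3))
        assert d["time:x:kurt"] == pytest.approx(np.mean(z**4))
        assert d["time:x:energy"] == pytest.approx(np.sum(x**2))

    def test_zero_y_percentile_sums_vanish(self, rng):
        x = rng.normal(size=1000)
        fv = time_domain_features(make_window(x, np.zeros(1000), x))
        d = fv.as_dict()
        assert d["time:y:sqsum_p25"] == 0.0
        assert d["time:y:sqsum_p05"] == 0.0

    def test_percentile_sums_direct(self, rng):
        y = rng.normal(size=1000)
        fv = time_domain_features(make_window(np.zeros(1000), y, np.zeros(1000)))
        d = fv.as_dict()
        expected = np.sum(y[y < np.percentile(y, 25)] ** 2)
        assert d["time:y:sqsum_p25"] == pytest.approx(expected)


class TestFreqDomainFeatures:
    def _tone(self, freqs_amps):
        t = np.arange(1000) / 100.0
        sig = np.zeros(1000)
        for f, a in freqs_amps:
            sig += a * np.sin(2 * np.pi * f * t)
        return make_window(sig, np.ones(1000), np.ones(1000))

    def test_pure_tone_max_at_its_bin(self):
        w = self._tone([(2.0, 1.0)])
        d = freq_domain_features(w).as_dict()
        # a unit sine's one-sided DFT magnitude at its bin is 1/2
        assert d["freq:x:maxmag_1_5"] == pytest.approx(0.5, rel=1e-6)

    def test_zero_signal_all_zero(self):
        w = make_window(np.zeros(1000), np.ones(1000), np.zeros(1000))
        d = freq_domain_features(w).as_dict()
        assert d["freq:x:maxmag_1_5"] == 0.0
        assert d["freq:x:summag_0_5"] == 0.0
        assert d["freq:x:npeaks"] == 0.0

    def test_two_tones_two_peaks(self):
        w = self._tone([(2.0, 1.0), (4.0, 1.0)])
        d = freq_domain_features(w).as_dict()
        assert d["freq:x:npeaks"] == 2.0

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            freq_domain_features(self._tone([(2.0, 1.0)]), sample_rate_hz=5.0)


class TestPca:
    def test_rank_one_matrix_single_component(self, rng):
        direction = np.array([1.0, 2.0, -1.0, 0.5])
        mat = np.outer(rng.normal(size=30), direction)
        proj = fit_pca(mat, 2)
        assert proj.explained_variance[0] > 0
        assert proj.explained_variance[1] == pytest.approx(0.0, abs=1e-20)

    def test_training_mean_maps_to_zero(self, rng):
        mat = rng.normal(size=(40, 5))
        proj = fit_pca(mat, 3)
        np.testing.assert_allclose(apply_pca(proj, mat.mean(axis=0)),
                                   np.zeros(3), atol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        mat = np.array([
            [1.0, 2.0, 0.5, -1.0],
            [0.0, 1.5, 1.0, 0.5],
            [2.0, -0.5, 0.0, 1.0],
            [1.5, 1.0, -0.5, 0.0],
            [-1.0, 0.5, 2.0, 1.5],
        ])
        proj = fit_pca(mat, 4)
        cov = np.cov(mat, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        np.testing.assert_allclose(proj.explained_variance, evals[order], atol=1e-10)
        for k in range(4):
            # eigenvectors defined up to sign
            dot = abs(np.dot(proj.components[k], evecs[:, order[k]]))
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_rows_orthonormal(self, rng):
        proj = fit_pca(rng.normal(size=(50, 8)), 5)
        np.testing.assert_allclose(proj.components @ proj.components.T,
                                   np.eye(5), atol=1e-8)

    def test_projected_coordinates_uncorrelated(self, rng):
        mat = rng.normal(size=(200, 6)) @ np.diag([3.0, 2.0, 1.5, 1.0, 0.5, 0.2])
        proj = fit_pca(mat, 4)
        scores = apply_pca(proj, mat)
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * cov[0, 0]

    def test_unfitted_projection_rejected(self):
        with pytest.raises(NotFittedError):
            apply_pca(None, np.zeros(3))

    def test_k_exceeding_dimension_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(10, 3)), 4)


class TestRegistry:
    def test_130_stable_names(self):
        names = feature_registry()
        assert len(names) == 130
        assert len(set(names)) == 130
        assert names == feature_registry()  # stable order

    def test_groups_partition_registry(self):
        groups = feature_groups()
        flat = [n for members in groups.values() for n in members]
        assert sorted(flat) == sorted(feature_registry())

    def test_full_extraction_finite_and_ordered(self, rng):
        windows = []
        for cid in (1, 2):
            for i in range(10):
                t = np.arange(1000) / 100.0
                x = 0.3 * cid * np.sin(2 * np.pi * 1.5 * t + rng.uniform(0, 6)) \
                    + rng.normal(scale=0.05, size=1000)
                windows.append(make_window(x, x + 0.1, 1.0 - x, class_id=cid, index=i))
        extractor = FeatureExtractor().fit(windows)
        mat = extractor.transform(windows)
        assert mat.shape == (20, 130)
        assert np.all(np.isfinite(mat))
        fv = extractor.transform_window(windows[0])
        assert fv.names == feature_registry()

    def test_unfitted_extractor_rejected(self, rng):
        w = make_window(rng.normal(size=1000))
        with pytest.raises(NotFittedError):
            FeatureExtractor().transform_window(w)

    def test_pc_features_scores(self, rng):
        windows = [make_window(rng.normal(size=1000), rng.normal(size=1000),
                               rng.normal(size=1000), index=i) for i in range(12)]
        pcas = fit_signal_pcas(windows, n_components=4)
        fv = pc_features(windows[0], pcas)
        assert len(fv.values) == 16
        assert np.all(np.isfinite(fv.values))
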