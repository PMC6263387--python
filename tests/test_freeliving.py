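"""Unsupervised session modeling, lab-model matching, intensity timelines."""

import numpy as np
import pytest

from wristhar.classifiers import ClassifierBank, GaussianComponent, MixtureModel
from wristhar.freeliving import (
    INTENSITY_CODES,
    MatchResult,
    cluster_session,
    estimate_num_activities,
    intensity_correlation,
    match_models,
    met_timeline,
    observed_intensity_codes,
    session_summary,
)
from wristhar.synthetic_data import (
    activity_dictionary,
    simulate_feature_session,
    synthetic_feature_bank,
)


def single_gauss_bank(means, cov_scale=1.0):
    d = len(next(iter(means.values())))
    return ClassifierBank(models={
        cid: MixtureModel(
            [GaussianComponent(1.0, np.asarray(mu, float), np.eye(d) * cov_scale)],
            class_id=cid,
        )
        for cid, mu in means.items()
    })


class TestEstimateNumActivities:
    def test_single_gaussian_selects_k1(self, rng):
        x = rng.normal(size=(1000, 3))
        sess = estimate_num_activities(x, k_range=range(1, 5), seed=0)
        assert sess.K == 1
        assert sess.scores[1]["bic"] == min(s["bic"] for s in sess.scores.values())

    def test_three_separated_clusters_select_k3(self, rng):
        blobs = [rng.normal(size=(300, 2)) + mu
                 for mu in ([0, 0], [8, 0], [0, 8])]
        x = np.vstack(blobs)
        sess = estimate_num_activities(x, k_range=range(1, 6), seed=0)
        assert sess.K == 3

    def test_k_range_singleton(self, rng):
        x = rng.normal(size=(100, 2))
        sess = estimate_num_activities(x, k_range=[1], seed=0)
        assert sess.K == 1

    def test_loglik_monotone_in_k(self, rng):
        """The unpenalized likelihood cannot decrease with more clusters."""
        blobs = [rng.normal(size=(200, 2)) + mu for mu in ([0, 0], [6, 0])]
        x = np.vstack(blobs)
        sess = estimate_num_activities(x, k_range=range(1, 5), seed=0)
        lls = [sess.scores[k]["loglik"] for k in sorted(sess.scores)]
        assert all(b >= a - 1.0 for a, b in zip(lls, lls[1:]))

    def test_infeasible_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_num_activities(rng.normal(size=(30, 2)),
                                    k_range=range(1, 6), seed=0)
        with pytest.raises(ValueError):
            estimate_num_activities(rng.normal(size=(100, 2)), k_range=[], seed=0)


class TestClusterSession:
    def test_blocked_data_few_transitions(self, rng):
        x = np.vstack([rng.normal(size=(100, 2)),
                       rng.normal(size=(100, 2)) + [6, 0]])
        sess = estimate_num_activities(x, k_range=[2], seed=0)
        sess = cluster_session(x, sess, seed=0)
        transitions = np.sum(np.diff(sess.assignments) != 0)
        assert transitions <= 2

    def test_k1_constant_assignment(self, rng):
        x = rng.normal(size=(100, 2))
        sess = estimate_num_activities(x, k_range=[1], seed=0)
        sess = cluster_session(x, sess, seed=0)
        assert np.all(sess.assignments == 1)

    def test_agrees_with_raw_labels_when_far_apart(self, rng):
        x = np.vstack([rng.normal(size=(80, 2)),
                       rng.normal(size=(80, 2)) + [10, 10]])
        sess = estimate_num_activities(x, k_range=[2], seed=0)
        sess = cluster_session(x, sess, seed=0)
        # emission dominates: path splits exactly at the block boundary
        first, second = sess.assignments[:80], sess.assignments[80:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]


class TestMatchModels:
    def test_exact_means_identity_match(self, rng):
        means = {3: [0.0, 0.0], 7: [5.0, 0.0], 20: [0.0, 5.0]}
        bank = single_gauss_bank(means)
        x = np.vstack([rng.normal(size=(50, 2), scale=0.1) + means[c]
                       for c in (3, 7, 20)])
        sess = estimate_num_activities(x, k_range=[3], seed=0)
        # place cluster means exactly at lab means
        for comp, cid in zip(
            sorted(sess.mixture.components, key=lambda c: tuple(c.mean)),
            sorted(means, key=lambda c: tuple(means[c])),
        ):
            comp.mean = np.asarray(means[cid], float)
        sess.cluster_models = [
            MixtureModel([GaussianComponent(1.0, c.mean, c.cov)])
            for c in sess.mixture.components
        ]
        match = match_models(sess, bank)
        np.testing.assert_allclose(match.distance, 0.0, atol=1e-12)
        assert sorted(match.matched_class.tolist()) == [3, 7, 20]

    def test_equidistant_tie_lower_class_id(self):
        bank = single_gauss_bank({3: [0.0, 0.0], 7: [4.0, 0.0]})
        sess_mix = MixtureModel(
            [GaussianComponent(1.0, np.array([2.0, 0.0]), np.eye(2))]
        )
        sess = _session_from(sess_mix)
        match = match_models(sess, bank)
        assert match.matched_class[0] == 3

    def test_jittered_clusters_match_correctly(self, rng):
        bank = synthetic_feature_bank([1, 7, 20, 23], dim=6,
                                      separation=5.0, seed=1)
        x, y = simulate_feature_session(
            bank, [(1, 100), (7, 100), (20, 100)], seed=2
        )
        sess = estimate_num_activities(x, k_range=[3], seed=0)
        sess = cluster_session(x, sess, seed=0)
        match = match_models(sess, bank)
        # every cluster matched to the right lab class, none to the absent one
        assert sorted(match.matched_class.tolist()) == [1, 7, 20]
        pred = match.matched_class[sess.assignments - 1]
        assert np.mean(pred == y) >= 0.98

    def test_dimension_mismatch_rejected(self):
        bank = single_gauss_bank({1: [0.0, 0.0, 0.0]})
        sess = _session_from(
            MixtureModel([GaussianComponent(1.0, np.zeros(2), np.eye(2))])
        )
        with pytest.raises(ValueError):
            match_models(sess, bank)


def _session_from(mixture):
    from wristhar.freeliving import SessionModel

    return SessionModel(
        K=len(mixture.components), mixture=mixture,
        cluster_models=[
            MixtureModel([GaussianComponent(1.0, c.mean, c.cov)])
            for c in mixture.components
        ],
        n_windows=0,
    )


class TestMetTimeline:
    @pytest.mark.parametrize(
        "cid, met, code",
        [(20, 8.3, 3), (10, 2.8, 1), (23, 4.0, 2)],
    )
    def test_dictionary_met_and_band(self, cid, met, code):
        match = MatchResult(matched_class=[cid], distance=[0.0])
        tl = met_timeline(np.array([1, 1]), match, activity_dictionary())
        assert tl.met[0] == met
        assert tl.codes[0] == code

    def test_missing_dictionary_entry_rejected(self):
        match = MatchResult(matched_class=[99], distance=[0.0])
        with pytest.raises(KeyError):
            met_timeline(np.array([1]), match, activity_dictionary())

    def test_multi_cluster_assignment_routing(self):
        match = MatchResult(matched_class=[10, 20], distance=[0.0, 0.0])
        tl = met_timeline(np.array([1, 2, 2, 1]), match, activity_dictionary())
        np.testing.assert_array_equal(tl.class_ids, [10, 20, 20, 10])
        np.testing.assert_array_equal(tl.codes, [1, 3, 3, 1])


class TestIntensityCorrelation:
    def test_identical_sequences(self):
        assert intensity_correlation([1, 2, 3, 1], [1, 2, 3, 1]) == pytest.approx(1.0)

    def test_reverse_coded_two_level(self):
        est = np.array([1, 3, 1, 3])
        obs = 4 - est  # L<->V swap
        assert intensity_correlation(est, obs) == pytest.approx(-1.0)

    def test_hand_computed_toy(self):
        est = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        obs = np.array([1.0, 2.0, 2.0, 2.0, 2.0, 3.0])
        num = np.sum((est - est.mean()) * (obs - obs.mean()))
        den = np.sqrt(np.sum((est - est.mean()) ** 2)
                      * np.sum((obs - obs.mean()) ** 2))
        assert intensity_correlation(est, obs) == pytest.approx(num / den)

    def test_zero_variance_undefined(self):
        assert np.isnan(intensity_correlation([2, 2, 2], [1, 2, 3]))

    def test_spearman_option(self):
        r = intensity_correlation([1, 2, 3, 3], [1, 2, 2, 3], method="spearman")
        assert 0 < r <= 1

    def test_observed_label_mapping(self):
        codes = observed_intensity_codes(["sitting", "walking", "jogging"])
        np.testing.assert_array_equal(codes, [1, 2, 3])
        with pytest.raises(KeyError):
            observed_intensity_codes(["flying"])


class TestSessionSummary:
    def _timeline(self, class_ids, codes):
        mets = np.asarray(codes, dtype=float)
        from wristhar.freeliving import IntensityTimeline

        return IntensityTimeline(class_ids=np.asarray(class_ids),
                                 met=mets, codes=np.asarray(codes))

    def test_single_class_100_percent(self):
        s = session_summary(self._timeline([5, 5, 5], [1, 1, 1]))
        assert s.class_percent == {5: 100.0}
        assert s.intensity_percent == {"L": 100.0}

    def test_three_to_one_split(self):
        s = session_summary(self._timeline([1, 1, 1, 7], [1, 1, 1, 2]))
        assert s.class_percent[1] == pytest.approx(75.0)
        assert s.class_percent[7] == pytest.approx(25.0)
        assert s.intensity_percent == {"L": 75.0, "M": 25.0}

    def test_percentages_sum_to_100(self, rng):
        ids = rng.integers(1, 5, size=40)
        codes = rng.integers(1, 4, size=40)
        s = session_summary(self._timeline(ids, codes))
        assert sum(s.class_percent.values()) == pytest.approx(100.0, abs=1e-6)
        assert sum(s.intensity_percent.values()) == pytest.approx(100.0, abs=1e-6)

    def test_order_permutation_invariant(self, rng):
        ids = rng.integers(1, 4, size=30)
        codes = rng.integers(1, 4, size=30)
        perm = rng.permutation(30)
        a = session_summary(self._timeline(ids, codes))
        b = session_summary(self._timeline(ids[perm], codes[perm]))
        assert a.class_percent == b.class_percent
        assert a.intensity_percent == b.intensity_percent


class TestEndToEndFeatureSpace:
    def test_identity_recovery_small(self, rng):
        """Block sessions drawn from a separated bank are recovered."""
        bank = synthetic_feature_bank([1, 10, 20], dim=6, separation=5.0, seed=0)
        blocks = [(1, 300), (10, 250), (20, 200), (1, 250)]
        x, y = simulate_feature_session(bank, blocks, seed=5)
        sess = estimate_num_activities(x, k_range=range(1, 6), seed=0)
        sess = cluster_session(x, sess, seed=0)
        match = match_models(sess, bank)
        pred = match.matched_class[sess.assignments - 1]
        assert abs(sess.K - 3) <= 1
        assert np.mean(pred == y) >= 0.9
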