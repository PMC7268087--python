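"""HMM estimation and decoding: closed-form single-state fit, parameter
recovery on synthetic data, Viterbi vs exhaustive path enumeration, partial
correlation maps vs a residualisation oracle, and optimal state alignment
vs factorial enumeration."""

from itertools import permutations, product

import numpy as np
import pytest
from scipy.stats import multivariate_normal, spearmanr

from netdyn import (
    EnvelopeDataset,
    HMMParams,
    StateTimeCourses,
    align_states,
    concatenate_subjects,
    fit_hmm,
    make_ground_truth,
    simulate_envelope_subject,
    simulate_state_path,
    state_spatial_maps,
    viterbi_decode,
)


def hand_params(K, P, means, covs, A, pi):
    return HMMParams(n_states=K, means=np.asarray(means, float),
                     covariances=np.asarray(covs, float),
                     transition_matrix=np.asarray(A, float),
                     initial_distribution=np.asarray(pi, float))


class TestFit:
    def test_single_state_closed_form(self, rng):
        # K=1 maximum likelihood: mean and (ML) covariance of the data
        X = rng.standard_normal((3, 2000)) * [[1.0], [2.0], [0.5]] + [[0.0], [1.0], [-1.0]]
        params = fit_hmm(X, n_states=1, n_restarts=1, max_iter=10, cov_reg=0.0, seed=0)
        assert np.allclose(params.means[0], X.mean(axis=1), atol=1e-6)
        ml_cov = (X - X.mean(axis=1, keepdims=True)) @ (X - X.mean(axis=1, keepdims=True)).T / X.shape[1]
        assert np.allclose(params.covariances[0], ml_cov, atol=1e-6)

    def test_loglik_trace_monotone(self, small_cohort):
        ds = concatenate_subjects(small_cohort.envelopes[:3], small_cohort.subject_ids[:3], 40.0)
        params = fit_hmm(ds, n_states=4, n_restarts=1, max_iter=30, seed=1)
        diffs = np.diff(params.log_likelihood_trace)
        assert np.all(diffs > -1e-6)

    def test_two_state_recovery(self, toy_truth_2state, rng):
        truth = toy_truth_2state
        path = simulate_state_path(truth, 20_000, rng)
        env = simulate_envelope_subject(truth, path, rng)
        params = fit_hmm(env, n_states=2, n_restarts=2, max_iter=60, seed=0)
        ref = hand_params(2, 6, truth.state_means, truth.state_covariances,
                          truth.transition_matrix, truth.initial_distribution)
        perm = align_states(params, ref)
        for j in range(2):
            est = params.transition_matrix[perm[j], perm[j]]
            assert abs(est - truth.transition_matrix[j, j]) < 0.05

    def test_seed_reproducible_bit_for_bit(self, small_cohort):
        ds = concatenate_subjects(small_cohort.envelopes[:2], small_cohort.subject_ids[:2], 40.0)
        p1 = fit_hmm(ds, n_states=3, n_restarts=2, max_iter=15, seed=7)
        p2 = fit_hmm(ds, n_states=3, n_restarts=2, max_iter=15, seed=7)
        assert np.array_equal(p1.means, p2.means)
        assert np.array_equal(p1.transition_matrix, p2.transition_matrix)

    def test_nonfinite_data_rejected(self):
        X = np.ones((2, 100))
        X[0, 5] = np.nan
        with pytest.raises(ValueError):
            fit_hmm(X, n_states=2)

    def test_occupancy_recovery_on_default_style_cohort(self, rng):
        # decoded occupancy of a well-separated 3-state chain approaches the
        # generator's stationary distribution
        truth = make_ground_truth(n_states=3, n_parcels=6, self_persistence=0.88,
                                  separation=3.0, seed=5)
        path = simulate_state_path(truth, 15_000, rng)
        env = simulate_envelope_subject(truth, path, rng)
        params = fit_hmm(env, n_states=3, n_restarts=2, max_iter=50, seed=2)
        stc = viterbi_decode(params, env)
        occ = stc.activations.mean(axis=1)
        ref = hand_params(3, 6, truth.state_means, truth.state_covariances,
                          truth.transition_matrix, truth.initial_distribution)
        perm = align_states(params, ref)
        tv = 0.5 * np.abs(occ[perm] - truth.stationary_distribution()).sum()
        assert tv < 0.05
        true_occ = np.bincount(path, minlength=3) / path.size
        rho = spearmanr(occ[perm], true_occ).statistic
        assert rho > 0.9


class TestViterbi:
    def brute_force_path(self, params, X):
        """Exhaustive argmax over all K^T candidate paths."""
        K, T = params.n_states, X.shape[1]
        best, best_lp = None, -np.inf
        for cand in product(range(K), repeat=T):
            lp = np.log(params.initial_distribution[cand[0]])
            lp += multivariate_normal.logpdf(X[:, 0], params.means[cand[0]],
                                             params.covariances[cand[0]])
            for t in range(1, T):
                lp += np.log(params.transition_matrix[cand[t - 1], cand[t]])
                lp += multivariate_normal.logpdf(X[:, t], params.means[cand[t]],
                                                 params.covariances[cand[t]])
            if lp > best_lp:
                best, best_lp = cand, lp
        return np.array(best)

    def test_matches_exhaustive_enumeration(self, rng):
        params = hand_params(
            2, 2,
            means=[[0.0, 0.0], [1.5, -1.0]],
            covs=[np.eye(2), [[1.0, 0.3], [0.3, 1.0]]],
            A=[[0.8, 0.2], [0.4, 0.6]],
            pi=[0.5, 0.5],
        )
        for _ in range(5):
            X = rng.standard_normal((2, 5))
            stc = viterbi_decode(params, X)
            assert np.array_equal(stc.state_sequence, self.brute_force_path(params, X))

    def test_single_state_all_assigned(self, rng):
        params = hand_params(1, 2, [[0.0, 0.0]], [np.eye(2)], [[1.0]], [1.0])
        stc = viterbi_decode(params, rng.standard_normal((2, 50)))
        assert np.all(stc.state_sequence == 0)

    def test_one_hot_columns(self, rng):
        params = hand_params(3, 2, rng.standard_normal((3, 2)),
                             np.tile(np.eye(2), (3, 1, 1)),
                             np.full((3, 3), 1 / 3), np.full(3, 1 / 3))
        stc = viterbi_decode(params, rng.standard_normal((2, 200)))
        assert np.array_equal(stc.activations.sum(axis=0), np.ones(200))

    def test_decoding_restarts_at_subject_boundaries(self, rng):
        # decoding a 2-subject dataset equals decoding each subject alone
        params = hand_params(2, 2, [[0.0, 0.0], [2.0, 2.0]],
                             np.tile(np.eye(2), (2, 1, 1)),
                             [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        a, b = rng.standard_normal((2, 60)), rng.standard_normal((2, 40)) + 1.0
        ds = concatenate_subjects([a, b], ["s1", "s2"], 40.0)
        joint = viterbi_decode(params, ds)
        solo_a = viterbi_decode(params, a)
        solo_b = viterbi_decode(params, b)
        assert np.array_equal(joint.segment("s1"), solo_a.activations)
        assert np.array_equal(joint.segment("s2"), solo_b.activations)


class TestSpatialMaps:
    def one_hot(self, seq, K):
        act = np.zeros((K, len(seq)), dtype=np.int8)
        act[np.asarray(seq), np.arange(len(seq))] = 1
        return act

    def test_elevated_parcel_positive_entry(self, toy_truth_2state, rng):
        truth = toy_truth_2state
        path = simulate_state_path(truth, 5000, rng)
        env = simulate_envelope_subject(truth, path, rng)
        stc = StateTimeCourses(self.one_hot(path, 2), [("s", 0, 5000)])
        maps = state_spatial_maps(stc, env)
        for k in range(2):
            elevated = truth.state_means[k] > 0
            assert np.all(maps[k, elevated] > 0)

    def test_matches_residualization_oracle_k2(self, rng):
        seq = (rng.random(400) < 0.4).astype(int)
        env = rng.standard_normal((3, 400)) + 0.8 * seq
        stc = StateTimeCourses(self.one_hot(seq, 2), [("s", 0, 400)])
        maps = state_spatial_maps(stc, env)
        # with two mutually exclusive indicators the one-hot redundancy
        # leaves nothing to control for beyond the mean: the partial
        # correlation equals the sign-flipped simple correlation with the
        # complementary indicator, computed here by direct residualisation
        # on the intercept (i.e. demeaning)
        S = self.one_hot(seq, 2).astype(float).T
        for k in range(2):
            comp = S[:, 1 - k]
            for p in range(3):
                y = env[p]
                ry, rc = y - y.mean(), comp - comp.mean()
                oracle = -(ry @ rc) / np.sqrt((ry @ ry) * (rc @ rc))
                assert maps[k, p] == pytest.approx(oracle, abs=1e-8)
        # complementary one-hot indicators: maps are sign-flipped images
        assert np.allclose(maps[0], -maps[1], atol=1e-8)

    def test_never_active_state_flagged_nan(self, rng):
        seq = np.zeros(100, dtype=int)
        seq[40:60] = 1  # state 2 never active
        env = rng.standard_normal((2, 100))
        stc = StateTimeCourses(self.one_hot(seq, 3), [("s", 0, 100)])
        maps = state_spatial_maps(stc, env)
        assert np.all(np.isnan(maps[2]))
        assert np.all(np.isfinite(maps[:2]))

    def test_values_in_unit_interval(self, small_cohort):
        ds = concatenate_subjects(small_cohort.envelopes, small_cohort.subject_ids, 40.0)
        act = np.zeros((4, ds.n_samples), dtype=np.int8)
        offset = 0
        for path in small_cohort.true_paths:
            act[path, np.arange(offset, offset + path.size)] = 1
            offset += path.size
        maps = state_spatial_maps(
            StateTimeCourses(act, ds.subject_boundaries), ds)
        assert np.nanmax(np.abs(maps)) <= 1.0


class TestAlignStates:
    def params_with_means(self, means):
        means = np.asarray(means, float)
        K, P = means.shape
        return hand_params(K, P, means, np.tile(np.eye(P), (K, 1, 1)),
                           np.full((K, K), 1 / K), np.full(K, 1 / K))

    def test_self_alignment_identity(self, rng):
        p = self.params_with_means(rng.standard_normal((4, 3)))
        assert np.array_equal(align_states(p, p), np.arange(4))

    def test_label_swap_recovered(self, rng):
        means = rng.standard_normal((3, 4))
        ref = self.params_with_means(means)
        swapped = self.params_with_means(means[[2, 0, 1]])
        perm = align_states(swapped, ref)
        assert np.array_equal(perm, [1, 2, 0])

    @pytest.mark.parametrize("K", [3, 5])
    def test_matches_factorial_enumeration(self, K, rng):
        ref_means = rng.standard_normal((K, 3))
        est_means = rng.standard_normal((K, 3))
        ref = self.params_with_means(ref_means)
        est = self.params_with_means(est_means)
        perm = align_states(est, ref)
        cost = lambda p: sum(np.linalg.norm(est_means[p[j]] - ref_means[j]) for j in range(K))
        best = min(permutations(range(K)), key=cost)
        assert cost(perm) == pytest.approx(cost(best))

    def test_state_count_mismatch_rejected(self, rng):
        a = self.params_with_means(rng.standard_normal((2, 3)))
        b = self.params_with_means(rng.standard_normal((3, 3)))
        with pytest.raises(ValueError):
            align_states(a, b)


class TestHmmlearnCrossCheck:
    def test_decoding_agrees_with_hmmlearn(self, toy_truth_2state, rng):
        """Independent decoder: hmmlearn's Viterbi on our fitted parameters."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        truth = toy_truth_2state
        path = simulate_state_path(truth, 4000, rng)
        env = simulate_envelope_subject(truth, path, rng)
        params = fit_hmm(env, n_states=2, n_restarts=1, max_iter=40, seed=3)
        model = hmmlearn.GaussianHMM(n_components=2, covariance_type="full", init_params="")
        model.startprob_ = params.initial_distribution
        model.transmat_ = params.transition_matrix
        model.means_ = params.means
        model.covars_ = params.covariances
        theirs = model.predict(env.T)
        ours = viterbi_decode(params, env).state_sequence
        assert np.mean(ours == theirs) > 0.999

    def test_likelihood_competitive_with_hmmlearn(self, toy_truth_2state, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        truth = toy_truth_2state
        path = simulate_state_path(truth, 4000, rng)
        env = simulate_envelope_subject(truth, path, rng)
        ours = fit_hmm(env, n_states=2, n_restarts=2, max_iter=60, seed=1, cov_reg=0.0)
        model = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                     n_iter=60, random_state=1)
        model.fit(env.T)
        theirs = model.score(env.T)
        assert ours.log_likelihood >= theirs - 0.001 * abs(theirs)
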