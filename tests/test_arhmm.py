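"""AR-HMM model, likelihoods, and Gibbs machinery."""

import numpy as np
import pytest

from sniffsearch.arhmm import (ARHMMParams, GibbsConfig, PriorHyper,
                               crossval_model_scan, emission_loglik, gibbs_fit,
                               heldout_loglik, log_joint_likelihood,
                               match_states, n_free_parameters, sample_params,
                               sample_states, usage_filter)
from sniffsearch.synthetic import gen_arhmm_params, simulate_trials

from conftest import enumerate_posterior


def _iid_params(S=1, d=1):
    return ARHMMParams(pi=np.ones((S, S)) / S, init=np.ones(S) / S,
                       A=np.zeros((S, d, d)), b=np.zeros((S, d)),
                       Q=np.tile(np.eye(d), (S, 1, 1)))


class TestLogJointLikelihood:
    def test_iid_gaussian_closed_form(self):
        """With A=0, b=0, Q=I the joint likelihood reduces to iid standard
        normal terms from the second frame on."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 1))
        params = _iid_params()
        got = log_joint_likelihood(params, [x], [np.zeros(20, int)])
        expect = np.sum(-0.5 * (np.log(2 * np.pi) + x[1:] ** 2))
        assert got == pytest.approx(expect, abs=1e-10)

    def test_unvisited_state_does_not_change_value(self, toy_arhmm):
        params, x = toy_arhmm
        z = np.zeros(8, int)
        v2 = log_joint_likelihood(params, [x], [z])
        grown = ARHMMParams(
            pi=np.array([[0.8, 0.2, 0.0], [0.3, 0.7, 0.0], [1 / 3, 1 / 3, 1 / 3]]),
            init=np.array([0.5, 0.5, 0.0]),
            A=np.concatenate([params.A, np.zeros((1, 1, 1))]),
            b=np.concatenate([params.b, np.zeros((1, 1))]),
            Q=np.concatenate([params.Q, np.eye(1)[None]]),
        )
        v3 = log_joint_likelihood(grown, [x], [z])
        assert v3 == pytest.approx(v2, abs=1e-12)

    def test_matches_naive_term_by_term_sum(self, toy_arhmm):
        """Oracle: loop over frames summing transition and Gaussian terms."""
        params, x = toy_arhmm
        rng = np.random.default_rng(2)
        z = rng.integers(0, 2, 8)
        expect = 0.0
        for t in range(1, 8):
            expect += np.log(params.pi[z[t - 1], z[t]])
            mu = params.A[z[t]] @ x[t - 1] + params.b[z[t]]
            q = params.Q[z[t], 0, 0]
            expect += -0.5 * (np.log(2 * np.pi * q) + (x[t] - mu) ** 2 / q).item()
        got = log_joint_likelihood(params, [x], [z])
        assert got == pytest.approx(expect, abs=1e-10)


class TestStateSampler:
    def test_identical_emissions_follow_prior_chain(self):
        """When every state has the same emission law, the sampled chain
        statistics match the transition prior."""
        S = 2
        params = ARHMMParams(pi=np.array([[0.9, 0.1], [0.2, 0.8]]),
                             init=np.array([0.5, 0.5]),
                             A=np.zeros((S, 1, 1)), b=np.zeros((S, 1)),
                             Q=np.tile(np.eye(1), (S, 1, 1)))
        rng = np.random.default_rng(3)
        x = rng.normal(size=(400, 1))
        g = np.random.default_rng(4)
        z = np.concatenate([sample_states(params, x, g) for _ in range(40)])
        frac01 = np.mean(z[1:][z[:-1] == 0] == 1)
        assert frac01 == pytest.approx(0.1, abs=0.02)

    def test_disjoint_dynamics_recover_true_labels(self):
        params = gen_arhmm_params(2, 2, separation=5.0, noise_scale=0.01, seed=0)
        trajs, labels = simulate_trials(params, 3, (100, 100), seed=1)
        g = np.random.default_rng(5)
        for x, z in zip(trajs, labels):
            zs = sample_states(params, x, g)
            assert np.mean(zs == z) > 0.97

    def test_marginals_match_enumeration(self, toy_arhmm):
        """Time-wise marginals of repeated conditional draws agree with the
        exhaustive sum over all 2^8 label sequences."""
        params, x = toy_arhmm
        post, _ = enumerate_posterior(params, x)
        g = np.random.default_rng(6)
        freq = np.zeros((8, 2))
        n = 2000
        for _ in range(n):
            z = sample_states(params, x, g)
            freq[np.arange(8), z] += 1.0
        assert np.abs(freq / n - post).max() < 0.05


class TestParamSampler:
    def test_prior_reproduction_without_data(self):
        """With no assigned frames the conditional posterior is the prior:
        the mean of A draws approaches the identity prior mean."""
        prior = PriorHyper()
        g = np.random.default_rng(7)
        draws = [sample_params([np.zeros((2, 2))], [np.array([0, 0])],
                               prior, g, S=2).A[1] for _ in range(600)]
        assert np.abs(np.mean(draws, axis=0) - np.eye(2)).max() < 0.15

    def test_posterior_concentrates_on_least_squares(self):
        """Abundant data from a known AR process pins the posterior mean of
        A near the generating matrix."""
        params = gen_arhmm_params(1, 2, seed=8)
        trajs, labels = simulate_trials(params, 5, (2000, 2000), seed=9)
        g = np.random.default_rng(10)
        draws = [sample_params(trajs, labels, PriorHyper(), g, S=1).A[0]
                 for _ in range(50)]
        assert np.abs(np.mean(draws, axis=0) - params.A[0]).max() < 0.05

    def test_dirichlet_posterior_mean_with_uniform_mean_split(self):
        """Row posterior is Dirichlet(alpha/S + counts): with counts
        [[98, 2], [3, 97]] and alpha=4 the mean of row 0 is
        ((98+2)/(100+4), (2+2)/(100+4))."""
        # a walk with transition counts (0,0)=98, (0,1)=2, (1,0)=3, (1,1)=97
        z = np.array([1] * 98 + [0] * 50 + [1] + [0] * 50 + [1] + [0])
        counts = np.zeros((2, 2))
        np.add.at(counts, (z[:-1], z[1:]), 1)
        np.testing.assert_array_equal(counts, [[98, 2], [3, 97]])
        x = np.zeros((z.shape[0], 1))
        g = np.random.default_rng(11)
        rows = np.array([sample_params([x], [z], PriorHyper(alpha=4.0), g, S=2).pi[0]
                         for _ in range(4000)])
        assert rows.mean(axis=0)[0] == pytest.approx(100 / 104, abs=0.01)
        assert rows.mean(axis=0)[1] == pytest.approx(4 / 104, abs=0.01)


class TestGibbsFit:
    def test_retains_100_samples_under_defaults(self):
        params = gen_arhmm_params(2, 1, seed=12)
        trajs, _ = simulate_trials(params, 2, (30, 30), seed=13)
        fit = gibbs_fit(trajs, 2, cfg=GibbsConfig(n_iter=300, n_burn=200, seed=0))
        assert len(fit.samples) == 100
        for m in fit.posterior_marginals:
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        for m, z in zip(fit.posterior_marginals, fit.map_sequences):
            np.testing.assert_array_equal(z, np.argmax(m, axis=1))

    def test_same_seed_reproduces_fit(self):
        params = gen_arhmm_params(2, 2, seed=14)
        trajs, _ = simulate_trials(params, 3, (60, 60), seed=15)
        cfg = GibbsConfig(n_iter=20, n_burn=10, seed=42)
        f1 = gibbs_fit(trajs, 2, cfg=cfg)
        f2 = gibbs_fit(trajs, 2, cfg=cfg)
        np.testing.assert_array_equal(f1.map_sequences[0], f2.map_sequences[0])
        np.testing.assert_allclose(f1.expected_params.pi, f2.expected_params.pi)

    def test_label_permutation_symmetry(self):
        """Relabeling the generator's states yields the same fit up to a
        state permutation (Hungarian-aligned MAP sequences agree)."""
        params = gen_arhmm_params(3, 2, seed=16)
        trajs, labels = simulate_trials(params, 8, (80, 80), seed=17)
        fit = gibbs_fit(trajs, 3, cfg=GibbsConfig(60, 40, seed=1))
        perm = match_states(labels, fit.map_sequences, 3)
        acc = np.mean(np.concatenate(
            [perm[np.asarray(e)] == np.asarray(t)
             for e, t in zip(fit.map_sequences, labels)]))
        assert acc > 0.85


class TestHeldoutLoglik:
    def test_matches_enumeration(self, toy_arhmm):
        params, x = toy_arhmm
        _, logz = enumerate_posterior(params, x)
        assert heldout_loglik(params, [x]) == pytest.approx(logz, abs=1e-8)

    def test_single_state_equals_joint_likelihood(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=(25, 1))
        params = _iid_params()
        assert heldout_loglik(params, [x]) == pytest.approx(
            log_joint_likelihood(params, [x], [np.zeros(25, int)]), abs=1e-10)

    def test_point_mass_posterior_equals_joint(self):
        """With effectively deterministic labels (disjoint dynamics) the
        forward marginal approaches the joint at the true labels plus the
        uniform-init constant."""
        params = gen_arhmm_params(2, 2, separation=6.0, noise_scale=0.01, seed=19)
        trajs, labels = simulate_trials(params, 1, (60, 60), seed=20)
        marg = heldout_loglik(params, trajs)
        joint = log_joint_likelihood(params, trajs, labels) + np.log(0.5)
        assert marg >= joint - 1e-6
        assert marg - joint < 1.0  # entropy of the label posterior is tiny


class TestModelAssessment:
    @pytest.mark.parametrize("S,d,expect", [(1, 1, 3), (2, 1, 8), (16, 6, 1248)])
    def test_free_parameter_count(self, S, d, expect):
        assert n_free_parameters(S, d) == expect

    def test_usage_filter_threshold(self):
        z = np.repeat([0, 1, 2, 3], [50, 40, 6, 4])
        kept = usage_filter([z], threshold=0.05)
        assert list(kept) == [0, 1, 2]

    def test_crossval_scan_prefers_true_state_count(self):
        params = gen_arhmm_params(4, 2, seed=21)
        trajs, _ = simulate_trials(params, 16, (80, 80), seed=22)
        table = crossval_model_scan(trajs, [2, 4], cfg=GibbsConfig(50, 30, seed=2),
                                    split_seed=3)
        ll = dict(table)
        assert ll[4] > ll[2]


class TestValidation:
    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            n_free_parameters(0, 1)
        with pytest.raises(ValueError):
            GibbsConfig(n_iter=10, n_burn=10)
        with pytest.raises(ValueError):
            gen_arhmm_params(0, 2)
        with pytest.raises(ValueError):
            gen_arhmm_params(2, 2, separation=-1.0)
        with pytest.raises(ValueError):
            crossval_model_scan([np.zeros((5, 1))] * 3, [])
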