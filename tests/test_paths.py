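import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiddensingle.paths import (
    DegeneratePosteriorError,
    enumerate_monotone_paths,
    forward_backward_marginals,
    monotone_path_array,
    n_monotone_paths,
    path_likelihood,
    path_posterior,
    path_prior,
    strategy_marginals,
    transition_trial,
)
from hiddensingle.puzzle import ResponseCategory
from hiddensingle.strategy import EMISSION_MATRIX, Strategy

from conftest import random_valid_params

TARGET = ResponseCategory.TARGET
DISTRACTOR = ResponseCategory.DISTRACTOR
IN_HOUSE = ResponseCategory.IN_HOUSE


class TestEnumeration:
    def test_t25_gives_3276(self):
        assert n_monotone_paths(25) == 3276
        assert monotone_path_array(25).shape == (3276, 25)

    def test_t1_gives_4(self):
        assert len(list(enumerate_monotone_paths(1))) == 4

    def test_t2_gives_10_by_brute_force(self):
        oracle = [
            p for p in itertools.product(range(4), repeat=2) if p[0] <= p[1]
        ]
        assert len(oracle) == 10
        assert sorted(tuple(int(s) for s in p) for p in enumerate_monotone_paths(2)) == sorted(oracle)

    def test_paths_unique_and_monotone(self):
        paths = list(enumerate_monotone_paths(4))
        assert len(set(paths)) == len(paths) == n_monotone_paths(4)
        for p in paths:
            assert all(a <= b for a, b in zip(p, p[1:]))


class TestPathPrior:
    def test_all_success_path(self, solver):
        path = [Strategy.S] * 25
        assert path_prior(solver, path) == pytest.approx(float(solver.a[3]))

    @pytest.mark.parametrize("T", [1, 2, 3, 4, 5])
    def test_priors_sum_to_one(self, T):
        params = random_valid_params(np.random.default_rng(T))
        total = sum(path_prior(params, p) for p in enumerate_monotone_paths(T))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_decreasing_path_rejected(self, solver):
        with pytest.raises(ValueError):
            path_prior(solver, [Strategy.S, Strategy.UG])


class TestPathLikelihood:
    def test_raw_all_success_all_target(self, solver):
        assert path_likelihood([Strategy.S] * 5, [TARGET] * 5, mode="raw") == 1.0

    def test_effective_all_success_all_target(self, solver):
        lik = path_likelihood([Strategy.S] * 25, [TARGET] * 25, solver, "effective")
        assert lik == pytest.approx(solver.effective_emissions[3, 3] ** 25)

    def test_effective_success_in_house_impossible(self, solver):
        resp = [TARGET] * 24 + [IN_HOUSE]
        assert path_likelihood([Strategy.S] * 25, resp, solver, "effective") == 0.0

    def test_length_mismatch_rejected(self, solver):
        with pytest.raises(ValueError):
            path_likelihood([Strategy.S] * 3, [TARGET] * 4, solver)


class TestPathPosterior:
    def test_weights_sum_to_one(self, solver):
        post = path_posterior(solver, [TARGET, DISTRACTOR, TARGET, TARGET, TARGET])
        assert post.weights.sum() == pytest.approx(1.0)

    def test_brute_force_bayes_at_t3(self):
        params = random_valid_params(np.random.default_rng(17))
        resp = [DISTRACTOR, TARGET, TARGET]
        WR = params.W @ EMISSION_MATRIX
        joint = {}
        for path in itertools.product(range(4), repeat=3):
            if any(a > b for a, b in zip(path, path[1:])):
                continue
            p = params.a[path[0]]
            for a, b in zip(path[:-1], path[1:]):
                p *= params.X[a, b]
            for s, r in zip(path, resp):
                p *= WR[s, int(r)]
            joint[path] = p
        total = sum(joint.values())
        post = path_posterior(params, resp)
        for path_arr, w in zip(post.paths, post.weights):
            key = tuple(int(s) for s in path_arr)
            assert w == pytest.approx(joint[key] / total, abs=1e-12)

    def test_perfect_solver_retains_pd_start_paths(self, solver):
        post = path_posterior(solver, [TARGET] * 25)
        pd_start = [w for p, w in zip(post.paths, post.weights) if p[0] == Strategy.PD]
        assert sum(pd_start) > 0.0

    def test_raw_mode_can_degenerate(self, solver):
        # 25 in-house responses are impossible under raw R for any path with
        # positive prior mass once the chain has left UG with certainty
        params = random_valid_params(np.random.default_rng(2))
        params.a = np.array([0.0, 0.0, 0.0, 1.0])
        with pytest.raises(DegeneratePosteriorError):
            path_posterior(params, [IN_HOUSE] * 5, mode="raw")

    def test_top_paths_ordered(self, solver):
        post = path_posterior(solver, [TARGET] * 10)
        top = post.top_paths(3)
        assert len(top) == 3
        assert top[0][1] >= top[1][1] >= top[2][1]


class TestMarginals:
    def test_rows_normalized_and_tail_properties(self, solver):
        post = path_posterior(solver, [TARGET, TARGET, DISTRACTOR] + [TARGET] * 22)
        marg, cum = strategy_marginals(post)
        np.testing.assert_allclose(marg.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(cum[:, 0], 1.0, atol=1e-8)  # P(s_t >= UG) = 1
        assert np.all(np.diff(cum, axis=1) <= 1e-12)  # non-increasing in s

    @pytest.mark.parametrize("T", [2, 3, 5])
    def test_forward_backward_agrees_with_enumeration(self, T):
        gen = np.random.default_rng(40 + T)
        params = random_valid_params(gen)
        resp = [ResponseCategory(int(c)) for c in gen.integers(0, 4, size=T)]
        post = path_posterior(params, resp)
        fb = forward_backward_marginals(params, resp)
        np.testing.assert_allclose(post.marginals(), fb, atol=1e-10)

    def test_forward_backward_agrees_at_t25(self, solver):
        # responses drawn from the generative model itself, so every
        # sequence has positive probability under the effective emissions
        from hiddensingle.cohort import sample_categories, sample_path

        gen = np.random.default_rng(3)
        resp = sample_categories(sample_path(solver, 25, gen), solver, gen)
        post = path_posterior(solver, resp)
        np.testing.assert_allclose(
            post.marginals(), forward_backward_marginals(solver, resp), atol=1e-10
        )

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_prior_chain_dominance_non_decreasing_in_t(self, seed):
        """P(s_t >= s) under the prior chain never decreases over trials."""
        params = random_valid_params(np.random.default_rng(seed))
        probs = np.empty((10, 4))
        state = params.a.copy()
        for t in range(10):
            probs[t] = state
            state = state @ params.X
        cum = np.cumsum(probs[:, ::-1], axis=1)[:, ::-1]
        assert np.all(np.diff(cum, axis=0) >= -1e-12)


class TestTransitionTrial:
    def test_immediate_crossing(self):
        cum = np.zeros((3, 4))
        cum[:, 3] = [0.6, 0.7, 0.8]
        assert transition_trial(cum, Strategy.S) == 1

    def test_exact_threshold_never_crosses(self):
        cum = np.full((5, 4), 0.5)
        assert transition_trial(cum, Strategy.S) is None

    def test_worked_scan(self):
        cum = np.zeros((5, 4))
        cum[:, 3] = [0.2, 0.4, 0.51, 0.7, 0.9]
        assert transition_trial(cum, Strategy.S) == 3
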