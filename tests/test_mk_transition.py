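"""Mk transition engine: kernels, MCMC, stepping stone, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from conftest import enumeration_loglik, random_four_tip_tree, star_tree, two_tip_tree
from sodalake import mk_transition as mk
from sodalake import synthetic_data as sd
from sodalake.errors import InvalidArgumentError
from sodalake.trees import scale_tree


def _model(K=3, **kw):
    return mk.RateModel(n_states=K, **kw)


class TestRateModel:
    def test_generator_rows_sum_to_zero(self):
        Q = _model(3, rates={(0, 1): 2.0, (1, 0): 0.5}).generator()
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-14)

    def test_tie_symmetric_parameter_sharing(self):
        m = _model(3).tie_symmetric()
        assert m.n_free == 3
        Q = m.generator(np.array([1.0, 2.0, 3.0]))
        assert Q[0, 1] == Q[1, 0] == 1.0
        assert Q[1, 2] == Q[2, 1] == 3.0

    def test_zero_constraint(self):
        m = _model(2).with_zero((0, 1))
        Q = m.generator()
        assert Q[0, 1] == 0.0
        assert m.n_free == 1

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            _model(2, rates={(0, 1): -1.0})

    def test_bad_root_frequencies_rejected(self):
        with pytest.raises(InvalidArgumentError):
            _model(2, root_frequencies=np.array([0.7, 0.7]))


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        P = mk.transition_probabilities(_model(3), 0.0)
        np.testing.assert_allclose(P, np.eye(3), atol=1e-14)

    def test_equal_rates_closed_form(self):
        # symmetric K=3 chain: P_ii(t) = 1/3 + (2/3) exp(-3qt)
        q, t = 0.7, 0.9
        rates = {(i, j): q for i in range(3) for j in range(3) if i != j}
        P = mk.transition_probabilities(_model(3, rates=rates), t)
        diag = 1 / 3 + (2 / 3) * np.exp(-3 * q * t)
        np.testing.assert_allclose(np.diag(P), diag, rtol=1e-10)
        off = (1 - diag) / 2
        np.testing.assert_allclose(P[0, 1], off, rtol=1e-10)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(4)
        rates = {(i, j): rng.uniform(0.1, 3) for i in range(3) for j in range(3) if i != j}
        P = mk.transition_probabilities(_model(3, rates=rates), 2.5)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)

    def test_ergodic_limit_reaches_stationary(self):
        rng = np.random.default_rng(8)
        rates = {(i, j): rng.uniform(0.5, 2) for i in range(3) for j in range(3) if i != j}
        P = mk.transition_probabilities(_model(3, rates=rates), 200.0)
        assert np.max(np.abs(P - P[0])) < 1e-8

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            rates = {(i, j): rng.uniform(0.05, 2)
                     for i in range(3) for j in range(3) if i != j}
            m = _model(3, rates=rates)
            t1, t2 = rng.uniform(0.1, 2, size=2)
            lhs = mk.transition_probabilities(m, t1 + t2)
            rhs = mk.transition_probabilities(m, t1) @ mk.transition_probabilities(m, t2)
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mk.transition_probabilities(_model(2), -0.1)


class TestPruningLikelihood:
    def test_star_tree_frozen_chain(self):
        tree = star_tree(5, branch_length=0.0)
        mat = np.zeros((5, 3))
        mat[:, 1] = 1.0
        tips = mk.TipStateMatrix(tip_labels=tree.tip_labels, matrix=mat)
        ll = mk.pruning_log_likelihood(tree, tips, _model(3))
        assert ll == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_fully_ambiguous_tips_give_unit_likelihood(self):
        tree = sd.generate_tree(30, 1.0, seed=3)
        tips = mk.TipStateMatrix(tip_labels=list(tree.tip_labels),
                                 matrix=np.ones((30, 3)))
        rng = np.random.default_rng(1)
        rates = {(i, j): rng.uniform(0.1, 3) for i in range(3) for j in range(3) if i != j}
        ll = mk.pruning_log_likelihood(tree, tips, _model(3, rates=rates))
        assert abs(ll) < 1e-12

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            tree = random_four_tip_tree(rng)
            rates = {(i, j): rng.uniform(0.05, 2.5)
                     for i in range(3) for j in range(3) if i != j}
            model = _model(3, rates=rates)
            mat = (rng.uniform(size=(4, 3)) < 0.6).astype(float)
            mat[mat.sum(axis=1) == 0, 0] = 1.0
            tips = mk.TipStateMatrix(tip_labels=["A", "B", "C", "D"], matrix=mat)
            ll = mk.pruning_log_likelihood(tree, tips, model)
            ref = enumeration_loglik(tree, mat, model.generator(),
                                     model.root_frequencies)
            assert ll == pytest.approx(ref, abs=1e-10)

    def test_child_order_invariance(self):
        tree = sd.generate_tree(20, 1.0, seed=6)
        tips = sd.simulate_tip_states(tree, sd.MkSimConfig(
            n_tips=20, true_rates={(0, 1): 1.0, (1, 0): 0.5,
                                   (1, 2): 0.7, (2, 1): 0.7}, seed=2))
        model = _model(3)
        ll1 = mk.pruning_log_likelihood(tree, tips, model)
        flipped = tree.copy()
        flipped.children = [list(reversed(c)) for c in flipped.children]
        ll2 = mk.pruning_log_likelihood(flipped, tips, model)
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_impossible_data_under_zero_constraint(self):
        # root forced to state 0 and all outflow from 0 forbidden
        tree = two_tip_tree(0.5, 0.5)
        tips = mk.TipStateMatrix(tip_labels=["A", "B"],
                                 matrix=np.array([[0.0, 1.0], [0.0, 1.0]]))
        model = mk.RateModel(n_states=2, root_frequencies=np.array([1.0, 0.0]),
                             ).with_zero((0, 1))
        ll = mk.pruning_log_likelihood(tree, tips, model)
        assert ll == float("-inf")

    def test_label_mismatch_rejected(self):
        tree = two_tip_tree(0.1, 0.1)
        tips = mk.TipStateMatrix(tip_labels=["A", "X"],
                                 matrix=np.array([[1.0, 0.0], [0.0, 1.0]]))
        with pytest.raises(InvalidArgumentError):
            mk.pruning_log_likelihood(tree, tips, _model(2))


class TestMcmc:
    def _small_problem(self):
        tree = scale_tree(sd.generate_tree(12, 1.0, seed=4), 0.3)
        tips = sd.simulate_tip_states(tree, sd.MkSimConfig(
            n_tips=12, true_rates={(0, 1): 1.0, (1, 0): 1.0},
            root_frequencies=(0.5, 0.5), seed=5))
        return tree, tips

    def test_posterior_matches_grid_quadrature(self):
        # 2 tips in different states, single symmetric rate, uniform prior:
        # the trace distribution must match direct likelihood x prior integration
        tree = two_tip_tree(0.5, 0.5)
        tips = mk.TipStateMatrix(tip_labels=["A", "B"],
                                 matrix=np.array([[1.0, 0.0], [0.0, 1.0]]))
        model = mk.RateModel(n_states=2).tie_symmetric()
        prior = mk.PriorSpec("uniform", params=(0.0, 20.0))
        like = mk.MkLikelihood(tree, tips)
        qs = np.linspace(1e-6, 20, 20_001)
        dens = np.array([np.exp(like(model.generator(np.array([q])),
                                     model.root_frequencies)) for q in qs])
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2
                                               * np.diff(qs))])
        cdf /= cdf[-1]
        trace = mk.mcmc_sample(tree, tips, model, prior,
                               mk.McmcConfig(iterations=100_000, burn_in=5_000,
                                             thinning=1, seed=11))
        samples = np.sort(trace.free[:, 0])
        emp = np.arange(1, len(samples) + 1) / len(samples)
        ks = np.max(np.abs(emp - np.interp(samples, qs, cdf)))
        assert ks < 0.05

    def test_zero_constraint_respected_in_trace(self):
        tree, tips = self._small_problem()
        # K=2 with q(1->0)=0: check the expanded rate table
        model = mk.RateModel(n_states=2).with_zero((1, 0))
        trace = mk.mcmc_sample(tree, tips, model, mk.PriorSpec("exponential"),
                               mk.McmcConfig(iterations=2_000, burn_in=500,
                                             thinning=5, seed=1))
        frame = trace.rates_frame(model)
        assert (frame["q(S1->S0)"] == 0.0).all()
        assert (frame["q(S0->S1)"] > 0.0).all()

    def test_tied_rates_identical_in_trace(self):
        tree, tips = self._small_problem()
        model = mk.RateModel(n_states=2).tie_symmetric()
        trace = mk.mcmc_sample(tree, tips, model, mk.PriorSpec("gamma"),
                               mk.McmcConfig(iterations=2_000, burn_in=500,
                                             thinning=5, seed=2))
        frame = trace.rates_frame(model)
        np.testing.assert_array_equal(frame["q(S0->S1)"], frame["q(S1->S0)"])

    def test_hyper_prior_dimensions_sampled(self):
        tree, tips = self._small_problem()
        model = mk.RateModel(n_states=2).tie_symmetric()
        trace = mk.mcmc_sample(tree, tips, model, mk.PriorSpec("hyper-gamma"),
                               mk.McmcConfig(iterations=3_000, burn_in=500,
                                             thinning=5, seed=3))
        assert trace.hyper is not None
        assert trace.hyper.shape[1] == 2
        assert np.all((trace.hyper > 0) & (trace.hyper < 10))
        assert trace.hyper.std(axis=0).min() > 0  # hyper dims actually move

    def test_determinism(self):
        tree, tips = self._small_problem()
        model = mk.RateModel(n_states=2).tie_symmetric()
        cfg = mk.McmcConfig(iterations=1_500, burn_in=300, thinning=5, seed=9)
        t1 = mk.mcmc_sample(tree, tips, model, mk.PriorSpec("exponential"), cfg)
        t2 = mk.mcmc_sample(tree, tips, model, mk.PriorSpec("exponential"), cfg)
        np.testing.assert_array_equal(t1.free, t2.free)


class TestSteppingStone:
    def test_variance_shrinks_with_more_iterations(self):
        tree = scale_tree(sd.generate_tree(6, 1.0, seed=5), 0.5)
        tips = sd.simulate_tip_states(tree, sd.MkSimConfig(
            n_tips=6, true_rates={(0, 1): 1.0, (1, 0): 1.0},
            root_frequencies=(0.5, 0.5), seed=7))
        model = mk.RateModel(n_states=2).with_equal_rates()

        def estimates(ipd):
            return [mk.stepping_stone_logml(tree, tips, model,
                                            mk.PriorSpec("exponential"),
                                            n_stones=8, iterations_per_stone=ipd,
                                            seed=s).log_marginal_likelihood
                    for s in range(10)]

        assert np.std(estimates(400)) < np.std(estimates(50))

    def test_beta_schedule_shape(self):
        tree = two_tip_tree(0.5, 0.5)
        tips = mk.TipStateMatrix(tip_labels=["A", "B"], matrix=np.ones((2, 2)))
        model = mk.RateModel(n_states=2).tie_symmetric()
        res = mk.stepping_stone_logml(tree, tips, model, n_stones=10,
                                      iterations_per_stone=20, seed=0)
        assert res.beta_schedule[0] == 1.0
        assert res.beta_schedule[-1] == 0.0
        assert np.all(np.diff(res.beta_schedule) < 0)


class TestModelComparison:
    @pytest.mark.parametrize("a,b,expect", [
        (-50.0, -50.0, "no very strong preference"),
        (-40.0, -50.0, "very strong evidence for model a"),
        (-50.0, -41.0, "no very strong preference"),
        (-55.0, -44.0, "very strong evidence for model b"),
    ])
    def test_threshold_and_direction(self, a, b, expect):
        lbf, verdict = mk.compare_models(a, b)
        assert verdict == expect
        assert lbf == pytest.approx(a - b)

    def test_antisymmetry(self):
        lbf_ab, _ = mk.compare_models(-12.0, -30.0)
        lbf_ba, _ = mk.compare_models(-30.0, -12.0)
        assert lbf_ab == -lbf_ba


class TestEncodeTipStates:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["Africa", "Asia", "NorthAmerica"],
                            index=[f"sp{i}" for i in range(len(rows))])

    def test_threshold_coding(self):
        tips = mk.encode_tip_states(self._frame([[1.0, 0.0, 0.0],
                                                 [0.5, 0.4, 0.1]]),
                                    ambiguity_threshold=0.2)
        np.testing.assert_array_equal(tips.matrix,
                                      [[1, 0, 0], [1, 1, 0]])

    def test_argmax_fallback(self):
        tips = mk.encode_tip_states(self._frame([[0.05, 0.05, 0.9]]),
                                    ambiguity_threshold=0.95)
        np.testing.assert_array_equal(tips.matrix, [[0, 0, 1]])

    def test_rows_are_normalized_first(self):
        tips = mk.encode_tip_states(self._frame([[50.0, 40.0, 10.0]]),
                                    ambiguity_threshold=0.2)
        np.testing.assert_array_equal(tips.matrix, [[1, 1, 0]])

    def test_zero_row_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mk.encode_tip_states(self._frame([[0.0, 0.0, 0.0]]))


class TestCongruence:
    def test_identical_chains_pass_at_one(self):
        a = np.random.default_rng(0).normal(size=(500, 2))
        out = mk.run_congruence([a, a.copy(), a.copy()])
        np.testing.assert_allclose(out["psrf"], 1.0)
        assert out.attrs["congruent"]

    def test_disjoint_chains_fail(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(500, 1))
        b = rng.normal(10, 1, size=(500, 1))
        out = mk.run_congruence([a, b])
        assert out["psrf"].iloc[0] > 2.0
        assert not out.attrs["congruent"]

    def test_same_target_chains_converge(self):
        rng = np.random.default_rng(2)
        chains = [rng.normal(size=(4000, 3)) for _ in range(3)]
        out = mk.run_congruence(chains)
        assert (out["psrf"] < 1.1).all()
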