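"""Fixation probabilities, the rare-mutation chain, and its equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repsim import (
    EvolutionConfig,
    GameParams,
    average_cooperation,
    edge_payoffs,
    fixation_probability,
    run_evolution_experiment,
    stationary_distribution,
    transition_matrix,
)
from repsim.evolution import EdgePayoffs
from repsim.norms import allc, alld


def _edge(pi_M, pi_R):
    return EdgePayoffs("M", "R", np.asarray(pi_M, float), np.asarray(pi_R, float))


class TestFixationProbability:
    @pytest.mark.parametrize("N", [2, 10, 50])
    def test_identical_payoffs_give_exactly_one_over_N(self, N):
        pi = np.linspace(0, 3, N - 1)
        assert fixation_probability(_edge(pi, pi), s=1.7) == 1.0 / N

    @pytest.mark.parametrize("N", [2, 10, 50])
    def test_neutral_selection_gives_exactly_one_over_N(self, N):
        rng = np.random.default_rng(N)
        edge = _edge(rng.normal(size=N - 1), rng.normal(size=N - 1))
        assert fixation_probability(edge, s=0.0) == 1.0 / N

    @pytest.mark.parametrize("d,s", [(0.5, 1.0), (-2.0, 0.3), (0.0, 2.0)])
    def test_two_player_closed_form(self, d, s):
        rho = fixation_probability(_edge([d], [0.0]), s)
        assert rho == pytest.approx(1.0 / (1.0 + np.exp(-s * d)), rel=1e-12)

    @given(delta=st.floats(0.01, 2.0), seed=st.integers(0, 100))
    @settings(max_examples=30, derandomize=True)
    def test_monotone_in_payoff_advantage(self, delta, seed):
        rng = np.random.default_rng(seed)
        pi_M = rng.normal(size=9)
        pi_R = rng.normal(size=9)
        lo = fixation_probability(_edge(pi_M, pi_R), s=1.0)
        hi = fixation_probability(_edge(pi_M + delta, pi_R), s=1.0)
        assert hi > lo

    def test_large_payoff_differences_do_not_overflow(self):
        rho = fixation_probability(_edge(np.full(49, -500.0), np.zeros(49)), s=5.0)
        assert 0.0 <= rho < 1e-12
        rho = fixation_probability(_edge(np.full(49, 500.0), np.zeros(49)), s=5.0)
        assert 0.5 < rho <= 1.0

    def test_nan_payoffs_rejected(self):
        with pytest.raises(ValueError):
            fixation_probability(_edge([np.nan], [0.0]), s=1.0)


class TestTransitionMatrix:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        rho = rng.uniform(0, 0.5, size=(3, 3))
        W = transition_matrix(rho)
        assert np.allclose(W.sum(axis=1), 1.0)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert W[i, j] == rho[i, j] / 2

    def test_symmetric_neutral_chain_is_uniform(self):
        rho = np.full((3, 3), 1 / 50)
        v = stationary_distribution(transition_matrix(rho))
        assert np.allclose(v, 1 / 3)

    def test_absorbing_norm_takes_all_mass(self):
        # every other norm's mutants fix into norm 0; norm 0 never leaves
        rho = np.array([[0.0, 0.0, 0.0],
                        [1.0, 0.0, 0.0],
                        [1.0, 0.0, 0.0]])
        v = stationary_distribution(transition_matrix(rho))
        assert v[0] == pytest.approx(1.0, abs=1e-12)


class TestStationaryDistribution:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_power_iteration(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.01, 1.0, size=(3, 3))
        W /= W.sum(axis=1, keepdims=True)
        v = stationary_distribution(W)
        # independent oracle: brute-force power iteration
        u = np.full(3, 1 / 3)
        for _ in range(20_000):
            u = u @ W
        assert np.abs(v - u).max() < 1e-12
        assert np.abs(v @ W - v).max() < 1e-10
        assert v.sum() == pytest.approx(1.0)

    def test_doubly_stochastic_is_uniform(self):
        W = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        assert np.allclose(stationary_distribution(W), 1 / 3)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.eye(3) * 0.5)


def test_average_cooperation_is_dot_product():
    assert average_cooperation(np.array([0.5, 0.25, 0.25]),
                               np.array([0.9, 1.0, 0.0])) == pytest.approx(0.70)
    assert average_cooperation(np.array([0.0, 1.0, 0.0]),
                               np.array([0.3, 1.0, 0.0])) == 1.0


class TestEdgePayoffs:
    def test_allc_exploited_by_alld(self):
        cfg = EvolutionConfig(norm="L1", N=6, T=20_000, replicates=2, seed=4)
        edge = edge_payoffs("ALLC", "ALLD", cfg)
        # a lone cooperator pays without return; larger clusters of
        # cooperators help each other, but defectors always do better
        assert edge.pi_M[0] < 0
        assert np.all(edge.pi_R >= 0)      # defectors only ever receive
        assert np.all(edge.pi_M < edge.pi_R)
        # exact payoffs: ALLC/ALLD behavior is deterministic
        N, b, c = cfg.N, cfg.params.b, cfg.params.c
        k = np.arange(1, N)
        assert np.allclose(edge.pi_M, (b * (k - 1) - c * (N - 1)) / (N - 1))
        assert np.allclose(edge.pi_R, b * k / (N - 1))
        rev = edge.reversed()
        assert np.array_equal(rev.pi_M, edge.pi_R[::-1])

    def test_deterministic_given_seed(self):
        cfg = EvolutionConfig(norm="L1", N=4, T=5_000, replicates=2, seed=8)
        a = edge_payoffs("L1", "ALLD", cfg)
        b = edge_payoffs("L1", "ALLD", cfg)
        assert np.array_equal(a.pi_M, b.pi_M) and np.array_equal(a.pi_R, b.pi_R)


class TestExperiment:
    def test_neutral_selection_gives_uniform_equilibrium(self):
        cfg = EvolutionConfig(norm="L1", N=6, s=0.0, T=5_000, replicates=1, seed=2)
        res = run_evolution_experiment(cfg)
        assert np.allclose(res.stationary, 1 / 3)
        assert np.allclose(res.rho[res.rho > 0], 1 / 6)

    def test_relabeled_allc_competition_is_alld_dominated(self):
        """With two unconditional cooperators and ALLD, defectors take over:
        a degenerate check of the full pipeline on simulated edges."""
        from repsim.evolution import (
            edge_payoffs as ep,
            fixation_probability as fp,
        )
        from repsim.norms import SocialNorm

        allc2 = SocialNorm("ALLC2", allc().assessment.copy(), allc().action.copy())
        cfg = EvolutionConfig(norm="L1", N=8, T=20_000, replicates=2, seed=5)
        names = [allc2, allc(), alld()]
        rho = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i != j:
                    rho[i, j] = fp(ep(names[j], names[i], cfg, edge_id=3 * i + j), cfg.s)
        v = stationary_distribution(transition_matrix(rho))
        assert v[2] > 0.9
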