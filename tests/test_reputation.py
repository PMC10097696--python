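"""Image-matrix dynamics: single rounds, long-run statistics, payoffs."""

import numpy as np
import pytest

from repsim import (
    AssessmentFrame,
    GameParams,
    ImageMatrix,
    Population,
    init_image,
    interaction_round,
    payoff_from_rates,
    run_binary_baseline,
    run_reputation_dynamics,
)


class TestInitImage:
    def test_all_good_consensus(self, frame5):
        pop = Population(["L1"] * 3)
        M = init_image(pop, frame5, 0)
        assert np.all(M.scores == 0)
        assert np.all(M.judgments() == 1)
        assert M.time == 0

    def test_all_bad_init(self, frame5):
        M = init_image(Population(["L1"] * 3), frame5, -1)
        assert np.all(M.judgments() == 0)

    def test_binary_good_init(self):
        M = init_image(Population(["L1", "L2"]), AssessmentFrame.binary(), 1)
        assert np.all(M.judgments() == 1)

    def test_out_of_range_rejected(self, frame5):
        with pytest.raises(ValueError):
            init_image(Population(["L1"] * 3), frame5, 6)


class TestInteractionRound:
    def test_cooperative_round_increments_donor_column(self, frame5, noise_free_params, rng):
        pop = Population(["L1"] * 4)
        M = init_image(pop, frame5, 0)
        M, action = interaction_round(M, 0, 1, pop, noise_free_params, rng)
        assert action == 1  # cooperates: everyone judged good
        assert np.all(M.scores[:, 0] == 1)
        assert np.all(M.scores[:, 1:] == 0)

    def test_saturation_at_maximum(self, frame5, noise_free_params, rng):
        pop = Population(["L1"] * 3)
        M = init_image(pop, frame5, frame5.A)
        M, _ = interaction_round(M, 0, 1, pop, noise_free_params, rng)
        assert np.all(M.scores[:, 0] == frame5.A)

    def test_defector_gets_decremented(self, frame5, noise_free_params, rng):
        pop = Population(["ALLD"] + ["L1"] * 3)
        M = init_image(pop, frame5, 0)
        M, action = interaction_round(M, 0, 1, pop, noise_free_params, rng)
        assert action == 0
        # L1 observers judge the recipient good, so defection is bad
        assert np.all(M.scores[1:, 0] == -1)

    def test_donor_equals_recipient_rejected(self, frame5, noise_free_params, rng):
        pop = Population(["L1"] * 3)
        M = init_image(pop, frame5, 0)
        with pytest.raises(ValueError):
            interaction_round(M, 1, 1, pop, noise_free_params, rng)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_only_donor_column_changes(self, frame5, noisy_params, seed):
        rng = np.random.default_rng(seed)
        pop = Population(["L1", "L2", "ALLC", "ALLD", "L8"])
        M = init_image(pop, frame5, 0)
        scores = rng.integers(frame5.V, frame5.A + 1, size=(5, 5))
        M.scores[:] = scores
        donor, recipient = 2, 4
        before = M.scores.copy()
        interaction_round(M, donor, recipient, pop, noisy_params, rng)
        untouched = np.delete(np.arange(5), donor)
        assert np.array_equal(M.scores[:, untouched], before[:, untouched])
        assert np.all(np.abs(M.scores[:, donor] - before[:, donor]) <= 1)


class TestPayoff:
    def test_full_cooperation_gives_b_minus_c(self):
        x = np.ones((4, 4))
        assert np.allclose(payoff_from_rates(x, 5, 1), 4.0)

    def test_no_cooperation_gives_zero(self):
        assert np.allclose(payoff_from_rates(np.zeros((4, 4)), 5, 1), 0.0)

    def test_two_player_asymmetric(self):
        x = np.array([[0.0, 1.0], [0.0, 0.0]])
        pi = payoff_from_rates(x, 5, 1)
        assert pi[0] == pytest.approx(-1.0)
        assert pi[1] == pytest.approx(5.0)

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            payoff_from_rates(np.zeros((1, 1)), 5, 1)
        with pytest.raises(ValueError):
            payoff_from_rates(np.full((3, 3), 1.5), 5, 1)


class TestGameParams:
    def test_cost_must_be_below_benefit(self):
        with pytest.raises(ValueError):
            GameParams(b=1, c=1)
        with pytest.raises(ValueError):
            GameParams(eps=1.5)


class TestLongRun:
    def test_homogeneous_allc_full_cooperation(self, frame5, noisy_params):
        pop = Population(["ALLC"] * 6)
        stats = run_reputation_dynamics(pop, noisy_params, frame5, T=20_000, seed=11)
        off = ~np.eye(6, dtype=bool)
        assert np.all(stats.coop_rate[off] == 1.0)
        assert np.all(stats.avg_judgment == 1.0)

    def test_homogeneous_alld_no_cooperation(self, frame5, noisy_params):
        pop = Population(["ALLD"] * 6)
        stats = run_reputation_dynamics(pop, noisy_params, frame5, T=20_000, seed=12)
        assert np.all(stats.coop_rate == 0.0)

    def test_l1_noise_free_stays_fully_cooperative(self, frame5, noise_free_params):
        """Perfect information, all-good start: disagreement can never arise."""
        pop = Population(["L1"] * 8)
        stats = run_reputation_dynamics(pop, noise_free_params, frame5, T=20_000, seed=13)
        off = ~np.eye(8, dtype=bool)
        assert np.all(stats.coop_rate[off] == 1.0)
        assert np.all(stats.avg_judgment == 1.0)

    def test_seed_determinism(self, frame5, noisy_params, small_mixed_population):
        a = run_reputation_dynamics(small_mixed_population, noisy_params, frame5,
                                    T=30_000, seed=7)
        b = run_reputation_dynamics(small_mixed_population, noisy_params, frame5,
                                    T=30_000, seed=7)
        assert np.array_equal(a.avg_judgment, b.avg_judgment)
        assert np.array_equal(a.coop_rate, b.coop_rate)
        assert np.array_equal(a.payoff, b.payoff)

    def test_invalid_burn_in_rejected(self, frame5, noisy_params, small_mixed_population):
        with pytest.raises(ValueError):
            run_reputation_dynamics(small_mixed_population, noisy_params, frame5,
                                    T=1000, burn_in=1000, seed=0)

    def test_estimators_agree_in_expectation(self, frame5, noisy_params):
        """The intended-action and empirical cooperation-rate estimators
        measure the same quantity (here judgments are noisy enough that both
        fluctuate)."""
        pop = Population(["L2"] * 4 + ["ALLD"] * 4)
        stats = run_reputation_dynamics(pop, GameParams(eps=0.15, q=0.5),
                                        AssessmentFrame.symmetric(1),
                                        T=400_000, seed=3)
        off = ~np.eye(8, dtype=bool)
        assert np.abs(stats.coop_rate - stats.empirical_coop_rate)[off].max() < 0.05

    def test_mixed_thirds_l1_singles_out_defectors(self, frame5, noisy_params):
        """Equal thirds of L1/ALLC/ALLD, R=5: the leading-eight players keep
        a perfectly correlated good image of each other and judge the
        unconditional defectors bad."""
        pop = Population.from_counts([("L1", 30), ("ALLC", 30), ("ALLD", 30)])
        stats = run_reputation_dynamics(pop, noisy_params, frame5,
                                        T=220_000, burn_in=20_000, seed=1)
        l1, alld = slice(0, 30), slice(60, 90)
        l1_block = stats.avg_judgment[l1, l1][~np.eye(30, dtype=bool)]
        assert l1_block.mean() > 0.95
        assert stats.avg_judgment[l1, alld].mean() < 0.1


class TestBinaryReduction:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_quantitative_engine_reduces_to_binary_baseline(self, noisy_params, seed):
        """With scores in {0,1} and threshold 1, the integer-score engine's
        trajectory on a shared random stream is identical to the direct
        binary-reputation implementation."""
        pop = Population(["L1"] * 4 + ["ALLC"] * 2 + ["ALLD"] * 2)
        quant = run_reputation_dynamics(pop, noisy_params, AssessmentFrame.binary(),
                                        T=20_000, seed=seed, initial_score=1,
                                        snapshot_every=100, keep_final=True)
        binary = run_binary_baseline(pop, noisy_params, T=20_000, seed=seed,
                                     initial_good=True, snapshot_every=100,
                                     keep_final=True)
        assert np.array_equal(quant.snapshots, binary.snapshots)
        assert np.array_equal(quant.final.scores, binary.final.scores)
        assert np.array_equal(quant.coop_rate, binary.coop_rate)
        assert np.allclose(quant.avg_judgment, binary.avg_judgment)
        assert np.allclose(quant.payoff, binary.payoff)


class TestKernelReferenceAgreement:
    def test_noise_free_kernel_steps_match_reference_round(self, noise_free_params):
        """Under perfect information each round map is deterministic given
        the (donor, recipient) pair; every kernel transition must equal the
        pure-Python reference round for some pair."""
        frame = AssessmentFrame.symmetric(2)
        pop = Population(["L1"] * 3 + ["ALLD"] * 2)
        stats = run_reputation_dynamics(pop, noise_free_params, frame, T=40,
                                        seed=9, snapshot_every=1, initial_score=0)
        prev = np.zeros((5, 5), dtype=np.int64)
        rng = np.random.default_rng(0)
        for snap in stats.snapshots:
            candidates = []
            for d in range(5):
                for r in range(5):
                    if d == r:
                        continue
                    M = ImageMatrix(prev.copy(), frame)
                    interaction_round(M, d, r, pop, noise_free_params, rng)
                    candidates.append(M.scores)
            assert any(np.array_equal(snap, c) for c in candidates)
            prev = snap
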