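import numpy as np
import pytest

from reactiven import (
    CountingStrategy,
    GameParameters,
    ReactiveStrategy,
    best_pure_memory_deviation,
    best_self_reactive_deviation,
    counting_partner_volume_exact,
    counting_to_reactive,
    enumerate_deviation_cycles,
    is_defector_oracle,
    is_partner_counting,
    is_partner_oracle,
    is_partner_reactive2,
    is_partner_reactive3,
    named_strategy,
    num_pure_strategies,
    partner_volume,
    minimal_constraints,
    reactive2_partner_volume_exact,
)
from reactiven.equilibrium import _classify_partner_batch, deviation_payoffs


class TestDeviationCycles:
    def test_n1_exactly_three_cycles(self):
        assert enumerate_deviation_cycles(1).cycles == ("C", "D", "CD")

    def test_n2_contains_the_named_sequences(self):
        cs = enumerate_deviation_cycles(2)
        for cycle in ("C", "D", "CD", "CCD", "CDD", "CCDD"):
            assert cycle in cs

    def test_canonical_rotation_membership(self):
        cs = enumerate_deviation_cycles(2)
        assert "DCC" in cs  # rotation of CCD
        assert "DC" in cs  # rotation of CD

    def test_cycles_cover_pure_self_reactive_behaviors(self):
        # 16 pure self-reactive-2 strategies; each settles on one of the
        # enumerated cycles, and every cycle is realized by at least one.
        assert num_pure_strategies("self_reactive", 2) == 16
        assert len(enumerate_deviation_cycles(2)) == 6

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_deviation_cycles(7)


class TestPartnerOracle:
    def test_tft_is_a_partner_with_binding_cooperation(self, donation):
        report = is_partner_oracle(named_strategy("TFT", 1), donation)
        assert report.is_partner
        assert report.worst_payoff == pytest.approx(0.5)
        assert "C" in report.binding_constraints

    def test_allc_is_exploitable_by_defection(self, donation):
        report = is_partner_oracle(named_strategy("ALLC", 1), donation)
        assert report.verdict == "exploitable"
        assert report.worst_deviation == "D"
        assert report.worst_payoff == pytest.approx(1.0)

    def test_exploitable_via_alternation(self, donation):
        report = is_partner_oracle(ReactiveStrategy(2, [1, 0.9, 0.9, 0.4]), donation)
        assert report.verdict == "exploitable"
        assert report.worst_deviation == "CD"
        assert report.worst_payoff == pytest.approx(0.9 - 0.25)

    def test_not_nice_strategies_flagged(self, donation):
        report = is_partner_oracle(ReactiveStrategy(2, [0.9, 0.2, 0.2, 0.1]), donation)
        assert report.verdict == "not_nice"

    def test_works_for_general_prisoners_dilemma(self):
        axelrod = GameParameters(R=3, S=0, T=5, P=1)
        assert is_partner_oracle(named_strategy("TFT", 1), axelrod).is_partner
        assert not is_partner_oracle(named_strategy("ALLC", 1), axelrod).is_partner


class TestClosedForms:
    def test_reactive2_examples(self, donation):
        assert is_partner_reactive2(ReactiveStrategy(2, [1, 0.7, 0.7, 0.4]), donation)[0]
        assert not is_partner_reactive2(named_strategy("ALLC", 2), donation)[0]

    @pytest.mark.parametrize("b", [0.6, 1.0, 3.0, 10.0])
    def test_2tft_is_a_partner_for_all_b_greater_c(self, b):
        g = GameParameters.donation(b, 0.5)
        assert is_partner_reactive2(named_strategy("2TFT", 2), g)[0]

    def test_reactive3_zero_tail_partner(self, donation):
        p = ReactiveStrategy(3, [1, 0, 0, 0, 0, 0, 0, 0])
        assert is_partner_reactive3(p, donation)[0]

    def test_reactive3_boundary_equality_is_partner(self, donation):
        # (p_CCD + p_CDC + p_DCC)/3 exactly at threshold 1 - (1/3)(c/b).
        t = 1.0 - donation.c / (3 * donation.b)
        p = ReactiveStrategy(3, [1, t, t, 0, t, 0, 0, 0])
        ok, slacks = is_partner_reactive3(p, donation)
        assert ok
        assert slacks["CCD"] == pytest.approx(0.0, abs=1e-12)

    def test_counting_n1_reduces_to_reactive1_condition(self, donation):
        assert is_partner_counting(CountingStrategy(1, [1.0, 0.5]), donation)[0]
        assert not is_partner_counting(CountingStrategy(1, [1.0, 0.51]), donation)[0]

    def test_counting_thresholds_n4(self):
        g = GameParameters.donation(2.0, 1.0)
        ok, slacks = is_partner_counting(
            CountingStrategy(4, [1.0, 0.875, 0.75, 0.625, 0.5]), g
        )
        assert ok
        for key in ("r_3", "r_2", "r_1", "r_0"):
            assert slacks[key] == pytest.approx(0.0, abs=1e-12)

    def test_wrong_memory_length_rejected(self, donation):
        with pytest.raises(ValueError):
            is_partner_reactive2(named_strategy("TFT", 1), donation)

    def test_non_donation_game_rejected(self):
        axelrod = GameParameters(R=3, S=0, T=5, P=1)
        with pytest.raises(ValueError):
            is_partner_reactive2(named_strategy("2TFT", 2), axelrod)


class TestClosedFormOracleAgreement:
    """Closed-form conditions and the brute-force cycle oracle must agree off
    the measure-zero boundary."""

    def _agree(self, P, family, n, game):
        cf = _classify_partner_batch(P, family, n, game)
        R = (
            P
            if family == "reactive"
            else np.stack(
                [
                    counting_to_reactive(CountingStrategy(n, row)).probs
                    for row in P
                ]
            )
        )
        _, pay = deviation_payoffs(R, n, game)
        worst = pay.max(axis=1)
        oracle = (R[:, 0] >= 1.0 - 1e-9) & (worst <= game.R + 1e-9)
        off_boundary = np.abs(worst - game.R) > 1e-9
        return int(np.sum((cf != oracle) & off_boundary))

    @pytest.mark.parametrize("family, n", [("reactive", 2), ("reactive", 3), ("counting", 3)])
    def test_nice_slice_agreement(self, family, n, donation):
        rng = np.random.default_rng(500 + n)
        dim = 2**n if family == "reactive" else n + 1
        P = rng.random((2000, dim))
        P[:, 0] = 1.0
        assert self._agree(P, family, n, donation) == 0

    def test_full_cube_agreement(self, donation):
        rng = np.random.default_rng(7)
        P = rng.random((2000, 4))
        assert self._agree(P, "reactive", 2, donation) == 0

    def test_lifting_reactive2_reproduces_its_conditions_at_n3(self, donation):
        """The reactive-2 characterization is the special case of the
        reactive-3 one under memory lifting."""
        rng = np.random.default_rng(21)
        for _ in range(200):
            probs = rng.random(4)
            probs[0] = 1.0
            p2 = ReactiveStrategy(2, probs)
            ok2, _ = is_partner_reactive2(p2, donation)
            ok3, _ = is_partner_reactive3(p2.lift(3), donation)
            assert ok2 == ok3


class TestMinimalConstraints:
    def test_reactive1_single_defection_constraint(self, donation):
        assert minimal_constraints(1, donation) == ["D"]

    def test_reactive2_two_deviations(self, donation):
        assert minimal_constraints(2, donation) == ["D", "CD"]

    def test_reactive3_five_deviations(self, donation):
        assert minimal_constraints(3, donation) == ["D", "CD", "CCD", "CDD", "CCDD"]


class TestDefectors:
    def test_alld_is_a_defector(self, donation):
        assert is_defector_oracle(named_strategy("ALLD", 1), donation)

    def test_allc_is_not(self, donation):
        assert not is_defector_oracle(named_strategy("ALLC", 1), donation)

    def test_gtft_is_not(self, donation):
        assert not is_defector_oracle(named_strategy("GTFT", 1, donation), donation)

    def test_tft_rewards_cooperation_too_much_to_be_a_defector(self, donation):
        # Against TFT a cooperating deviator earns b - c > P, so mutual
        # defection is not a Nash outcome even though TFT retaliates forever.
        assert not is_defector_oracle(named_strategy("TFT", 1), donation)

    def test_grudging_low_cooperator_is_a_defector(self, donation):
        # p_D = 0 and p_C so low that cooperation never pays for the coplayer.
        assert is_defector_oracle(ReactiveStrategy(1, [0.2, 0.0]), donation)


class TestPartnerSetGeometry:
    def test_partner_set_shrinks_with_cost(self):
        rng = np.random.default_rng(3)
        P = rng.random((3000, 4))
        P[:, 0] = 1.0
        games = [GameParameters.donation(1.0, c) for c in (0.2, 0.5, 0.8)]
        hits = [_classify_partner_batch(P, "reactive", 2, g) for g in games]
        assert np.all(hits[1] <= hits[0])
        assert np.all(hits[2] <= hits[1])

    @pytest.mark.parametrize("n", [2, 3])
    def test_counting_volume_matches_product_formula(self, n, donation):
        est, se = partner_volume("counting", n, donation, 30_000, seed=42)
        exact = counting_partner_volume_exact(n, donation)
        assert abs(est - exact) < 3 * se + 1e-12

    def test_reactive2_volume_matches_polyhedron_formula(self, donation):
        est, se = partner_volume("reactive", 2, donation, 30_000, seed=43)
        exact = reactive2_partner_volume_exact(donation)
        assert abs(est - exact) < 3 * se + 1e-12

    def test_no_partners_when_cost_exceeds_benefit(self):
        g = GameParameters.donation(1.0, 1.2, strict=False)
        est, se = partner_volume("counting", 2, g, 5_000, seed=44)
        assert est == 0.0
        assert counting_partner_volume_exact(2, g) == 0.0

    def test_full_cube_mode_measures_exact_niceness(self, donation):
        est, _ = partner_volume("reactive", 2, donation, 5_000, seed=45, nice_only=False)
        assert est == 0.0  # exact niceness has measure zero


class TestReductionTheorem:
    def test_memory1_best_response_is_self_reactive(self, donation):
        """Best deviation among all 16 pure memory-1 strategies equals the
        best pure self-reactive deviation, for random reactive-1 opponents."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            p = ReactiveStrategy(1, rng.uniform(0.02, 0.98, 2))
            best_mem = best_pure_memory_deviation(p, donation)
            best_cycle, _ = best_self_reactive_deviation(p, donation)
            assert best_mem == pytest.approx(best_cycle, abs=1e-8)

    def test_memory2_smoke(self, donation):
        """Single reactive-2 opponent against all 65,536 pure memory-2
        deviators (the full sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(10)
        p = ReactiveStrategy(2, rng.uniform(0.05, 0.95, 4))
        best_mem = best_pure_memory_deviation(p, donation)
        best_cycle, _ = best_self_reactive_deviation(p, donation)
        assert best_mem == pytest.approx(best_cycle, abs=1e-8)
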