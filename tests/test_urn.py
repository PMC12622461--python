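"""Urn model: training, strategy preferences, choice rule, grid simulation."""

import numpy as np
import pytest

from rulegen import (
    GridConfig,
    LearnerState,
    Strategy,
    Urn,
    build_language,
    choose_urn,
    grid_cell_means,
    preferred_urn,
    run_grid,
    sample_preference_strength,
    simulate_test_phase,
    train_urns,
)
from rulegen.experiment import test_schedule as make_test_schedule
from rulegen.urn import simulate_learner


def make_state(counts_a, counts_b, strategy, k=0, group=1, non_baseline="a"):
    urn_a = Urn("a", {f"a{i}": c for i, c in enumerate(counts_a)})
    urn_b = Urn("b", {f"b{i}": c for i, c in enumerate(counts_b)})
    return LearnerState(
        group=group,
        urns=(urn_a, urn_b),
        strategy=Strategy(strategy),
        preference_strength=k,
        non_baseline_label=non_baseline,
    )


SKEW4_72 = [42, 18, 9, 3]
UNIF4_72 = [18] * 4
UNIF8_72 = [9] * 8


class TestTraining:
    @pytest.mark.parametrize(
        "group, expected",
        [(1, {tuple(SKEW4_72), tuple(UNIF4_72)}), (2, {tuple(UNIF4_72), tuple(UNIF8_72)})],
    )
    def test_post_training_urns(self, group, expected):
        lang = build_language(group, seed=0)
        state = train_urns(lang)
        vectors = {tuple(u.count_vector()) for u in state.urns}
        assert vectors == expected
        assert all(u.n == 72 for u in state.urns)


class TestPreferenceStrength:
    def test_poisson_moments(self):
        rng = np.random.default_rng(0)
        draws = np.array([sample_preference_strength(50, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(50, abs=0.5)
        assert draws.var() == pytest.approx(50, rel=0.05)
        assert (draws == 45).any()  # k = 45 is a plausible draw from Poisson(50)

    @pytest.mark.parametrize("lam", [0, -1.5])
    def test_invalid_lambda_rejected(self, lam):
        with pytest.raises(ValueError):
            sample_preference_strength(lam, np.random.default_rng(0))


class TestPreferredUrn:
    def test_probability_matching_always_tie(self):
        assert preferred_urn(make_state(SKEW4_72, UNIF4_72, "probability_matching")) is None

    def test_low_entropy_worked_example(self):
        # post-familiar-trial state: the skewed urn (1.5 bits) beats the
        # updated uniform urn at just under 2 bits
        state = make_state(SKEW4_72, [19, 18, 18, 18], "low_entropy")
        assert preferred_urn(state) == "a"

    def test_tolerance_group1_tie(self):
        # N = 8, e = 4 each side, theta ~ 3.8: neither rule productive
        state = make_state(SKEW4_72, UNIF4_72, "tolerance")
        assert preferred_urn(state) is None

    def test_tolerance_group2_prefers_unif8(self):
        # N = 12, theta ~ 4.8: Unif8 (e = 4) productive, Unif4 (e = 8) not
        state = make_state(UNIF8_72, UNIF4_72, "tolerance", group=2)
        assert preferred_urn(state) == "a"

    def test_type_count_group1_tie(self):
        assert preferred_urn(make_state(SKEW4_72, UNIF4_72, "type_count")) is None

    def test_type_count_group2_prefers_unif8(self):
        assert preferred_urn(make_state(UNIF8_72, UNIF4_72, "type_count", group=2)) == "a"

    @pytest.mark.parametrize(
        "counts_a, counts_b, winner",
        [
            (SKEW4_72, UNIF4_72, "a"),  # skew beats uniform, same type count
            (UNIF4_72, UNIF8_72, "a"),  # fewer uniform types beat more
            (SKEW4_72, UNIF8_72, "a"),
        ],
    )
    def test_rank1_and_low_entropy_orderings_coincide(self, counts_a, counts_b, winner):
        for strategy in ("rank1_skew", "low_entropy"):
            state = make_state(counts_a, counts_b, strategy)
            assert preferred_urn(state) == winner

    def test_low_freq_tail_prefers_longer_tail(self):
        assert preferred_urn(make_state(SKEW4_72, UNIF4_72, "low_freq_tail")) == "a"
        assert preferred_urn(make_state(UNIF8_72, UNIF4_72, "low_freq_tail")) == "a"


class TestChooseUrn:
    def test_worked_example_62_38(self):
        # 72 tokens + k = 45 against 73 tokens: U = (117/190, 73/190)
        state = make_state(SKEW4_72, [19, 18, 18, 18], "low_entropy", k=45)
        probs, chosen = choose_urn(state, "a", np.random.default_rng(0))
        assert probs[0] == pytest.approx(117 / 190)
        assert probs[1] == pytest.approx(73 / 190)
        assert round(probs[0], 2) == 0.62 and round(probs[1], 2) == 0.38
        assert chosen in ("a", "b")

    def test_k_zero_reduces_to_probability_matching(self):
        state = make_state(SKEW4_72, [19, 18, 18, 18], "low_entropy", k=0)
        probs, _ = choose_urn(state, "a", np.random.default_rng(0))
        assert probs == pytest.approx((72 / 145, 73 / 145))

    def test_probabilities_sum_to_one_and_order_invariant(self):
        sa = make_state(SKEW4_72, UNIF4_72, "low_entropy", k=20)
        sb = make_state(UNIF4_72, SKEW4_72, "low_entropy", k=20)
        pa, _ = choose_urn(sa, "a", np.random.default_rng(0))
        pb, _ = choose_urn(sb, "a", np.random.default_rng(0))
        assert sum(pa) == pytest.approx(1.0)
        assert pa == pytest.approx(pb)  # (preferred, dispreferred) order

    def test_large_k_forces_preferred(self):
        state = make_state(SKEW4_72, UNIF4_72, "low_entropy", k=10**9)
        probs, chosen = choose_urn(state, "a", np.random.default_rng(0))
        assert probs[0] > 0.999999
        assert chosen == "a"


class TestTestPhase:
    def _run(self, group, strategy, k, seed):
        rng = np.random.default_rng(seed)
        lang = build_language(group, rng)
        state = train_urns(lang, strategy, k)
        sched = make_test_schedule(lang, rng)
        return simulate_test_phase(state, sched, rng), lang

    def test_token_conservation_and_familiar_accuracy(self):
        result, lang = self._run(1, "low_freq_tail", 45, seed=0)
        assert sum(u.n for u in result.state.urns) == 160  # 144 + 16
        familiar = result.trials[~result.trials["is_novel"]]
        # perfect learners: every familiar trial answered with the trained urn
        for _, row in familiar.iterrows():
            assert lang.stem_to_rank[row["stem"]][0] == row["chosen"]

    def test_each_novel_choice_adds_frequency_1_type(self):
        result, lang = self._run(2, "type_count", 10, seed=1)
        novel = result.trials[result.trials["is_novel"]]
        for _, row in novel.iterrows():
            urn = result.state.urn(row["chosen"])
            assert urn.counts[row["stem"]] == 1

    def test_schedule_language_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        lang_a = build_language(1, np.random.default_rng(0))
        lang_b = build_language(1, np.random.default_rng(99))
        state = train_urns(lang_a)
        sched = make_test_schedule(lang_b, rng)
        with pytest.raises(ValueError):
            simulate_test_phase(state, sched, rng)

    def test_proportions_come_in_eighths(self):
        result, _ = self._run(1, "rank1_skew", 30, seed=2)
        prop = result.non_baseline_proportion
        assert prop in [i / 8 for i in range(9)]


class TestGrid:
    def test_k_zero_equivalent_to_probability_matching(self):
        """With preference strength forced to 0, every strategy collapses to
        probability matching: grand mean indistinguishable from 50%."""
        for si, strategy in enumerate(Strategy):
            props = [
                simulate_learner(
                    group, strategy, None,
                    np.random.default_rng((si, group, i)),
                    preference_strength=0,
                )
                for i in range(150)
                for group in (1, 2)
            ]
            assert np.mean(props) == pytest.approx(0.5, abs=0.04)

    def test_lambda_monotonicity_low_freq_tail(self):
        """|mean - 50%| grows (within MC error) with preference strength."""
        devs = []
        for li, lam in enumerate((1, 10, 50)):
            props = [
                simulate_learner(1, "low_freq_tail", lam,
                                 np.random.default_rng((li, i)))
                for i in range(400)
            ]
            devs.append(abs(np.mean(props) - 0.5))
        assert devs[0] <= devs[1] + 0.03
        assert devs[1] <= devs[2] + 0.03

    def test_run_grid_shape_and_determinism(self):
        config = GridConfig(
            strategies=(Strategy.PROBABILITY_MATCHING, Strategy.TYPE_COUNT),
            lambda_grid=(5.0, 50.0),
            n_learners=40,
            seed=123,
        )
        grid = run_grid(config)
        assert len(grid) == 2 * 2 * 2 * 40
        assert grid["prop_non_baseline"].between(0, 1).all()
        assert np.allclose(grid["prop_non_baseline"] * 8 % 1, 0)
        again = run_grid(config)
        assert grid.equals(again)
        means = grid_cell_means(grid)
        assert len(means) == 8

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GridConfig(lambda_grid=(0.0,))
        with pytest.raises(ValueError):
            GridConfig(n_learners=0)
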