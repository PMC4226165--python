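import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrobeat import agents, behavior, task
from entrobeat.behavior import (StayShiftCounts, UndefinedStatisticError,
                                behavioral_indices, block_entropy,
                                condition_summary, conditional_policy,
                                count_transitions, entropy)
from entrobeat.task import BlockLog, TaskConfig, TrialRecord

ADV, DIS = "advantageous", "disadvantageous"


def _trials(choices, outcomes, block=0):
    return [TrialRecord(block, i, c, o, "left")
            for i, (c, o) in enumerate(zip(choices, outcomes))]


class TestCountTransitions:
    def test_hand_counted_example(self):
        # transitions: stay|gain, shift|loss, stay|loss, shift|gain
        trials = _trials([ADV, ADV, DIS, DIS, ADV],
                         ["gain", "loss", "loss", "gain", "gain"])
        counts = count_transitions(trials)
        # rows: (stay, shift); columns: (gain, loss)
        assert counts.num.tolist() == [[1.0, 1.0], [1.0, 1.0]]
        assert counts.n_transitions == 4

    def test_all_timeouts_give_empty_counts(self):
        trials = _trials(["none"] * 5, ["loss"] * 5)
        assert count_transitions(trials).n_transitions == 0

    def test_timeout_breaks_chain_both_directions(self):
        trials = _trials([ADV, "none", ADV, ADV],
                         ["gain", "loss", "gain", "gain"])
        counts = count_transitions(trials)
        assert counts.n_transitions == 1  # only t2 -> t3

    def test_constant_choice_all_stays(self):
        trials = _trials([ADV] * 40, ["gain"] * 30 + ["loss"] * 10)
        counts = count_transitions(trials)
        assert counts.num[0].sum() == 39  # stays
        assert counts.num[1].sum() == 0   # shifts

    def test_fewer_than_two_trials(self):
        assert count_transitions(_trials([ADV], ["gain"])).n_transitions == 0


class TestConditionalPolicy:
    def test_zero_counts_smooth_to_half(self):
        p = conditional_policy(StayShiftCounts(np.zeros((2, 2)), c=1)).p
        assert np.allclose(p, 0.5)

    def test_smoothed_probability_examples(self):
        counts = StayShiftCounts(np.array([[3.0, 39.0], [1.0, 0.0]]), c=1)
        p = conditional_policy(counts).p
        assert p[0, 0] == pytest.approx(4 / 6)
        assert p[0, 1] == pytest.approx(40 / 41)

    def test_unsmoothed_empty_state_is_undefined(self):
        counts = StayShiftCounts(np.array([[2.0, 0.0], [1.0, 0.0]]), c=0)
        with pytest.raises(UndefinedStatisticError):
            conditional_policy(counts)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = StayShiftCounts(rng.integers(0, 50, (2, 2)).astype(float), c=1)
            p = conditional_policy(counts).p
            assert np.allclose(p.sum(axis=0), 1.0)
            assert ((p > 0) & (p < 1)).all()


class TestEntropy:
    def test_uniform_policy_is_maximal(self):
        p = behavior.ConditionalPolicy(np.full((2, 2), 0.5))
        assert entropy(p) == 1.0

    def test_mixed_policy_value(self):
        p = behavior.ConditionalPolicy(np.array([[2 / 3, 1 / 2], [1 / 3, 1 / 2]]))
        assert entropy(p) == pytest.approx((0.9182958340544896 + 1.0) / 2,
                                           abs=1e-12)

    def test_constant_agent_entropy_small_but_positive(self):
        trials = _trials([ADV] * 40, ["gain"] * 28 + ["loss"] * 12)
        h = block_entropy(trials)
        assert 0 < h < 0.35

    def test_oracle_equivalence_enumerated_terms(self):
        """Entropy equals a direct four-term p*log2(p) enumeration."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            counts = StayShiftCounts(rng.integers(0, 60, (2, 2)).astype(float), c=1)
            pol = conditional_policy(counts)
            brute = -sum(pol.p[a, s] * math.log2(pol.p[a, s])
                         for a in range(2) for s in range(2)) / 2
            assert entropy(pol) == pytest.approx(brute, abs=1e-12)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=2, max_size=60))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_label_swap_invariance(self, seq):
        choices = [ADV if c else DIS for c, _ in seq]
        outcomes = ["gain" if o else "loss" for _, o in seq]
        swapped = [DIS if c == ADV else ADV for c in choices]
        h0 = block_entropy(_trials(choices, outcomes))
        h1 = block_entropy(_trials(swapped, outcomes))
        assert h0 == pytest.approx(h1, abs=1e-14)

    def test_deterministic_policies_agree(self):
        """Constant choice and perfect WSLS give identical H whenever the
        per-state transition totals match."""
        outcomes = ["gain"] * 20 + ["loss"] * 19 + ["gain"]
        const = _trials([ADV] * 40, outcomes)
        wsls_choices = [ADV]
        for o in outcomes[:-1]:
            prev = wsls_choices[-1]
            wsls_choices.append(prev if o == "gain" else
                                (DIS if prev == ADV else ADV))
        wsls = _trials(wsls_choices, outcomes)
        c0, c1 = count_transitions(const), count_transitions(wsls)
        assert (c0.num.sum(axis=0) == c1.num.sum(axis=0)).all()
        assert block_entropy(const) == pytest.approx(block_entropy(wsls))


class TestBehavioralIndices:
    def test_reward_acquisition_counts_timeouts_as_losses(self):
        trials = _trials([ADV, "none", ADV, DIS],
                         ["gain", "loss", "gain", "loss"])
        ix = behavioral_indices(BlockLog(trials, None, 0))
        assert ix.reward_acquisition == pytest.approx(2 / 4)
        assert ix.response_bias == pytest.approx(2 / 3)  # among responded

    def test_all_gain_block(self):
        trials = _trials([ADV, DIS, ADV], ["gain"] * 3)
        assert behavioral_indices(BlockLog(trials, None, 0)
                                  ).reward_acquisition == 1.0

    def test_no_responses_is_undefined(self):
        trials = _trials(["none"] * 4, ["loss"] * 4)
        with pytest.raises(UndefinedStatisticError):
            behavioral_indices(BlockLog(trials, None, 0))

    def test_reward_rate_tracks_bias_under_contingencies(self):
        # bias 0.68 under 70/30 implies gain rate 0.68*0.7 + 0.32*0.3 = 0.572
        cfg = TaskConfig.contingent(blocks=1, trials_per_block=40_000)
        logs = task.run_session(agents.BiasedRandom(0.68), cfg, seed=13)
        ix = behavioral_indices(logs[0])
        se = np.sqrt(0.572 * (1 - 0.572) / 40_000)
        assert abs(ix.reward_acquisition - 0.572) < 3 * se

    def test_random_schedule_reward_is_half(self):
        cfg = TaskConfig.random_reward(blocks=1, trials_per_block=40_000)
        logs = task.run_session(agents.BiasedRandom(0.9), cfg, seed=14)
        ix = behavioral_indices(logs[0])
        assert abs(ix.reward_acquisition - 0.5) < 3 * np.sqrt(0.25 / 40_000)


class TestConditionSummary:
    def test_identical_blocks_equal_block_value(self):
        trials = _trials([ADV, DIS, ADV, DIS], ["gain", "loss", "gain", "loss"])
        blocks = [BlockLog(trials, None, 0)] * 3
        summary = condition_summary(blocks)
        single = behavioral_indices(blocks[0])
        assert summary.entropy_H == pytest.approx(single.entropy_H)
        assert summary.response_bias == pytest.approx(single.response_bias)

    def test_mean_of_blocks(self):
        # engineered blocks with different entropies average arithmetically
        blocks = []
        for choices, outcomes in [
            ([ADV] * 10, ["gain"] * 10),
            ([ADV, DIS] * 5, ["gain", "loss"] * 5),
            ([ADV, ADV, DIS, DIS] * 3, ["gain", "loss"] * 6),
        ]:
            blocks.append(BlockLog(_trials(choices, outcomes), None, 0))
        per_block = [behavioral_indices(b).entropy_H for b in blocks]
        assert condition_summary(blocks).entropy_H == pytest.approx(
            np.mean(per_block))

    def test_pooled_aggregation_option(self):
        cfg = TaskConfig.contingent()
        logs = task.run_session(agents.OutcomeConditioned(0.7, 0.4), cfg, seed=1)
        mean_h = condition_summary(logs).entropy_H
        pooled_h = condition_summary(logs, entropy_aggregation="pooled").entropy_H
        assert 0 < pooled_h <= 1
        assert mean_h != pooled_h  # distinct definitions in general


def test_entropy_independent_of_response_bias():
    """For iid biased choosers, estimated entropy matches the entropy of
    the implied outcome-conditioned stay policy — bias does not leak in."""
    cfg = TaskConfig.contingent(blocks=1, trials_per_block=30_000)
    for p_adv in (0.3, 0.5, 0.7):
        logs = task.run_session(agents.BiasedRandom(p_adv), cfg, seed=17)
        h = block_entropy(logs[0].trials)
        stay = p_adv ** 2 + (1 - p_adv) ** 2
        expected = agents.expected_entropy(
            agents.OutcomeConditioned(stay, stay))
        assert abs(h - expected) < 0.02
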