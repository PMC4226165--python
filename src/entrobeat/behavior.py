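"""Behavioral indices: response bias, reward acquisition, and the
smoothed conditional-entropy measure of exploration.

The exploration statistic is the normalized conditional Shannon entropy of
Stay/Shift actions given the previous trial's outcome.  Within each block,
every consecutive pair of responded trials contributes one transition: the
*state* S is the previous trial's outcome (gain or loss) and the *action*
a is Stay (same stimulus chosen again, by stimulus identity, not screen
side) or Shift.  Counts are smoothed with an additive constant c
(default 1)::

    P(a|S) = (Num(a|S) + c) / sum_k (Num(k|S) + c)

and the entropy, normalized to [0, 1] by the number of states N = 2, is::

    H = -(1/N) * sum_S sum_a P(a|S) * log2 P(a|S)

Fixed strategies (constant choice, deterministic Win-Stay/Lose-Shift)
score near 0 (not exactly 0, because of c); outcome-independent random
choice scores near 1.  H is independent of task performance by
construction: it sees only the stay/shift structure, never which stimulus
was advantageous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .task import ADV, GAIN, LOSS, NONE, BlockLog, TrialRecord

ACTIONS = ("stay", "shift")
STATES = ("gain", "loss")


class UndefinedStatisticError(ValueError):
    """Raised when an index is undefined for the given data (e.g. zero
    responded trials, or c = 0 with an empty state column)."""


@dataclass
class StayShiftCounts:
    """2x2 transition-count table; rows = action (stay, shift), columns =
    previous-outcome state (gain, loss)."""

    num: np.ndarray  # shape (2, 2), integer counts
    c: float = 1.0
    n_transitions: int = 0

    def __post_init__(self):
        self.num = np.asarray(self.num, dtype=float)
        if self.num.shape != (2, 2):
            raise ValueError("count table must be 2x2 (action x state)")
        if (self.num < 0).any():
            raise ValueError("counts must be non-negative")
        if self.c < 0:
            raise ValueError("smoothing constant c must be >= 0")
        self.n_transitions = int(self.num.sum())


@dataclass
class ConditionalPolicy:
    """Smoothed conditional probabilities P(a|S); columns sum to 1."""

    p: np.ndarray  # shape (2, 2), action x state

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (2, 2):
            raise ValueError("policy table must be 2x2 (action x state)")
        if not np.allclose(self.p.sum(axis=0), 1.0):
            raise ValueError("each state column must sum to 1")


@dataclass
class BehavioralIndices:
    response_bias: float
    reward_acquisition: float
    entropy_H: float
    n_states_N: int = 2


def count_transitions(trials: Sequence[TrialRecord], c: float = 1.0) -> StayShiftCounts:
    """Tabulate Stay/Shift counts by previous-trial outcome within a block.

    A transition (t-1, t) contributes iff both trials carry a real choice;
    timeout (choice = none) trials break the chain in both directions.
    The first trial of a block contributes no transition.
    """
    num = np.zeros((2, 2))
    for prev, cur in zip(trials, trials[1:]):
        if prev.choice == NONE or cur.choice == NONE:
            continue
        a = 0 if cur.choice == prev.choice else 1  # stay / shift
        s = 0 if prev.outcome == GAIN else 1
        num[a, s] += 1
    return StayShiftCounts(num=num, c=c)


def conditional_policy(counts: StayShiftCounts) -> ConditionalPolicy:
    """Additively smoothed conditional stay/shift probabilities."""
    c = counts.c
    col_totals = counts.num.sum(axis=0) + 2 * c
    if c == 0 and (col_totals == 0).any():
        state = STATES[int(np.argmin(col_totals))]
        raise UndefinedStatisticError(
            f"P(a|S) undefined: no transitions in state {state!r} and c=0")
    return ConditionalPolicy(p=(counts.num + c) / col_totals)


def entropy(policy: ConditionalPolicy, n_states: int = 2) -> float:
    """Normalized conditional entropy of a stay/shift policy, in bits.

    Zero-probability entries contribute zero (the p*log2(p) -> 0 limit);
    with c > 0 smoothing all entries are interior and H is in (0, 1].
    """
    p = policy.p
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return float(-terms.sum() / n_states)


def block_entropy(trials: Sequence[TrialRecord], c: float = 1.0) -> float:
    """Convenience: count -> smooth -> entropy for one block."""
    return entropy(conditional_policy(count_transitions(trials, c=c)))


def behavioral_indices(block: BlockLog, c: float = 1.0) -> BehavioralIndices:
    """Response bias, reward acquisition, and entropy for one block.

    Response bias is the advantageous-choice rate among responded trials;
    reward acquisition is the gain rate over *all* trials (timeouts count
    as losses, matching the task's payoff rule).
    """
    trials = block.trials
    if not trials:
        raise UndefinedStatisticError("empty block")
    responded = [t for t in trials if t.choice != NONE]
    if not responded:
        raise UndefinedStatisticError("response bias undefined: no responded trials")
    bias = sum(t.choice == ADV for t in responded) / len(responded)
    reward = sum(t.outcome == GAIN for t in trials) / len(trials)
    return BehavioralIndices(
        response_bias=bias,
        reward_acquisition=reward,
        entropy_H=block_entropy(trials, c=c),
    )


def condition_summary(blocks: Sequence[BlockLog], c: float = 1.0,
                      entropy_aggregation: str = "mean_of_blocks") -> BehavioralIndices:
    """Condition-level indices: per-block values averaged (unweighted).

    ``entropy_aggregation='pooled'`` instead pools the transition counts of
    all blocks before smoothing — provided because a single per-condition
    entropy can be defined either way; the mean of block entropies is the
    default.
    """
    if not blocks:
        raise UndefinedStatisticError("need at least one block")
    per_block = [behavioral_indices(b, c=c) for b in blocks]
    if entropy_aggregation == "mean_of_blocks":
        h = float(np.mean([ix.entropy_H for ix in per_block]))
    elif entropy_aggregation == "pooled":
        pooled = np.zeros((2, 2))
        for b in blocks:
            pooled += count_transitions(b.trials, c=c).num
        h = entropy(conditional_policy(StayShiftCounts(num=pooled, c=c)))
    else:
        raise ValueError(f"unknown entropy_aggregation: {entropy_aggregation!r}")
    return BehavioralIndices(
        response_bias=float(np.mean([ix.response_bias for ix in per_block])),
        reward_acquisition=float(np.mean([ix.reward_acquisition for ix in per_block])),
        entropy_H=h,
    )


def entropy_from_stay_counts(stay_counts: np.ndarray, totals: np.ndarray,
                             c: float = 1.0) -> np.ndarray:
    """Vectorized entropy from per-state stay counts.

    ``stay_counts`` and ``totals`` have shape ``batch + (2,)`` (last axis =
    state gain, loss).  Identical arithmetic to
    ``entropy(conditional_policy(count_transitions(...)))`` — the
    2x2 table is (stay, shift) = (stay_counts, totals - stay_counts).
    """
    stay_counts = np.asarray(stay_counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    p_stay = (stay_counts + c) / (totals + 2 * c)
    h = binary_entropy_array(p_stay)
    return h.mean(axis=-1)


def binary_entropy_array(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return -(np.where(p > 0, p * np.log2(p), 0.0)
                 + np.where(p < 1, (1 - p) * np.log2(1 - p), 0.0))


def stay_counts_from_arrays(choices: np.ndarray, outcomes: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-state stay counts from boolean choice/outcome arrays.

    ``choices``/``outcomes`` have shape ``batch + (n_trials,)`` (one block
    per row of the batch; transitions never cross the last axis boundary).
    Returns ``(stay_counts, totals)`` of shape ``batch + (2,)``.
    """
    stay = choices[..., 1:] == choices[..., :-1]
    state_gain = outcomes[..., :-1]
    stay_g = (stay & state_gain).sum(axis=-1)
    stay_l = (stay & ~state_gain).sum(axis=-1)
    tot_g = state_gain.sum(axis=-1)
    tot_l = (~state_gain).sum(axis=-1)
    return (np.stack([stay_g, stay_l], axis=-1),
            np.stack([tot_g, tot_l], axis=-1))


def score_trial_log(log: pd.DataFrame, c: float = 1.0) -> pd.DataFrame:
    """Per-(subject, condition, block) behavioral indices from a trial log.

    Expects the trial-log schema (columns subject_id, condition, block,
    trial, choice in {adv, disadv, none}, outcome in {gain, loss},
    side_adv in {L, R}); see :mod:`entrobeat.io`.
    """
    choice_map = {"adv": ADV, "disadv": "disadvantageous", "none": NONE}
    rows = []
    for (subj, cond, block), grp in log.groupby(
            ["subject_id", "condition", "block"], sort=True):
        grp = grp.sort_values("trial")
        trials = [
            TrialRecord(int(block), int(r.trial), choice_map[r.choice], r.outcome,
                        "left" if r.side_adv == "L" else "right")
            for r in grp.itertuples()
        ]
        ix = behavioral_indices(BlockLog(trials, config=None, seed=-1), c=c)
        rows.append({"subject_id": subj, "condition": cond, "block": int(block),
                     "response_bias": ix.response_bias,
                     "reward_acquisition": ix.reward_acquisition,
                     "entropy": ix.entropy_H})
    return pd.DataFrame(rows)
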