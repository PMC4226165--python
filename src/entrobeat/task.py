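"""Two-option stochastic decision-making task.

Simulates the choice task used in the study design this package models:
two abstract stimuli, one "advantageous" and one "disadvantageous",
delivering monetary gains/losses (±100 JPY) with fixed per-stimulus
probabilities (70/30 in the contingent-reward condition, 50/50 in the
random-reward condition).  A response timeout counts as a loss.  The
left/right screen position of the advantageous stimulus is randomized
per trial and is irrelevant to all downstream Stay/Shift statistics,
which operate on stimulus identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Literal, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .agents import Agent

Condition = Literal["contingent", "random", "control"]
Choice = Literal["advantageous", "disadvantageous", "none"]
Outcome = Literal["gain", "loss"]

ADV = "advantageous"
DIS = "disadvantageous"
NONE = "none"
GAIN = "gain"
LOSS = "loss"


class ConfigurationError(ValueError):
    """Raised for invalid task or agent configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Reward contingencies and trial structure for one condition.

    ``p_gain_advantageous`` / ``p_gain_disadvantageous`` are the gain
    probabilities attached to the two stimuli.  ``schedule_mode`` selects
    i.i.d. Bernoulli draws at choice time (default) or a pre-permuted
    schedule with exact gain counts per stimulus.
    """

    condition: Condition = "contingent"
    p_gain_advantageous: float = 0.70
    p_gain_disadvantageous: float = 0.30
    trials_per_block: int = 40
    blocks: int = 3
    stake: int = 100
    timeout_is_loss: bool = True
    schedule_mode: Literal["bernoulli", "exact_count"] = "bernoulli"

    def __post_init__(self) -> None:
        if self.condition not in ("contingent", "random", "control"):
            raise ConfigurationError(f"unknown condition: {self.condition!r}")
        for name in ("p_gain_advantageous", "p_gain_disadvantageous"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.trials_per_block < 2:
            raise ConfigurationError(
                "trials_per_block must be >= 2 (entropy needs a transition)"
            )
        if self.blocks < 1:
            raise ConfigurationError("blocks must be >= 1")
        if self.schedule_mode not in ("bernoulli", "exact_count"):
            raise ConfigurationError(f"unknown schedule_mode: {self.schedule_mode!r}")

    @classmethod
    def contingent(cls, **kw) -> "TaskConfig":
        """The 70/30 low-uncertainty preset."""
        return cls(condition="contingent", p_gain_advantageous=0.70,
                   p_gain_disadvantageous=0.30, **kw)

    @classmethod
    def random_reward(cls, **kw) -> "TaskConfig":
        """The 50/50 high-uncertainty preset (contingency unlearnable)."""
        return cls(condition="random", p_gain_advantageous=0.50,
                   p_gain_disadvantageous=0.50, **kw)

    @classmethod
    def control(cls, p_gain_advantageous: float = 0.70,
                p_gain_disadvantageous: float = 0.30, **kw) -> "TaskConfig":
        """Computer-choice control condition with the given mapping."""
        return cls(condition="control",
                   p_gain_advantageous=p_gain_advantageous,
                   p_gain_disadvantageous=p_gain_disadvantageous, **kw)


@dataclass(frozen=True)
class TrialRecord:
    block_index: int
    trial_index: int
    choice: Choice
    outcome: Outcome
    side_of_advantageous: Literal["left", "right"]

    def __post_init__(self) -> None:
        if self.choice == NONE and self.outcome != LOSS:
            raise ValueError("timeout trials must have outcome 'loss'")


@dataclass
class BlockLog:
    trials: list[TrialRecord]
    config: TaskConfig
    seed: int

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.trials)


def _gain_probability(config: TaskConfig, choice: str) -> float:
    return (config.p_gain_advantageous if choice == ADV
            else config.p_gain_disadvantageous)


def _exact_count_schedule(config: TaskConfig, rng: np.random.Generator) -> dict:
    """Per-stimulus outcome schedules with exact gain counts for one block."""
    n = config.trials_per_block
    schedules = {}
    for stim in (ADV, DIS):
        n_gain = round(_gain_probability(config, stim) * n)
        outcomes = np.array([GAIN] * n_gain + [LOSS] * (n - n_gain), dtype=object)
        rng.shuffle(outcomes)
        schedules[stim] = list(outcomes)
    return schedules


def _draw_outcome(config: TaskConfig, choice: str, rng: np.random.Generator,
                  schedule: dict | None, counters: dict) -> str:
    if choice == NONE:
        return LOSS
    if config.schedule_mode == "exact_count":
        k = counters[choice]
        counters[choice] += 1
        sched = schedule[choice]
        # agent chose this stimulus more often than the schedule length:
        # cannot happen within a block (schedule length == trials_per_block)
        return sched[k]
    return GAIN if rng.random() < _gain_probability(config, choice) else LOSS


def run_session(agent: "Agent", config: TaskConfig, seed: int) -> list[BlockLog]:
    """Run ``config.blocks`` blocks of the task with a behavioral agent.

    Identical (agent spec, config, seed) triples yield identical logs.
    The agent's ``act`` receives the previous trial's choice/outcome
    (``None`` on a block's first trial — transitions do not carry across
    the long inter-block gaps) and its learning state, if any, persists
    across blocks within the session.
    """
    if config.condition not in ("contingent", "random"):
        raise ConfigurationError(
            f"run_session expects contingent or random condition, got "
            f"{config.condition!r}; use control_session for control blocks"
        )
    rng = np.random.default_rng(seed)
    agent = agent.fresh()
    logs: list[BlockLog] = []
    for b in range(config.blocks):
        schedule = (_exact_count_schedule(config, rng)
                    if config.schedule_mode == "exact_count" else None)
        counters = {ADV: 0, DIS: 0}
        trials: list[TrialRecord] = []
        prev_choice: str | None = None
        prev_outcome: str | None = None
        for t in range(config.trials_per_block):
            side = "left" if rng.random() < 0.5 else "right"
            choice = agent.act(prev_choice, prev_outcome, rng)
            outcome = _draw_outcome(config, choice, rng, schedule, counters)
            if choice != NONE:
                agent.update(choice, outcome)
            trials.append(TrialRecord(b, t, choice, outcome, side))
            prev_choice = None if choice == NONE else choice
            prev_outcome = None if choice == NONE else outcome
        logs.append(BlockLog(trials, config, seed))
    return logs


def control_session(config: TaskConfig, seed: int) -> list[BlockLog]:
    """Computer-choice control blocks: uniform random choice, no timeouts."""
    if config.condition != "control":
        raise ConfigurationError("control_session requires condition='control'")
    rng = np.random.default_rng(seed)
    logs: list[BlockLog] = []
    for b in range(config.blocks):
        schedule = (_exact_count_schedule(config, rng)
                    if config.schedule_mode == "exact_count" else None)
        counters = {ADV: 0, DIS: 0}
        trials = []
        for t in range(config.trials_per_block):
            side = "left" if rng.random() < 0.5 else "right"
            choice = ADV if rng.random() < 0.5 else DIS
            outcome = _draw_outcome(config, choice, rng, schedule, counters)
            trials.append(TrialRecord(b, t, choice, outcome, side))
        logs.append(BlockLog(trials, config, seed))
    return logs


def relabel_stimuli(logs: Sequence[BlockLog]) -> list[BlockLog]:
    """Swap which abstract stimulus is called advantageous.

    Stay/Shift statistics are label-invariant; this helper exists so tests
    and users can verify that directly.
    """
    swap = {ADV: DIS, DIS: ADV, NONE: NONE}
    out = []
    for log in logs:
        trials = [replace(t, choice=swap[t.choice],
                          side_of_advantageous=("left" if t.side_of_advantageous == "right"
                                                else "right"))
                  for t in log.trials]
        out.append(BlockLog(trials, log.config, log.seed))
    return out


def simulate_outcome_conditioned(
    p_stay_gain: np.ndarray,
    p_stay_loss: np.ndarray,
    n_blocks: int,
    n_trials: int,
    p_gain_adv: float = 0.70,
    p_gain_dis: float = 0.30,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized simulation of outcome-conditioned stay/shift agents.

    ``p_stay_gain``/``p_stay_loss`` broadcast to an arbitrary batch shape;
    returns boolean arrays ``(choices_adv, outcomes_gain)`` of shape
    ``batch + (n_blocks, n_trials)``.  Semantics match ``run_session`` with
    an :class:`~entrobeat.agents.OutcomeConditioned` agent under a
    Bernoulli schedule: uniform first choice per block, stay probability
    set by the previous trial's outcome, outcome drawn with the chosen
    stimulus's gain probability.  Used by the synthetic-cohort generator
    and by convergence tests where per-record Python objects would be
    needlessly slow.
    """
    if rng is None:
        rng = np.random.default_rng()
    psg = np.asarray(p_stay_gain, dtype=float)
    psl = np.asarray(p_stay_loss, dtype=float)
    batch = np.broadcast_shapes(psg.shape, psl.shape)
    psg = np.broadcast_to(psg, batch)[..., None]
    psl = np.broadcast_to(psl, batch)[..., None]
    shape = batch + (n_blocks,)
    choices = np.empty(shape + (n_trials,), dtype=bool)
    outcomes = np.empty(shape + (n_trials,), dtype=bool)
    choice = rng.random(shape) < 0.5  # True = advantageous
    for t in range(n_trials):
        if t > 0:
            p_stay = np.where(outcomes[..., t - 1], psg, psl)
            stay = rng.random(shape) < p_stay
            choice = np.where(stay, choice, ~choice)
        p_gain = np.where(choice, p_gain_adv, p_gain_dis)
        outcomes[..., t] = rng.random(shape) < p_gain
        choices[..., t] = choice
    return choices, outcomes
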