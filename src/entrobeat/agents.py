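"""Generative choice policies spanning the exploration-entropy range.

These agents exist to exercise the conditional-entropy statistic and to
build synthetic cohorts; none of them is fitted to empirical data.  The
catalogue covers the fixed strategies the entropy measure is designed to
score near zero (constant choice, deterministic Win-Stay/Lose-Shift), the
outcome-conditioned family whose stay probabilities parameterize entropy
directly, purely random biased choice, and a Rescorla–Wagner/softmax
learner whose sharpness ("inverse temperature") controls exploration the
way trial-by-trial reinforcement-learning accounts do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .task import ADV, DIS, NONE, GAIN, ConfigurationError


def binary_entropy(p: float | np.ndarray) -> float | np.ndarray:
    """Shannon entropy (bits) of a Bernoulli(p) variable; h(0)=h(1)=0."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log2(p), 0.0)
              + np.where(p < 1, (1 - p) * np.log2(1 - p), 0.0))
    return float(h) if h.ndim == 0 else h


class Agent:
    """act/update contract used by :func:`entrobeat.task.run_session`."""

    lapse_probability: float = 0.0

    def fresh(self) -> "Agent":
        """Return a copy with any learning state reset."""
        return self

    def act(self, prev_choice, prev_outcome, rng: np.random.Generator) -> str:
        if self.lapse_probability and rng.random() < self.lapse_probability:
            return NONE
        return self._policy(prev_choice, prev_outcome, rng)

    def _policy(self, prev_choice, prev_outcome, rng) -> str:
        raise NotImplementedError

    def update(self, choice: str, outcome: str) -> None:
        pass


def _uniform(rng: np.random.Generator) -> str:
    return ADV if rng.random() < 0.5 else DIS


@dataclass
class BiasedRandom(Agent):
    """I.i.d. choice of the advantageous stimulus with probability p_adv."""

    p_adv: float = 0.5
    lapse_probability: float = 0.0

    def __post_init__(self):
        _check_prob("p_adv", self.p_adv)
        _check_prob("lapse_probability", self.lapse_probability)

    def _policy(self, prev_choice, prev_outcome, rng):
        return ADV if rng.random() < self.p_adv else DIS


@dataclass
class Constant(Agent):
    """Picks a stimulus uniformly on the first trial, then never deviates."""

    lapse_probability: float = 0.0
    _stimulus: str | None = field(default=None, repr=False)

    def fresh(self):
        return Constant(lapse_probability=self.lapse_probability)

    def _policy(self, prev_choice, prev_outcome, rng):
        if self._stimulus is None:
            self._stimulus = _uniform(rng)
        return self._stimulus


@dataclass
class WSLS(Agent):
    """Win-Stay/Lose-Shift, executed with probability ``p_execute``.

    With probability 1 − p_execute the opposite action (lose-stay or
    win-shift) is taken, so p_execute = 1 is the deterministic strategy
    and p_execute = 0.5 is outcome-independent random choice.
    """

    p_execute: float = 1.0
    lapse_probability: float = 0.0

    def __post_init__(self):
        _check_prob("p_execute", self.p_execute)
        _check_prob("lapse_probability", self.lapse_probability)

    def _policy(self, prev_choice, prev_outcome, rng):
        if prev_choice is None or prev_choice == NONE:
            return _uniform(rng)
        wsls_action = prev_choice if prev_outcome == GAIN else _other(prev_choice)
        if rng.random() < self.p_execute:
            return wsls_action
        return _other(wsls_action)


@dataclass
class OutcomeConditioned(Agent):
    """Stays with the previous stimulus with a per-outcome probability.

    This family parameterizes the conditional-entropy statistic directly:
    the asymptotic entropy is the mean binary entropy of the two stay
    probabilities.
    """

    p_stay_given_gain: float = 0.5
    p_stay_given_loss: float = 0.5
    lapse_probability: float = 0.0

    def __post_init__(self):
        _check_prob("p_stay_given_gain", self.p_stay_given_gain)
        _check_prob("p_stay_given_loss", self.p_stay_given_loss)
        _check_prob("lapse_probability", self.lapse_probability)

    def _policy(self, prev_choice, prev_outcome, rng):
        if prev_choice is None or prev_choice == NONE:
            return _uniform(rng)
        p_stay = (self.p_stay_given_gain if prev_outcome == GAIN
                  else self.p_stay_given_loss)
        return prev_choice if rng.random() < p_stay else _other(prev_choice)


@dataclass
class QSoftmax(Agent):
    """Two-armed Rescorla–Wagner learner with softmax choice.

    Action values start at 0 and update as Q ← Q + α(r − Q) with r = +1
    for a gain and −1 for a loss; choice probabilities are softmax with
    inverse temperature β.  Generative scaffolding only — large β with
    moderate α drives response bias above 0.5 in the contingent task.
    """

    learning_rate: float = 0.3
    inverse_temperature: float = 3.0
    lapse_probability: float = 0.0
    _q: dict = field(default=None, repr=False)

    def __post_init__(self):
        if not 0.0 < self.learning_rate <= 1.0:
            raise ConfigurationError("learning_rate must be in (0, 1]")
        if self.inverse_temperature < 0:
            raise ConfigurationError("inverse_temperature must be >= 0")
        _check_prob("lapse_probability", self.lapse_probability)
        if self._q is None:
            self._q = {ADV: 0.0, DIS: 0.0}

    def fresh(self):
        return QSoftmax(learning_rate=self.learning_rate,
                        inverse_temperature=self.inverse_temperature,
                        lapse_probability=self.lapse_probability)

    def _policy(self, prev_choice, prev_outcome, rng):
        b = self.inverse_temperature
        # numerically safe two-option softmax
        d = b * (self._q[ADV] - self._q[DIS])
        p_adv = 1.0 / (1.0 + math.exp(-d)) if abs(d) < 700 else (d > 0) * 1.0
        return ADV if rng.random() < p_adv else DIS

    def update(self, choice, outcome):
        r = 1.0 if outcome == GAIN else -1.0
        self._q[choice] += self.learning_rate * (r - self._q[choice])


def _other(choice: str) -> str:
    return DIS if choice == ADV else ADV


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name}={value} outside [0, 1]")


def expected_entropy(agent: Agent) -> float:
    """Asymptotic normalized conditional entropy of an agent's policy.

    Closed forms exist for the stationary families: the statistic converges
    to the mean binary entropy of the stay probabilities in the two
    previous-outcome states.  For a learning agent (QSoftmax) there is no
    stationary closed form and the caller must estimate by simulation.
    """
    if isinstance(agent, OutcomeConditioned):
        return float((binary_entropy(agent.p_stay_given_gain)
                      + binary_entropy(agent.p_stay_given_loss)) / 2.0)
    if isinstance(agent, WSLS):
        # stay|gain = p_execute, stay|loss = 1 - p_execute
        return float(binary_entropy(agent.p_execute))
    if isinstance(agent, Constant):
        return 0.0
    if isinstance(agent, BiasedRandom):
        # i.i.d. choice: P(stay) = p^2 + (1-p)^2 in both states
        p = agent.p_adv
        return float(binary_entropy(p * p + (1 - p) * (1 - p)))
    raise ConfigurationError(
        f"no stationary closed form for {type(agent).__name__}; "
        "estimate entropy by simulation"
    )


_KIND_ALIASES = {
    "biased_random": "biased_random", "biased": "biased_random",
    "constant": "constant",
    "wsls": "wsls",
    "outcome_conditioned": "outcome_conditioned", "ocond": "outcome_conditioned",
    "q_softmax": "q_softmax", "qsoftmax": "q_softmax",
}

_PARAM_ALIASES = {
    "biased_random": {"p_adv": "p_adv", "p": "p_adv"},
    "constant": {},
    "wsls": {"p_execute": "p_execute", "p": "p_execute"},
    "outcome_conditioned": {
        "p_stay_given_gain": "p_stay_given_gain", "psg": "p_stay_given_gain",
        "p_stay_given_loss": "p_stay_given_loss", "psl": "p_stay_given_loss",
    },
    "q_softmax": {
        "learning_rate": "learning_rate", "alpha": "learning_rate",
        "inverse_temperature": "inverse_temperature", "beta": "inverse_temperature",
    },
}

_CONSTRUCTORS = {
    "biased_random": BiasedRandom,
    "constant": Constant,
    "wsls": WSLS,
    "outcome_conditioned": OutcomeConditioned,
    "q_softmax": QSoftmax,
}


def parse_agent(spec: str) -> Agent:
    """Build an agent from a CLI spec string.

    Examples: ``wsls:p_execute=0.9``, ``ocond:psg=0.8,psl=0.3``,
    ``qsoftmax:alpha=0.3,beta=5``, ``constant``, ``biased:p=0.68``.
    Any spec may append ``lapse=<prob>``.
    """
    kind_str, _, params_str = spec.partition(":")
    kind = _KIND_ALIASES.get(kind_str.strip().lower())
    if kind is None:
        raise ConfigurationError(f"unknown agent kind: {kind_str!r}")
    aliases = _PARAM_ALIASES[kind]
    kwargs = {}
    if params_str:
        for item in params_str.split(","):
            key, _, val = item.partition("=")
            key = key.strip().lower()
            if not _ or not key:
                raise ConfigurationError(f"malformed agent parameter: {item!r}")
            if key in ("lapse", "lapse_probability"):
                kwargs["lapse_probability"] = float(val)
                continue
            if key not in aliases:
                raise ConfigurationError(
                    f"unknown parameter {key!r} for agent kind {kind!r}")
            kwargs[aliases[key]] = float(val)
    return _CONSTRUCTORS[kind](**kwargs)
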