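"""Stateful learning rules mapping own reward history to the next action.

Two completely uncoupled rules are provided:

* **Melioration** -- epsilon-greedy choice over per-action running-mean
  reward estimates (Q-values with a 1/K learning rate).  With probability
  ``epsilon`` the action is drawn uniformly over the *whole* action set
  (including the greedy action); otherwise an action with maximal Q-value
  is played, ties broken uniformly at random.
* **Roth-Erev** -- probability-matching over accumulated propensities.
  The chosen action's propensity grows by ``(1 - epsilon) * reward``; every
  other action receives the spillover ``epsilon / (n - 1) * reward``.
  Propensities are clamped below at a small positive floor so the choice
  probabilities stay well-defined when noisy rewards are negative.

Both learners observe only their own choice and their own realised reward.
The round protocol is strictly: choose, observe reward, update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "MeliorationState",
    "RothErevState",
    "mel_choose",
    "mel_update",
    "re_choose",
    "re_update",
    "make_learner",
    "choose",
    "update",
    "DEFAULT_PROPENSITY_FLOOR",
]

DEFAULT_PROPENSITY_FLOOR = 1e-6


def _check_epsilon(epsilon: float) -> float:
    epsilon = float(epsilon)
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError(f"epsilon must lie in [0, 1]; got {epsilon}")
    return epsilon


@dataclass
class MeliorationState:
    """Per-agent state of the melioration rule.

    ``q_values[e]`` is the arithmetic mean of all rewards received on
    rounds where action ``e`` was chosen (0 while unvisited); ``counts[e]``
    is the number of such rounds.  ``t`` counts completed rounds.
    """

    n_actions: int
    epsilon: float
    q_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    t: int = 0
    truncate_rewards_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.n_actions < 2:
            raise ValueError("n_actions must be >= 2")
        self.epsilon = _check_epsilon(self.epsilon)
        if self.q_values is None:
            self.q_values = np.zeros(self.n_actions)
        else:
            self.q_values = np.asarray(self.q_values, dtype=float).copy()
        if self.counts is None:
            self.counts = np.zeros(self.n_actions, dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64).copy()
        if self.q_values.shape != (self.n_actions,) or self.counts.shape != (
            self.n_actions,
        ):
            raise ValueError("q_values and counts must have length n_actions")

    @property
    def rule(self) -> str:
        return "melioration"


@dataclass
class RothErevState:
    """Per-agent state of the Roth-Erev rule.

    Absent floor clamping, ``sum(propensities) == n_actions +
    cumulative_reward`` exactly: the chosen action gains ``(1 - eps) * y``
    and the remaining ``n - 1`` actions gain ``eps / (n - 1) * y`` each.
    """

    n_actions: int
    epsilon: float
    propensities: np.ndarray = field(default=None)  # type: ignore[assignment]
    t: int = 0
    cumulative_reward: float = 0.0
    floor: float = DEFAULT_PROPENSITY_FLOOR
    truncate_rewards_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.n_actions < 2:
            raise ValueError("n_actions must be >= 2")
        self.epsilon = _check_epsilon(self.epsilon)
        if self.floor <= 0:
            raise ValueError("propensity floor must be strictly positive")
        if self.propensities is None:
            self.propensities = np.ones(self.n_actions)
        else:
            self.propensities = np.asarray(self.propensities, dtype=float).copy()
        if self.propensities.shape != (self.n_actions,):
            raise ValueError("propensities must have length n_actions")
        if (self.propensities <= 0).any():
            raise ValueError("propensities must be strictly positive")

    @property
    def rule(self) -> str:
        return "roth_erev"


# ---------------------------------------------------------------------------
# melioration
# ---------------------------------------------------------------------------

def mel_choose(state: MeliorationState, rng: np.random.Generator) -> int:
    """Epsilon-greedy draw: uniform exploration with probability epsilon,
    otherwise a uniformly chosen maximiser of the Q-values."""
    if rng.random() < state.epsilon:
        return int(rng.integers(state.n_actions))
    q = state.q_values
    maximisers = np.flatnonzero(q == q.max())
    if maximisers.size == 1:
        return int(maximisers[0])
    return int(rng.choice(maximisers))


def mel_update(state: MeliorationState, chosen: int, reward: float) -> MeliorationState:
    """Incremental-mean update of the chosen action's Q-value (in place)."""
    if not (0 <= chosen < state.n_actions):
        raise IndexError(f"action index {chosen} out of range")
    if not np.isfinite(reward):
        raise ValueError(f"reward must be finite; got {reward}")
    if state.truncate_rewards_at_zero:
        reward = max(0.0, reward)
    state.counts[chosen] += 1
    state.q_values[chosen] += (reward - state.q_values[chosen]) / state.counts[chosen]
    state.t += 1
    return state


# ---------------------------------------------------------------------------
# Roth-Erev
# ---------------------------------------------------------------------------

def re_choose(state: RothErevState, rng: np.random.Generator) -> int:
    """Draw an action with probability proportional to its propensity."""
    p = state.propensities
    total = p.sum()
    u = rng.random() * total
    return int(min(np.searchsorted(np.cumsum(p), u, side="right"), state.n_actions - 1))


def re_update(state: RothErevState, chosen: int, reward: float) -> RothErevState:
    """Propensity update with exploration spillover and a positive floor."""
    if not (0 <= chosen < state.n_actions):
        raise IndexError(f"action index {chosen} out of range")
    if not np.isfinite(reward):
        raise ValueError(f"reward must be finite; got {reward}")
    if state.truncate_rewards_at_zero:
        reward = max(0.0, reward)
    spill = state.epsilon / (state.n_actions - 1) * reward
    state.propensities += spill
    state.propensities[chosen] += (1.0 - state.epsilon) * reward - spill
    np.maximum(state.propensities, state.floor, out=state.propensities)
    state.cumulative_reward += reward
    state.t += 1
    return state


# ---------------------------------------------------------------------------
# rule-generic dispatch and construction
# ---------------------------------------------------------------------------

LearnerState = MeliorationState | RothErevState


def choose(state: LearnerState, rng: np.random.Generator) -> int:
    """Dispatch to the state's choice rule."""
    if isinstance(state, MeliorationState):
        return mel_choose(state, rng)
    if isinstance(state, RothErevState):
        return re_choose(state, rng)
    raise TypeError(f"unknown learner state type: {type(state).__name__}")


def update(state: LearnerState, chosen: int, reward: float) -> LearnerState:
    """Dispatch to the state's update rule."""
    if isinstance(state, MeliorationState):
        return mel_update(state, chosen, reward)
    if isinstance(state, RothErevState):
        return re_update(state, chosen, reward)
    raise TypeError(f"unknown learner state type: {type(state).__name__}")


def make_learner(config: Mapping, n_actions: int) -> LearnerState:
    """Build a fresh learner state from a rule-spec mapping.

    Keys: ``rule`` ("melioration" or "roth_erev"), ``epsilon``, and
    optionally ``propensity_floor`` (roth_erev only) and
    ``truncate_rewards_at_zero``.
    """
    cfg = dict(config)
    rule = cfg.pop("rule")
    epsilon = float(cfg.pop("epsilon"))
    truncate = bool(cfg.pop("truncate_rewards_at_zero", False))
    if rule == "melioration":
        if cfg:
            raise ValueError(f"unknown melioration config key(s): {sorted(cfg)}")
        return MeliorationState(
            n_actions=n_actions, epsilon=epsilon, truncate_rewards_at_zero=truncate
        )
    if rule == "roth_erev":
        floor = float(cfg.pop("propensity_floor", DEFAULT_PROPENSITY_FLOOR))
        if cfg:
            raise ValueError(f"unknown roth_erev config key(s): {sorted(cfg)}")
        return RothErevState(
            n_actions=n_actions,
            epsilon=epsilon,
            floor=floor,
            truncate_rewards_at_zero=truncate,
        )
    raise ValueError(f"unknown rule {rule!r}; expected 'melioration' or 'roth_erev'")
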