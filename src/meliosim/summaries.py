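"""Summary statistics and convergence diagnostics over batch results.

The two core summaries mirror how repeated-game learning experiments are
usually reported: a distribution of pairs over joint outcomes at a
reference round, and per-agent *cumulative* relative choice frequencies
tracked at log-spaced checkpoints (each checkpoint value covers the whole
period from round 1 up to that round).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from meliosim.engine import BatchResult

__all__ = [
    "OutcomeDistribution",
    "FrequencyTrajectory",
    "ConvergenceReport",
    "outcome_distribution",
    "frequency_trajectory",
    "convergence_diagnostic",
    "expected_one_sided_exploration_count",
]


def expected_one_sided_exploration_count(n_pairs: int, epsilon: float) -> float:
    """Expected pairs observed at a given one-sided deviation cell of a
    2x2 game once both agents have locked onto a strict equilibrium.

    At the reference round one agent explores to the off-equilibrium
    action (probability ``epsilon / 2``) while the partner does not
    (probability ``1 - epsilon / 2``), giving
    ``n_pairs * (epsilon / 2) * (1 - epsilon / 2)``.
    """
    return n_pairs * (epsilon / 2.0) * (1.0 - epsilon / 2.0)


@dataclass
class OutcomeDistribution:
    """Distribution of pairs over joint outcomes at the final round."""

    game_name: str
    rule: str
    reference_round: int
    n_pairs: int
    actions_x: tuple[str, ...]
    actions_y: tuple[str, ...]
    counts: np.ndarray  # shape (|actions_x|, |actions_y|)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n_pairs

    def count(self, label_x: str, label_y: str) -> int:
        return int(
            self.counts[self.actions_x.index(label_x), self.actions_y.index(label_y)]
        )

    def proportion(self, label_x: str, label_y: str) -> float:
        return self.count(label_x, label_y) / self.n_pairs

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "action_x": ax,
                "action_y": ay,
                "count": int(self.counts[i, j]),
                "proportion": self.counts[i, j] / self.n_pairs,
            }
            for i, ax in enumerate(self.actions_x)
            for j, ay in enumerate(self.actions_y)
        ]
        return pd.DataFrame(rows)


@dataclass
class FrequencyTrajectory:
    """Across-agent mean and SD of cumulative choice frequencies.

    ``mean``/``sd`` have shape ``(n_checkpoints, n_actions)``;
    ``per_agent`` keeps the underlying ``(n_checkpoints, n_agents,
    n_actions)`` cumulative frequencies for per-agent diagnostics.
    """

    game_name: str
    rule: str
    player: str
    actions: tuple[str, ...]
    checkpoints: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    per_agent: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.checkpoints):
            for j, a in enumerate(self.actions):
                rows.append(
                    {
                        "round": int(t),
                        "player": self.player,
                        "action": a,
                        "mean_freq": self.mean[i, j],
                        "sd_freq": self.sd[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ConvergenceReport:
    """Per-agent convergence verdicts from cumulative-frequency stability."""

    tolerance: float
    window_checkpoints: np.ndarray
    converged: np.ndarray  # bool per agent
    amplitude: np.ndarray  # max cumulative-frequency range per agent

    @property
    def fraction_converged(self) -> float:
        return float(self.converged.mean())


def outcome_distribution(batch: BatchResult) -> OutcomeDistribution:
    """Tabulate pairs by their joint action at the final round."""
    if batch.n_pairs < 1:
        raise ValueError("batch is empty")
    return OutcomeDistribution(
        game_name=batch.game_name,
        rule=batch.rule,
        reference_round=batch.rounds,
        n_pairs=batch.n_pairs,
        actions_x=batch.actions_x,
        actions_y=batch.actions_y,
        counts=batch.outcome_counts(),
    )


def frequency_trajectory(batch: BatchResult, player: str = "x") -> FrequencyTrajectory:
    """Cumulative relative choice frequencies at the batch's checkpoints.

    ``player`` selects whose agents are aggregated: ``"x"``, ``"y"`` or
    ``"both"`` (only valid when both players share one action set).
    """
    if batch.checkpoints is None:
        raise ValueError(
            "batch has no checkpoint log; re-run the simulation with a "
            "checkpoint schedule (e.g. simulate --trajectories)"
        )
    if player == "x":
        counts = batch.checkpoint_counts_x
        actions = batch.actions_x
    elif player == "y":
        counts = batch.checkpoint_counts_y
        actions = batch.actions_y
    elif player == "both":
        if batch.actions_x != batch.actions_y:
            raise ValueError("player='both' needs identical action sets")
        counts = np.concatenate(
            [batch.checkpoint_counts_x, batch.checkpoint_counts_y], axis=1
        )
        actions = batch.actions_x
    else:
        raise ValueError(f"player must be 'x', 'y' or 'both'; got {player!r}")
    freqs = counts / batch.checkpoints[:, None, None]
    return FrequencyTrajectory(
        game_name=batch.game_name,
        rule=batch.rule,
        player=player,
        actions=actions,
        checkpoints=batch.checkpoints,
        mean=freqs.mean(axis=1),
        sd=freqs.std(axis=1),
        per_agent=freqs,
    )


def convergence_diagnostic(
    trajectory: FrequencyTrajectory, tolerance: float = 0.05
) -> ConvergenceReport:
    """Judge convergence from late-run cumulative-frequency stability.

    An agent counts as converged when, over the last half of the
    (log-spaced) checkpoints, the range of its cumulative frequency stays
    below ``tolerance`` for every action.  The per-agent ``amplitude`` is
    the largest such range, a direct measure of sustained oscillation.
    """
    n_cp = len(trajectory.checkpoints)
    if n_cp < 10:
        raise ValueError("need at least 10 checkpoints for the diagnostic")
    half = n_cp // 2
    window = trajectory.per_agent[half:]  # (cp, agents, actions)
    ranges = window.max(axis=0) - window.min(axis=0)
    amplitude = ranges.max(axis=1)
    return ConvergenceReport(
        tolerance=tolerance,
        window_checkpoints=trajectory.checkpoints[half:],
        converged=amplitude < tolerance,
        amplitude=amplitude,
    )
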