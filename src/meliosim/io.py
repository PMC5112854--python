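"""CSV serialisation of batch results and trajectory logs.

Output files start with ``#``-prefixed comment lines echoing the run
configuration (including the master seed); read them back with
``comment="#"`` or the readers below.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from meliosim.engine import BatchResult
from meliosim.summaries import frequency_trajectory

__all__ = [
    "results_frame",
    "write_results_csv",
    "read_results_csv",
    "trajectory_frame",
    "write_trajectories_csv",
    "read_trajectories_csv",
]


def _header(batch: BatchResult) -> str:
    return (
        f"# game={batch.game_name} rule={batch.rule} n_pairs={batch.n_pairs} "
        f"rounds={batch.rounds} epsilon={batch.epsilon} seed={batch.seed}\n"
    )


def results_frame(batch: BatchResult) -> pd.DataFrame:
    """One row per pair: final joint outcome plus whole-run relative
    choice frequencies of both agents."""
    data: dict = {
        "pair_id": np.arange(batch.n_pairs),
        "rule": batch.rule,
        "final_action_x": [batch.actions_x[i] for i in batch.final_x],
        "final_action_y": [batch.actions_y[i] for i in batch.final_y],
    }
    for j, a in enumerate(batch.actions_x):
        data[f"relfreq_x_{a}"] = batch.relfreq_x[:, j]
    for j, a in enumerate(batch.actions_y):
        data[f"relfreq_y_{a}"] = batch.relfreq_y[:, j]
    return pd.DataFrame(data)


def write_results_csv(batch: BatchResult, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(batch))
        results_frame(batch).to_csv(fh, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def trajectory_frame(batch: BatchResult) -> pd.DataFrame:
    """Long-format cumulative frequencies: one row per (checkpoint,
    agent, action)."""
    if batch.checkpoints is None:
        raise ValueError("batch carries no checkpoint log")
    frames = []
    for player in ("x", "y"):
        traj = frequency_trajectory(batch, player=player)
        n_cp, n_agents, n_actions = traj.per_agent.shape
        cp = np.repeat(batch.checkpoints, n_agents * n_actions)
        pid = np.tile(np.repeat(np.arange(n_agents), n_actions), n_cp)
        act = np.tile(list(traj.actions), n_cp * n_agents)
        frames.append(
            pd.DataFrame(
                {
                    "round": cp,
                    "pair_id": pid,
                    "player": player,
                    "action": act,
                    "cum_freq": traj.per_agent.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trajectories_csv(batch: BatchResult, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(batch))
        trajectory_frame(batch).to_csv(fh, index=False)


def read_trajectories_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
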