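"""Preset experiments reproducing the catalogue simulation study.

Each experiment id (``fig2`` ... ``fig14``) bundles the games, learning
rules and protocol constants of one published simulation: 10000 pairs per
rule and 1000 rounds at exploration rate 0.1 for games settled quickly,
and 1000 pairs per rule for 20000 rounds at exploration rate 0.2 for
games with only a mixed equilibrium.  ``scale`` multiplies the number of
pairs (floor 1) so reduced-size replications stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from meliosim.config import (
    DEFAULT_EPSILON,
    DEFAULT_PAIRS,
    DEFAULT_ROUNDS,
    MIXED_GAME_EPSILON,
    MIXED_GAME_ROUNDS,
)
from meliosim.engine import BatchResult, checkpoint_schedule, run_batch
from meliosim.games import build_fixture
from meliosim.io import write_results_csv, write_trajectories_csv
from meliosim.summaries import outcome_distribution

__all__ = ["EXPERIMENTS", "replicate_experiment"]

_RULES = ("melioration", "roth_erev")
_MIXED_PAIRS = 1000  # per rule, mixed-equilibrium protocol


@dataclass(frozen=True)
class RunSetup:
    name: str
    game: str
    rule: str
    n_pairs: int
    rounds: int
    epsilon: float
    game_params: dict = field(default_factory=dict)
    trajectories: bool = False


def _standard(exp: str, game: str, params: dict | None = None) -> list[RunSetup]:
    return [
        RunSetup(
            name=f"{exp}_{game}_{rule}",
            game=game,
            rule=rule,
            n_pairs=DEFAULT_PAIRS,
            rounds=DEFAULT_ROUNDS,
            epsilon=DEFAULT_EPSILON,
            game_params=dict(params or {}),
        )
        for rule in _RULES
    ]


def _mixed(
    exp: str,
    game: str,
    params: dict | None = None,
    rules: tuple[str, ...] = _RULES,
    n_pairs: int = _MIXED_PAIRS,
    tag: str = "",
) -> list[RunSetup]:
    return [
        RunSetup(
            name=f"{exp}_{game}{tag}_{rule}",
            game=game,
            rule=rule,
            n_pairs=n_pairs,
            rounds=MIXED_GAME_ROUNDS,
            epsilon=MIXED_GAME_EPSILON,
            game_params=dict(params or {}),
            trajectories=True,
        )
        for rule in rules
    ]


def _build_experiments() -> dict[str, list[RunSetup]]:
    exps: dict[str, list[RunSetup]] = {
        "fig2": _standard("fig2", "pd"),
        "fig3": _standard("fig3", "guess23"),
        "fig4": _standard("fig4", "three_eq"),
        "fig5": _standard("fig5", "coordination"),
        "fig8": _standard("fig8", "bos") + _standard("fig8", "chicken"),
        "fig9": _standard("fig9", "dispersion4"),
        "fig10": _mixed("fig10", "matching_pennies"),
        "fig11": _mixed("fig11", "rps"),
        "fig12": _mixed("fig12", "inspection"),
    }
    # reward sweep over the suboptimal coordination equilibrium
    exps["fig6"] = [
        run
        for r_bb in (2.0, 4.0, 6.0, 8.0, 10.0)
        for run in _standard(
            f"fig6_rBB{r_bb:g}", "coordination", {"reward_BB": r_bb}
        )
    ]
    # reward sweep over the mis-coordination cells
    exps["fig7"] = [
        run
        for a, b in ((0.0, 10.0), (5.0, 5.0), (8.0, 2.0))
        for run in _standard(f"fig7_a{a:g}b{b:g}", "coordination", {"a": a, "b": b})
    ]
    # punishment contrast, melioration only, 1000 criminal agents each
    exps["fig13"] = _mixed(
        "fig13",
        "inspection",
        {"punishment": 1.4},
        rules=("melioration",),
        n_pairs=1000,
        tag="_low_punishment",
    ) + _mixed(
        "fig13",
        "inspection",
        {"punishment": 0.0},
        rules=("melioration",),
        n_pairs=1000,
        tag="_high_punishment",
    )
    # long-run non-convergence showcase
    exps["fig14"] = _mixed("fig14", "shapley", n_pairs=100)
    return exps


EXPERIMENTS: dict[str, list[RunSetup]] = _build_experiments()


def replicate_experiment(
    which: str,
    scale: float = 1.0,
    seed: int = 0,
    outdir: str | Path | None = None,
    n_checkpoints: int = 50,
) -> dict[str, BatchResult]:
    """Run one preset experiment, optionally writing CSVs to ``outdir``.

    Returns a mapping from run name to :class:`BatchResult`.  Every run's
    master seed is derived deterministically from ``seed`` and the run
    name, so single experiments replay identically regardless of which
    other experiments are run.
    """
    if which not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {which!r}; available: {', '.join(EXPERIMENTS)}"
        )
    if scale <= 0:
        raise ValueError("scale must be strictly positive")
    outdir = Path(outdir) if outdir is not None else None
    results: dict[str, BatchResult] = {}
    for idx, setup in enumerate(EXPERIMENTS[which]):
        game = build_fixture(setup.game, setup.game_params)
        n_pairs = max(1, int(round(setup.n_pairs * scale)))
        cps = (
            checkpoint_schedule(setup.rounds, n_checkpoints)
            if setup.trajectories
            else None
        )
        batch = run_batch(
            game,
            {"rule": setup.rule, "epsilon": setup.epsilon},
            n_pairs=n_pairs,
            rounds=setup.rounds,
            master_seed=seed * 10007 + idx,
            checkpoints=cps,
        )
        results[setup.name] = batch
        if outdir is not None:
            write_results_csv(batch, outdir / f"{setup.name}.csv")
            outcome_distribution(batch).to_frame().to_csv(
                outdir / f"{setup.name}_outcomes.csv", index=False
            )
            if setup.trajectories:
                write_trajectories_csv(batch, outdir / f"{setup.name}_traj.csv")
    return results
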