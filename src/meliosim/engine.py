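"""Repeated simultaneous play between two learners, and seeded batches.

Two execution paths are provided:

* :func:`play_pair` -- a readable reference loop over one pair of learner
  state objects, returning the full trajectory.  Used for small runs and
  as the behavioural oracle in tests.
* :func:`run_batch` -- a vectorised kernel that advances many independent
  pairs in lock-step across rounds.  Pair ``i`` draws all of its
  randomness from a generator seeded with ``SeedSequence([master_seed,
  i])``, so each pair's result depends only on ``(master_seed, i)`` --
  not on the batch size, the chunking, or the order of execution -- and
  the whole batch replays bit-identically from the same inputs.

Within a round both players choose simultaneously: neither learner ever
sees the partner's action or reward, only its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from meliosim.games import GameConfigError, NormalFormGame, sample_rewards
from meliosim.learners import (
    DEFAULT_PROPENSITY_FLOOR,
    LearnerState,
    MeliorationState,
    RothErevState,
    choose,
    make_learner,
    update,
)

__all__ = [
    "PairTrajectory",
    "BatchResult",
    "play_pair",
    "run_batch",
    "checkpoint_schedule",
]

_CHUNK_PAIRS = 2000  # pairs advanced per vectorised block (memory bound)


@dataclass
class PairTrajectory:
    """Complete per-round record of one pair's repeated play."""

    actions_x: np.ndarray
    actions_y: np.ndarray
    rewards_x: np.ndarray
    rewards_y: np.ndarray

    @property
    def rounds(self) -> int:
        return len(self.actions_x)

    def __post_init__(self) -> None:
        n = len(self.actions_x)
        if not (len(self.actions_y) == len(self.rewards_x) == len(self.rewards_y) == n):
            raise ValueError("trajectory sequences must have identical length")


@dataclass
class BatchResult:
    """Summary of a batch of independent pairs playing the same game.

    ``final_x``/``final_y`` hold each pair's joint action at the last
    round.  ``relfreq_x``/``relfreq_y`` are per-agent relative choice
    frequencies over all rounds, shape ``(n_pairs, n_actions)``.  When a
    checkpoint schedule was requested, ``checkpoint_counts_x/y`` hold the
    cumulative per-action choice counts of every agent at each checkpoint
    time, shape ``(n_checkpoints, n_pairs, n_actions)``.
    """

    game_name: str
    rule: str
    n_pairs: int
    rounds: int
    epsilon: float
    seed: int
    actions_x: tuple[str, ...]
    actions_y: tuple[str, ...]
    final_x: np.ndarray
    final_y: np.ndarray
    relfreq_x: np.ndarray
    relfreq_y: np.ndarray
    checkpoints: np.ndarray | None = None
    checkpoint_counts_x: np.ndarray | None = None
    checkpoint_counts_y: np.ndarray | None = None
    last_window: int = 0
    window_outcome_counts: np.ndarray | None = None

    def outcome_counts(self, classify: str = "final") -> np.ndarray:
        """Count pairs by joint outcome, shape (|Ax|, |Ay|).

        ``classify="final"`` uses the joint action at the last round;
        ``classify="modal"`` uses each pair's modal joint outcome over the
        last ``last_window`` rounds (requires the window log, which
        de-noises the exploration scatter of the final round).
        """
        n_ax, n_ay = len(self.actions_x), len(self.actions_y)
        if classify == "final":
            flat = np.bincount(
                self.final_x * n_ay + self.final_y, minlength=n_ax * n_ay
            )
            return flat.reshape(n_ax, n_ay)
        if classify == "modal":
            if self.window_outcome_counts is None:
                raise ValueError(
                    "no window log; re-run with last_window > 0 for modal "
                    "outcome classification"
                )
            modal = self.window_outcome_counts.reshape(self.n_pairs, -1).argmax(axis=1)
            return np.bincount(modal, minlength=n_ax * n_ay).reshape(n_ax, n_ay)
        raise ValueError(f"classify must be 'final' or 'modal'; got {classify!r}")


def checkpoint_schedule(rounds: int, n_checkpoints: int = 50) -> np.ndarray:
    """Log-spaced, deduplicated checkpoint rounds in [1, rounds]."""
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    pts = np.unique(
        np.round(np.geomspace(1, rounds, num=min(n_checkpoints, rounds))).astype(int)
    )
    pts[-1] = rounds
    return pts


def play_pair(
    game: NormalFormGame,
    learner_x: LearnerState,
    learner_y: LearnerState,
    rounds: int,
    rng: np.random.Generator,
) -> PairTrajectory:
    """Run one pair for ``rounds`` rounds of simultaneous play.

    Each round: both learners choose (without seeing each other), rewards
    are sampled from the joint payoff cell, and each learner is updated
    with its own reward only.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if learner_x.n_actions != game.n_actions_x:
        raise GameConfigError(
            f"learner_x has {learner_x.n_actions} actions but game "
            f"{game.name!r} expects {game.n_actions_x}"
        )
    if learner_y.n_actions != game.n_actions_y:
        raise GameConfigError(
            f"learner_y has {learner_y.n_actions} actions but game "
            f"{game.name!r} expects {game.n_actions_y}"
        )
    ax = np.empty(rounds, dtype=np.int64)
    ay = np.empty(rounds, dtype=np.int64)
    rx = np.empty(rounds)
    ry = np.empty(rounds)
    for t in range(rounds):
        ax[t] = choose(learner_x, rng)
        ay[t] = choose(learner_y, rng)
        rx[t], ry[t] = sample_rewards(game, ax[t], ay[t], rng)
        update(learner_x, ax[t], rx[t])
        update(learner_y, ay[t], ry[t])
    return PairTrajectory(actions_x=ax, actions_y=ay, rewards_x=rx, rewards_y=ry)


# ---------------------------------------------------------------------------
# vectorised batch execution
# ---------------------------------------------------------------------------

def _pair_generators(master_seed: int, lo: int, hi: int) -> list[np.random.Generator]:
    return [
        np.random.Generator(np.random.PCG64(np.random.SeedSequence([master_seed, i])))
        for i in range(lo, hi)
    ]


def _masked_argmax_uniform(values: np.ndarray, mask: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Row-wise uniform draw among masked entries via random scores ``u``."""
    scores = np.where(mask, u, -1.0)
    return scores.argmax(axis=1)


def _run_chunk_melioration(
    game: NormalFormGame,
    epsilon: float,
    rounds: int,
    gens: Sequence[np.random.Generator],
    truncate: bool,
    checkpoints: np.ndarray | None,
    last_window: int = 0,
):
    n = len(gens)
    nax, nay = game.n_actions_x, game.n_actions_y
    k = 2 + nax + nay
    # Per-pair random blocks: k uniforms + 2 normals per round, one block
    # per pair so results are independent of batch composition.
    u = np.empty((n, rounds, k))
    z = np.empty((n, rounds, 2))
    for i, g in enumerate(gens):
        u[i] = g.random((rounds, k))
        z[i] = g.standard_normal((rounds, 2))

    qx = np.zeros((n, nax))
    kx = np.zeros((n, nax), dtype=np.int64)
    qy = np.zeros((n, nay))
    ky = np.zeros((n, nay), dtype=np.int64)
    rows = np.arange(n)
    sd = game.noise_sd
    mx, my = game.mean_payoff_x, game.mean_payoff_y

    cp_x = cp_y = None
    cp_set: dict[int, int] = {}
    if checkpoints is not None:
        cp_x = np.empty((len(checkpoints), n, nax), dtype=np.int64)
        cp_y = np.empty((len(checkpoints), n, nay), dtype=np.int64)
        cp_set = {int(t): i for i, t in enumerate(checkpoints)}
    wc = np.zeros((n, nax, nay), dtype=np.int32) if last_window > 0 else None

    last_ax = last_ay = None
    for t in range(rounds):
        ut = u[:, t, :]
        tb_x = ut[:, 2 : 2 + nax]
        tb_y = ut[:, 2 + nax :]
        explore_x = ut[:, 0] < epsilon
        explore_y = ut[:, 1] < epsilon
        greedy_x = _masked_argmax_uniform(qx, qx == qx.max(axis=1, keepdims=True), tb_x)
        greedy_y = _masked_argmax_uniform(qy, qy == qy.max(axis=1, keepdims=True), tb_y)
        ax = np.where(explore_x, tb_x.argmax(axis=1), greedy_x)
        ay = np.where(explore_y, tb_y.argmax(axis=1), greedy_y)

        rx = mx[ax, ay] + sd * z[:, t, 0]
        ry = my[ax, ay] + sd * z[:, t, 1]
        if truncate:
            np.maximum(rx, 0.0, out=rx)
            np.maximum(ry, 0.0, out=ry)

        kx[rows, ax] += 1
        qx[rows, ax] += (rx - qx[rows, ax]) / kx[rows, ax]
        ky[rows, ay] += 1
        qy[rows, ay] += (ry - qy[rows, ay]) / ky[rows, ay]

        if cp_x is not None and (t + 1) in cp_set:
            j = cp_set[t + 1]
            cp_x[j] = kx
            cp_y[j] = ky
        if wc is not None and t >= rounds - last_window:
            np.add.at(wc, (rows, ax, ay), 1)
        last_ax, last_ay = ax, ay

    return last_ax, last_ay, kx, ky, cp_x, cp_y, wc


def _run_chunk_roth_erev(
    game: NormalFormGame,
    epsilon: float,
    rounds: int,
    gens: Sequence[np.random.Generator],
    truncate: bool,
    floor: float,
    checkpoints: np.ndarray | None,
    last_window: int = 0,
):
    n = len(gens)
    nax, nay = game.n_actions_x, game.n_actions_y
    u = np.empty((n, rounds, 2))
    z = np.empty((n, rounds, 2))
    for i, g in enumerate(gens):
        u[i] = g.random((rounds, 2))
        z[i] = g.standard_normal((rounds, 2))

    px = np.ones((n, nax))
    py = np.ones((n, nay))
    kx = np.zeros((n, nax), dtype=np.int64)
    ky = np.zeros((n, nay), dtype=np.int64)
    rows = np.arange(n)
    sd = game.noise_sd
    mx, my = game.mean_payoff_x, game.mean_payoff_y
    spill_x = epsilon / (nax - 1)
    spill_y = epsilon / (nay - 1)

    cp_x = cp_y = None
    cp_set: dict[int, int] = {}
    if checkpoints is not None:
        cp_x = np.empty((len(checkpoints), n, nax), dtype=np.int64)
        cp_y = np.empty((len(checkpoints), n, nay), dtype=np.int64)
        cp_set = {int(t): i for i, t in enumerate(checkpoints)}
    wc = np.zeros((n, nax, nay), dtype=np.int32) if last_window > 0 else None

    last_ax = last_ay = None
    for t in range(rounds):
        cx = np.cumsum(px, axis=1)
        cy = np.cumsum(py, axis=1)
        ax = np.minimum(
            (cx < (u[:, t, 0] * cx[:, -1])[:, None]).sum(axis=1), nax - 1
        )
        ay = np.minimum(
            (cy < (u[:, t, 1] * cy[:, -1])[:, None]).sum(axis=1), nay - 1
        )

        rx = mx[ax, ay] + sd * z[:, t, 0]
        ry = my[ax, ay] + sd * z[:, t, 1]
        if truncate:
            np.maximum(rx, 0.0, out=rx)
            np.maximum(ry, 0.0, out=ry)

        px += spill_x * rx[:, None]
        px[rows, ax] += (1.0 - epsilon) * rx - spill_x * rx
        np.maximum(px, floor, out=px)
        py += spill_y * ry[:, None]
        py[rows, ay] += (1.0 - epsilon) * ry - spill_y * ry
        np.maximum(py, floor, out=py)

        kx[rows, ax] += 1
        ky[rows, ay] += 1
        if cp_x is not None and (t + 1) in cp_set:
            j = cp_set[t + 1]
            cp_x[j] = kx
            cp_y[j] = ky
        if wc is not None and t >= rounds - last_window:
            np.add.at(wc, (rows, ax, ay), 1)
        last_ax, last_ay = ax, ay

    return last_ax, last_ay, kx, ky, cp_x, cp_y, wc


def run_batch(
    game: NormalFormGame,
    rule_spec: Mapping,
    n_pairs: int,
    rounds: int,
    master_seed: int,
    checkpoints: np.ndarray | Sequence[int] | None = None,
    last_window: int = 0,
    chunk_pairs: int = _CHUNK_PAIRS,
) -> BatchResult:
    """Run ``n_pairs`` mutually independent pairs of identical learners.

    Parameters
    ----------
    rule_spec:
        Learner configuration mapping (see
        :func:`meliosim.learners.make_learner`); both members of every
        pair use this rule.
    checkpoints:
        Optional increasing round numbers at which cumulative per-agent
        action counts are recorded (e.g. from
        :func:`checkpoint_schedule`).
    last_window:
        When positive, joint-outcome counts over the final ``last_window``
        rounds are logged per pair, enabling modal-outcome classification
        (see :meth:`BatchResult.outcome_counts`).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    spec = dict(rule_spec)
    # validate the full spec up front (raises on unknown keys / bad values)
    probe = make_learner(spec, game.n_actions_x)
    rule = spec["rule"]
    epsilon = float(spec["epsilon"])
    truncate = bool(spec.get("truncate_rewards_at_zero", False))
    floor = probe.floor if isinstance(probe, RothErevState) else DEFAULT_PROPENSITY_FLOOR
    if checkpoints is not None:
        checkpoints = np.asarray(checkpoints, dtype=int)
        if checkpoints.size and (
            (np.diff(checkpoints) <= 0).any()
            or checkpoints[0] < 1
            or checkpoints[-1] > rounds
        ):
            raise ValueError("checkpoints must be strictly increasing in [1, rounds]")

    nax, nay = game.n_actions_x, game.n_actions_y
    final_x = np.empty(n_pairs, dtype=np.int64)
    final_y = np.empty(n_pairs, dtype=np.int64)
    counts_x = np.empty((n_pairs, nax), dtype=np.int64)
    counts_y = np.empty((n_pairs, nay), dtype=np.int64)
    cp_x = cp_y = None
    if checkpoints is not None:
        cp_x = np.empty((len(checkpoints), n_pairs, nax), dtype=np.int64)
        cp_y = np.empty((len(checkpoints), n_pairs, nay), dtype=np.int64)
    window_counts = (
        np.empty((n_pairs, nax, nay), dtype=np.int32) if last_window > 0 else None
    )

    for lo in range(0, n_pairs, chunk_pairs):
        hi = min(lo + chunk_pairs, n_pairs)
        gens = _pair_generators(master_seed, lo, hi)
        if rule == "melioration":
            ax, ay, kx, ky, ck_x, ck_y, wc = _run_chunk_melioration(
                game, epsilon, rounds, gens, truncate, checkpoints, last_window
            )
        else:
            ax, ay, kx, ky, ck_x, ck_y, wc = _run_chunk_roth_erev(
                game, epsilon, rounds, gens, truncate, floor, checkpoints, last_window
            )
        final_x[lo:hi] = ax
        final_y[lo:hi] = ay
        counts_x[lo:hi] = kx
        counts_y[lo:hi] = ky
        if cp_x is not None:
            cp_x[:, lo:hi] = ck_x
            cp_y[:, lo:hi] = ck_y
        if window_counts is not None:
            window_counts[lo:hi] = wc

    return BatchResult(
        game_name=game.name,
        rule=rule,
        n_pairs=n_pairs,
        rounds=rounds,
        epsilon=epsilon,
        seed=master_seed,
        actions_x=game.actions_x,
        actions_y=game.actions_y,
        final_x=final_x,
        final_y=final_y,
        relfreq_x=counts_x / rounds,
        relfreq_y=counts_y / rounds,
        checkpoints=None if checkpoints is None else checkpoints,
        checkpoint_counts_x=cp_x,
        checkpoint_counts_y=cp_y,
        last_window=last_window,
        window_outcome_counts=window_counts,
    )
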