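"""Game-theoretic reference predictions for two-person normal-form games.

All computations run on the *mean* payoff matrices: the reward noise is
zero-mean, so the expected game is the matrix game.  Mixed equilibria are
found by support enumeration over equal-size supports, which is exact for
the small (<= 4 actions per player) games this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from meliosim.games import NormalFormGame

__all__ = [
    "EquilibriumSet",
    "find_pure_nash",
    "find_dominant",
    "find_maximin",
    "mixed_equilibria",
    "payoff_dominance_order",
    "analyse_game",
    "is_degenerate",
]

_TOL = 1e-9


def _payoffs(game: NormalFormGame, player: str) -> np.ndarray:
    if player == "x":
        return game.mean_payoff_x
    if player == "y":
        return game.mean_payoff_y
    raise ValueError(f"player must be 'x' or 'y'; got {player!r}")


def find_pure_nash(game: NormalFormGame) -> list[tuple[int, int]]:
    """All joint pure outcomes where neither player can strictly gain by a
    unilateral deviation in mean payoffs."""
    ux, uy = game.mean_payoff_x, game.mean_payoff_y
    best_x = ux >= ux.max(axis=0, keepdims=True) - _TOL  # x best-responds per column
    best_y = uy >= uy.max(axis=1, keepdims=True) - _TOL  # y best-responds per row
    return [tuple(idx) for idx in np.argwhere(best_x & best_y)]


def find_dominant(game: NormalFormGame, player: str) -> list[int]:
    """Weakly dominant action(s) of ``player``.

    An action qualifies when it is at least as good as every alternative
    against all partner choices, and strictly better than *every*
    alternative against at least one partner choice.  Usually the result
    has zero or one element; degenerate games may yield more.
    """
    u = _payoffs(game, player)
    if player == "y":
        u = u.T  # rows become y's own actions
    n = u.shape[0]
    out = []
    for d in range(n):
        others = [a for a in range(n) if a != d]
        weak = all((u[d] >= u[a] - _TOL).all() for a in others)
        strict_somewhere = (u[d][None, :] > u[others] + _TOL).all(axis=0).any()
        if weak and strict_somewhere:
            out.append(d)
    return out


def find_maximin(game: NormalFormGame, player: str) -> list[int]:
    """All actions attaining the maximin value on mean payoffs."""
    u = _payoffs(game, player)
    if player == "y":
        u = u.T
    worst = u.min(axis=1)
    return [int(a) for a in np.flatnonzero(worst >= worst.max() - _TOL)]


def is_degenerate(game: NormalFormGame) -> bool:
    """Cheap degeneracy flag: some pure partner strategy admits more than
    one pure best response for a player."""
    ux, uy = game.mean_payoff_x, game.mean_payoff_y
    multi_x = ((ux >= ux.max(axis=0, keepdims=True) - _TOL).sum(axis=0) > 1).any()
    multi_y = ((uy >= uy.max(axis=1, keepdims=True) - _TOL).sum(axis=1) > 1).any()
    return bool(multi_x or multi_y)


def _indifference_solve(a: np.ndarray) -> np.ndarray | None:
    """Solve for the column player's support probabilities making the row
    player indifferent across ``a``'s rows; returns the probability vector
    over the support, or None if the system is singular/inconsistent."""
    k = a.shape[0]
    m = np.zeros((k + 1, k + 1))
    m[:k, :k] = a
    m[:k, k] = -1.0  # common value v
    m[k, :k] = 1.0  # probabilities sum to one
    rhs = np.zeros(k + 1)
    rhs[k] = 1.0
    try:
        sol = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError:
        return None
    if not np.isfinite(sol).all():
        return None
    return sol  # (probabilities..., value)


def mixed_equilibria(
    game: NormalFormGame, tol: float = _TOL
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All Nash equilibria found by equal-size support enumeration.

    Returns ``(p, q)`` profiles (full-length probability vectors for x and
    y), deduplicated; pure equilibria appear as unit vectors.  On
    degenerate games (see :func:`is_degenerate`) equilibrium components
    are represented by the vertices the enumeration finds, not the full
    continuum.
    """
    ux, uy = game.mean_payoff_x, game.mean_payoff_y
    nx, ny = game.n_actions_x, game.n_actions_y
    found: list[tuple[np.ndarray, np.ndarray]] = []
    for k in range(1, min(nx, ny) + 1):
        for sx in combinations(range(nx), k):
            for sy in combinations(range(ny), k):
                sx_a, sy_a = np.array(sx), np.array(sy)
                # y's probs on sy make x indifferent across sx
                sol_q = _indifference_solve(ux[np.ix_(sx_a, sy_a)])
                # x's probs on sx make y indifferent across sy
                sol_p = _indifference_solve(uy[np.ix_(sx_a, sy_a)].T)
                if sol_q is None or sol_p is None:
                    continue
                q_s, v = sol_q[:k], sol_q[k]
                p_s, w = sol_p[:k], sol_p[k]
                if (q_s < -tol).any() or (p_s < -tol).any():
                    continue
                p = np.zeros(nx)
                q = np.zeros(ny)
                p[sx_a] = np.clip(p_s, 0.0, None)
                q[sy_a] = np.clip(q_s, 0.0, None)
                p /= p.sum()
                q /= q.sum()
                # no profitable deviation outside the supports
                if (ux @ q).max() > v + 1e-7:
                    continue
                if (p @ uy).max() > w + 1e-7:
                    continue
                if not any(
                    np.abs(p - p0).max() < 1e-6 and np.abs(q - q0).max() < 1e-6
                    for p0, q0 in found
                ):
                    found.append((p, q))
    return found


def payoff_dominance_order(
    game: NormalFormGame, outcomes: list[tuple[int, int]] | None = None
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Pairs ``(e1, e2)`` of pure equilibria where ``e1`` payoff-dominates
    ``e2``: both players do at least as well at ``e1`` and at least one
    does strictly better."""
    if outcomes is None:
        outcomes = find_pure_nash(game)
    ux, uy = game.mean_payoff_x, game.mean_payoff_y
    order = []
    for e1 in outcomes:
        for e2 in outcomes:
            if e1 == e2:
                continue
            dx = ux[e1] - ux[e2]
            dy = uy[e1] - uy[e2]
            if dx >= -_TOL and dy >= -_TOL and (dx > _TOL or dy > _TOL):
                order.append((e1, e2))
    return order


@dataclass
class EquilibriumSet:
    """Bundle of the reference predictions for one game."""

    game_name: str
    pure: list[tuple[int, int]]
    mixed: list[tuple[np.ndarray, np.ndarray]]
    dominant_x: list[int]
    dominant_y: list[int]
    maximin_x: list[int]
    maximin_y: list[int]
    payoff_dominance: list[tuple[tuple[int, int], tuple[int, int]]]
    degenerate: bool

    def strictly_mixed(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Equilibria where both players randomise over >= 2 actions."""
        return [
            (p, q)
            for p, q in self.mixed
            if (p > _TOL).sum() >= 2 and (q > _TOL).sum() >= 2
        ]


def analyse_game(game: NormalFormGame) -> EquilibriumSet:
    """Compute the full equilibrium report for a game."""
    pure = find_pure_nash(game)
    return EquilibriumSet(
        game_name=game.name,
        pure=pure,
        mixed=mixed_equilibria(game),
        dominant_x=find_dominant(game, "x"),
        dominant_y=find_dominant(game, "y"),
        maximin_x=find_maximin(game, "x"),
        maximin_y=find_maximin(game, "y"),
        payoff_dominance=payoff_dominance_order(game, pure),
        degenerate=is_degenerate(game),
    )
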