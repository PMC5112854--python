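"""Independent reference computations used to cross-check the package.

Everything here is deliberately written against different primitives than
the implementation: closed forms for 2x2 games, linear programming for
constant-sum games, and exhaustive best-response checks on mean payoffs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def pure_nash_bruteforce(ux: np.ndarray, uy: np.ndarray) -> set[tuple[int, int]]:
    """Enumerate every cell and test unilateral deviations directly."""
    ux, uy = np.asarray(ux), np.asarray(uy)
    out = set()
    for i in range(ux.shape[0]):
        for j in range(ux.shape[1]):
            if all(ux[k, j] <= ux[i, j] + 1e-12 for k in range(ux.shape[0])) and all(
                uy[i, l] <= uy[i, j] + 1e-12 for l in range(ux.shape[1])
            ):
                out.add((i, j))
    return out


def mixed_2x2_closed_form(
    ux: np.ndarray, uy: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """Interior mixed equilibrium of a 2x2 game from the indifference
    closed form, or None if no interior solution exists."""
    ux, uy = np.asarray(ux, float), np.asarray(uy, float)
    dy = uy[0, 0] - uy[1, 0] - uy[0, 1] + uy[1, 1]
    dx = ux[0, 0] - ux[0, 1] - ux[1, 0] + ux[1, 1]
    if abs(dx) < 1e-12 or abs(dy) < 1e-12:
        return None
    p = (uy[1, 1] - uy[1, 0]) / dy  # x's probability of action 0
    q = (ux[1, 1] - ux[0, 1]) / dx  # y's probability of action 0
    if not (0 < p < 1 and 0 < q < 1):
        return None
    return np.array([p, 1 - p]), np.array([q, 1 - q])


def zero_sum_maximin(a: np.ndarray) -> tuple[float, np.ndarray]:
    """Value and a maximin strategy of the zero-sum game with row-player
    payoff matrix ``a``, via linear programming."""
    a = np.asarray(a, float)
    shift = a.min() - 1.0
    b = a - shift  # strictly positive payoffs
    m, n = b.shape
    # min sum(x) s.t. B^T x >= 1, x >= 0; value = 1/sum(x)
    res = linprog(
        c=np.ones(m), A_ub=-b.T, b_ub=-np.ones(n), bounds=[(0, None)] * m,
        method="highs",
    )
    assert res.success
    x = res.x
    value = 1.0 / x.sum() + shift
    return value, x / x.sum()


def is_epsilon_nash(
    ux: np.ndarray, uy: np.ndarray, p: np.ndarray, q: np.ndarray, eps: float = 1e-7
) -> bool:
    """Direct best-response verification of a mixed profile."""
    ux, uy = np.asarray(ux), np.asarray(uy)
    vx = p @ ux @ q
    vy = p @ uy @ q
    return bool((ux @ q <= vx + eps).all() and (p @ uy <= vy + eps).all())


def guess23_payoffs() -> tuple[np.ndarray, np.ndarray]:
    """Recompute the guessing-game payoff table from its verbal rule."""
    u_x = np.zeros((4, 4))
    u_y = np.zeros((4, 4))
    for gx in range(4):
        for gy in range(4):
            target = 2 * (gx + gy) / 6  # two thirds of the average guess
            dx, dy = abs(gx - target), abs(gy - target)
            if abs(dx - dy) < 1e-12:
                u_x[gx, gy] = u_y[gx, gy] = 5
            elif dx < dy:
                u_x[gx, gy] = 10
            else:
                u_y[gx, gy] = 10
    return u_x, u_y
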