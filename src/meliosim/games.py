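"""Two-person normal-form games with stochastic rewards, plus a fixture catalogue.

A :class:`NormalFormGame` stores *mean* payoffs; realised rewards are the
matrix mean plus independent Gaussian noise with standard deviation
``noise_sd`` (default 1.0), drawn independently for the two players and
across rounds.

Matrix orientation: rows index player x's actions, columns index player y's
actions, for *both* payoff matrices.  ``mean_payoff_x[i, j]`` is x's mean
reward and ``mean_payoff_y[i, j]`` is y's mean reward when x plays action
``i`` and y plays action ``j``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "NormalFormGame",
    "GameConfigError",
    "sample_rewards",
    "build_fixture",
    "list_fixtures",
    "load_game_spec",
    "save_game_spec",
    "FIXTURE_NAMES",
]


class GameConfigError(ValueError):
    """Raised for unknown fixture names or invalid game parameters."""


@dataclass(frozen=True)
class NormalFormGame:
    """A two-person normal-form game with Gaussian reward noise.

    Parameters
    ----------
    name:
        Identifier string.
    actions_x, actions_y:
        Ordered action labels for each player (at least two, unique).
    mean_payoff_x, mean_payoff_y:
        Mean-reward matrices of shape ``(len(actions_x), len(actions_y))``.
    noise_sd:
        Standard deviation of the additive Gaussian reward noise (>= 0).
    """

    name: str
    actions_x: tuple[str, ...]
    actions_y: tuple[str, ...]
    mean_payoff_x: np.ndarray
    mean_payoff_y: np.ndarray
    noise_sd: float = 1.0
    params: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ax = tuple(str(a) for a in self.actions_x)
        ay = tuple(str(a) for a in self.actions_y)
        object.__setattr__(self, "actions_x", ax)
        object.__setattr__(self, "actions_y", ay)
        mx = np.asarray(self.mean_payoff_x, dtype=float)
        my = np.asarray(self.mean_payoff_y, dtype=float)
        object.__setattr__(self, "mean_payoff_x", mx)
        object.__setattr__(self, "mean_payoff_y", my)
        if len(ax) < 2 or len(ay) < 2:
            raise GameConfigError("each player needs at least two actions")
        if len(set(ax)) != len(ax) or len(set(ay)) != len(ay):
            raise GameConfigError("action labels must be unique within a player")
        shape = (len(ax), len(ay))
        if mx.shape != shape or my.shape != shape:
            raise GameConfigError(
                f"payoff matrices must have shape {shape}; "
                f"got {mx.shape} and {my.shape}"
            )
        if not (np.isfinite(mx).all() and np.isfinite(my).all()):
            raise GameConfigError("payoff matrices must be finite")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise GameConfigError("noise_sd must be a non-negative real")

    @property
    def n_actions_x(self) -> int:
        return len(self.actions_x)

    @property
    def n_actions_y(self) -> int:
        return len(self.actions_y)

    def with_noise_sd(self, noise_sd: float) -> "NormalFormGame":
        """Return a copy of the game with a different noise level."""
        return NormalFormGame(
            name=self.name,
            actions_x=self.actions_x,
            actions_y=self.actions_y,
            mean_payoff_x=self.mean_payoff_x,
            mean_payoff_y=self.mean_payoff_y,
            noise_sd=noise_sd,
            params=dict(self.params),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "actions_x": list(self.actions_x),
            "actions_y": list(self.actions_y),
            "mean_payoff_x": self.mean_payoff_x.tolist(),
            "mean_payoff_y": self.mean_payoff_y.tolist(),
            "noise_sd": self.noise_sd,
        }


def sample_rewards(
    game: NormalFormGame, ax: int, ay: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one pair of realised rewards for the joint action ``(ax, ay)``.

    Each player receives the cell's mean payoff plus independent Gaussian
    noise with standard deviation ``game.noise_sd``.
    """
    if not (0 <= ax < game.n_actions_x):
        raise IndexError(f"action index {ax} out of range for player x")
    if not (0 <= ay < game.n_actions_y):
        raise IndexError(f"action index {ay} out of range for player y")
    if game.noise_sd == 0.0:
        return float(game.mean_payoff_x[ax, ay]), float(game.mean_payoff_y[ax, ay])
    nx, ny = rng.standard_normal(2)
    return (
        float(game.mean_payoff_x[ax, ay] + game.noise_sd * nx),
        float(game.mean_payoff_y[ax, ay] + game.noise_sd * ny),
    )


# ---------------------------------------------------------------------------
# fixture catalogue
# ---------------------------------------------------------------------------

_AB = ("A", "B")
_ABC = ("A", "B", "C")


def _sym(name, u_x, noise_sd=1.0, params=None, actions=_AB):
    """Symmetric two-player game: y's payoff matrix is x's transposed."""
    u_x = np.asarray(u_x, dtype=float)
    return NormalFormGame(
        name=name,
        actions_x=actions,
        actions_y=actions,
        mean_payoff_x=u_x,
        mean_payoff_y=u_x.T,
        noise_sd=noise_sd,
        params=params or {},
    )


def _fixture_pd() -> NormalFormGame:
    # B strictly dominant for both; (B,B) the unique pure equilibrium.
    return _sym("pd", [[7.0, 0.0], [10.0, 3.0]])


def _fixture_guess23() -> NormalFormGame:
    # Discrete "guess 2/3 of the average" over guesses {0,1,2,3}: the player
    # strictly closer to (2/3)*mean(guesses) earns 10, the other 0; ties 5/5.
    guesses = np.arange(4, dtype=float)
    n = len(guesses)
    u_x = np.zeros((n, n))
    u_y = np.zeros((n, n))
    for i, gx in enumerate(guesses):
        for j, gy in enumerate(guesses):
            target = (2.0 / 3.0) * (gx + gy) / 2.0
            dx, dy = abs(gx - target), abs(gy - target)
            if np.isclose(dx, dy):
                u_x[i, j] = u_y[i, j] = 5.0
            elif dx < dy:
                u_x[i, j], u_y[i, j] = 10.0, 0.0
            else:
                u_x[i, j], u_y[i, j] = 0.0, 10.0
    return NormalFormGame(
        name="guess23",
        actions_x=("0", "1", "2", "3"),
        actions_y=("0", "1", "2", "3"),
        mean_payoff_x=u_x,
        mean_payoff_y=u_y,
    )


def _fixture_three_eq() -> NormalFormGame:
    # B weakly dominant for x, A weakly dominant for y; three pure equilibria
    # (A,A), (B,A), (B,B), all paying (10, 10).  Only the mis-coordination
    # cell (A,B) pays (0, 0).
    return NormalFormGame(
        name="three_eq",
        actions_x=_AB,
        actions_y=_AB,
        mean_payoff_x=[[10.0, 0.0], [10.0, 10.0]],
        mean_payoff_y=[[10.0, 0.0], [10.0, 10.0]],
    )


def _fixture_coordination(
    reward_BB: float = 8.0, a: float = 0.0, b: float = 0.0
) -> NormalFormGame:
    # Diagonal rewards 10 / reward_BB; the off-diagonal rewards a (for the
    # A-chooser) and b (for the B-chooser) parameterise the mis-coordination
    # cells.  Defaults give the mixed equilibrium (A: 4/9, B: 5/9).
    u_x = [[10.0, a], [b, reward_BB]]
    return _sym(
        "coordination", u_x, params={"reward_BB": reward_BB, "a": a, "b": b}
    )


def _fixture_bos() -> NormalFormGame:
    # Battle of the sexes; mixed equilibrium x:(3/13, 10/13), y:(10/13, 3/13).
    return NormalFormGame(
        name="bos",
        actions_x=_AB,
        actions_y=_AB,
        mean_payoff_x=[[3.0, 0.0], [0.0, 10.0]],
        mean_payoff_y=[[10.0, 0.0], [0.0, 3.0]],
    )


def _fixture_chicken() -> NormalFormGame:
    # Pure equilibria (A,B) and (B,A); (B,B) is the worst outcome for both.
    return _sym("chicken", [[5.0, 2.0], [10.0, 0.0]])


def _fixture_dispersion4() -> NormalFormGame:
    # Anti-coordination: both earn 10 when the actions differ, 0 when equal.
    n = 4
    off = 10.0 * (1.0 - np.eye(n))
    return NormalFormGame(
        name="dispersion4",
        actions_x=("A", "B", "C", "D"),
        actions_y=("A", "B", "C", "D"),
        mean_payoff_x=off,
        mean_payoff_y=off,
    )


def _fixture_matching_pennies() -> NormalFormGame:
    # Constant-sum (10): x wins on a match, y on a mismatch.
    u_x = np.array([[10.0, 0.0], [0.0, 10.0]])
    return NormalFormGame(
        name="matching_pennies",
        actions_x=_AB,
        actions_y=_AB,
        mean_payoff_x=u_x,
        mean_payoff_y=10.0 - u_x,
    )


def _cyclic_3x3(diag: float) -> np.ndarray:
    # Row beats the previous column cyclically: A<B<C<A.  Win 10, loss 0.
    u = np.full((3, 3), 0.0)
    np.fill_diagonal(u, diag)
    for i in range(3):
        u[i, (i - 1) % 3] = 10.0  # row action beats the column it dominates
    return u


def _fixture_rps() -> NormalFormGame:
    return _sym("rps", _cyclic_3x3(diag=5.0), actions=_ABC)


def _fixture_shapley() -> NormalFormGame:
    # Identical to rps except the diagonal rewards are (0, 0) instead of (5, 5).
    return _sym("shapley", _cyclic_3x3(diag=0.0), actions=_ABC)


def _fixture_inspection(punishment: float = 0.0) -> NormalFormGame:
    # x = criminal (A: crime, B: no crime), y = inspector (A: inspect, B: spare).
    # ``punishment`` is x's mean payoff at (A,A); it must stay below the
    # no-crime payoff 4 for the game to keep a unique, strictly mixed
    # equilibrium x:(1/2, 1/2), y:(10/(14-c), 1 - 10/(14-c)) -- (5/7, 2/7)
    # at the default c = 0.  The uninspected-crime/no-crime payoffs (14, 4)
    # keep the equilibrium inspection rate well below the reachable
    # epsilon-greedy ceiling 1 - eps/2 across the punishment sweep.
    c = float(punishment)
    if c >= 4.0:
        raise GameConfigError(
            "punishment must be < 4 to preserve the unique mixed equilibrium"
        )
    return NormalFormGame(
        name="inspection",
        actions_x=_AB,
        actions_y=_AB,
        mean_payoff_x=[[c, 14.0], [4.0, 4.0]],
        mean_payoff_y=[[10.0, 0.0], [0.0, 10.0]],
        params={"punishment": c},
    )


_FIXTURES: dict[str, Callable[..., NormalFormGame]] = {
    "pd": _fixture_pd,
    "guess23": _fixture_guess23,
    "three_eq": _fixture_three_eq,
    "coordination": _fixture_coordination,
    "bos": _fixture_bos,
    "chicken": _fixture_chicken,
    "dispersion4": _fixture_dispersion4,
    "matching_pennies": _fixture_matching_pennies,
    "rps": _fixture_rps,
    "shapley": _fixture_shapley,
    "inspection": _fixture_inspection,
}

FIXTURE_NAMES: tuple[str, ...] = tuple(_FIXTURES)

_FIXTURE_PARAMS: dict[str, set[str]] = {
    "coordination": {"reward_BB", "a", "b"},
    "inspection": {"punishment"},
}


def list_fixtures() -> tuple[str, ...]:
    """Names of all built-in game fixtures."""
    return FIXTURE_NAMES


def build_fixture(
    name: str, params: Mapping[str, float] | None = None, noise_sd: float = 1.0
) -> NormalFormGame:
    """Build a catalogue game by name.

    Parameters
    ----------
    name:
        One of :data:`FIXTURE_NAMES`.
    params:
        Fixture-specific numeric parameters.  ``coordination`` accepts
        ``reward_BB`` (mean reward at (B,B), default 8) and the
        off-diagonal rewards ``a``/``b`` (defaults 0); ``inspection``
        accepts ``punishment`` (x's mean payoff at (A,A), default 0).
    noise_sd:
        Reward noise standard deviation (default 1.0).
    """
    if name not in _FIXTURES:
        raise GameConfigError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    params = dict(params or {})
    allowed = _FIXTURE_PARAMS.get(name, set())
    unknown = set(params) - allowed
    if unknown:
        raise GameConfigError(
            f"fixture {name!r} does not accept parameter(s): {sorted(unknown)}"
        )
    game = _FIXTURES[name](**params)
    if noise_sd != 1.0:
        game = game.with_noise_sd(noise_sd)
    return game


# ---------------------------------------------------------------------------
# JSON game specs
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = {"name", "actions_x", "actions_y", "mean_payoff_x", "mean_payoff_y"}


def load_game_spec(path: str | Path) -> NormalFormGame:
    """Load a game from a JSON spec file.

    Expected keys: ``name``, ``actions_x``, ``actions_y``, ``mean_payoff_x``,
    ``mean_payoff_y`` and optionally ``noise_sd``.  Rows of the payoff
    matrices index x's actions; columns index y's actions.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GameConfigError(f"could not parse game spec {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise GameConfigError(f"game spec {path} must be a JSON object")
    missing = _REQUIRED_KEYS - set(data)
    if missing:
        raise GameConfigError(f"game spec {path} missing key(s): {sorted(missing)}")
    unknown = set(data) - _REQUIRED_KEYS - {"noise_sd"}
    if unknown:
        raise GameConfigError(f"game spec {path} has unknown key(s): {sorted(unknown)}")
    return NormalFormGame(
        name=str(data["name"]),
        actions_x=tuple(data["actions_x"]),
        actions_y=tuple(data["actions_y"]),
        mean_payoff_x=np.asarray(data["mean_payoff_x"], dtype=float),
        mean_payoff_y=np.asarray(data["mean_payoff_y"], dtype=float),
        noise_sd=float(data.get("noise_sd", 1.0)),
    )


def save_game_spec(game: NormalFormGame, path: str | Path) -> None:
    """Write a game to a JSON spec file (see :func:`load_game_spec`)."""
    Path(path).write_text(json.dumps(game.to_dict(), indent=2) + "\n")


def resolve_game(ref: str, params: Mapping[str, float] | None = None) -> NormalFormGame:
    """Resolve a game reference: fixture name, or path to a JSON spec file."""
    if ref in _FIXTURES:
        return build_fixture(ref, params)
    p = Path(ref)
    if p.suffix.lower() == ".json" or p.exists():
        if params:
            raise GameConfigError("--param is only valid with fixture names")
        return load_game_spec(p)
    raise GameConfigError(
        f"{ref!r} is neither a known fixture ({', '.join(FIXTURE_NAMES)}) "
        "nor an existing JSON spec file"
    )
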