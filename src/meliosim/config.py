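"""Run configuration: validation, defaults, and file round-tripping.

Defaults follow the standard simulation protocol used throughout the
fixture catalogue: 10000 pairs per learning rule, 1000 rounds, exploration
rate 0.1, Gaussian reward noise with SD 1.  Games without pure equilibria
are conventionally run longer with more exploration (20000 rounds,
epsilon 0.2); the replicate presets apply that automatically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from meliosim.learners import DEFAULT_PROPENSITY_FLOOR

__all__ = ["RunConfig", "ConfigError", "load_config"]

DEFAULT_PAIRS = 10000
DEFAULT_ROUNDS = 1000
DEFAULT_EPSILON = 0.1
MIXED_GAME_ROUNDS = 20000
MIXED_GAME_EPSILON = 0.2


class ConfigError(ValueError):
    """Raised with a list of all configuration violations."""


@dataclass
class RunConfig:
    """Validated parameters of one simulation batch."""

    game: str = "pd"
    game_params: dict[str, float] = field(default_factory=dict)
    rule: str = "melioration"
    n_pairs: int = DEFAULT_PAIRS
    rounds: int = DEFAULT_ROUNDS
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0
    out: str | None = None
    trajectories: str | None = None
    n_checkpoints: int = 50
    truncate_rewards_at_zero: bool = False
    propensity_floor: float = DEFAULT_PROPENSITY_FLOOR

    def __post_init__(self) -> None:
        problems = []
        if self.rule not in ("melioration", "roth_erev"):
            problems.append(
                f"rule must be 'melioration' or 'roth_erev'; got {self.rule!r}"
            )
        if not isinstance(self.n_pairs, int) or self.n_pairs < 1:
            problems.append(f"n_pairs must be a positive integer; got {self.n_pairs!r}")
        if not isinstance(self.rounds, int) or self.rounds < 1:
            problems.append(f"rounds must be a positive integer; got {self.rounds!r}")
        if not (0.0 < float(self.epsilon) < 1.0):
            problems.append(f"epsilon must lie in (0, 1); got {self.epsilon!r}")
        if not isinstance(self.seed, int):
            problems.append(f"seed must be an integer; got {self.seed!r}")
        if self.n_checkpoints < 2:
            problems.append("n_checkpoints must be >= 2")
        if self.propensity_floor <= 0:
            problems.append("propensity_floor must be strictly positive")
        if problems:
            raise ConfigError("; ".join(problems))

    def rule_spec(self) -> dict[str, Any]:
        spec: dict[str, Any] = {
            "rule": self.rule,
            "epsilon": self.epsilon,
            "truncate_rewards_at_zero": self.truncate_rewards_at_zero,
        }
        if self.rule == "roth_erev":
            spec["propensity_floor"] = self.propensity_floor
        return spec

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2) + "\n")


_FIELDS = set(RunConfig.__dataclass_fields__)


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML/JSON file plus
    overrides (CLI flags); unknown keys are rejected by name."""
    data: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        loaded = (
            yaml.safe_load(text)
            if path.suffix.lower() in (".yaml", ".yml")
            else json.loads(text)
        )
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        data.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    unknown = set(data) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)
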