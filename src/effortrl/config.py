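"""Run configuration: baseline defaults, YAML loading and validation.

An empty configuration reproduces the baseline parameter point used across
the simulations (alpha=0.5, gamma=3, cost=0.2, delta=0.8, rewards 1/2, loop
gains 10/1; schedule simulation: gamma=6, bias=-3).  Unknown keys and
out-of-range values are rejected with the offending key named.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

from .core import ModelParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunable parameters with their baseline defaults."""

    # learning / choice
    alpha: float = 0.5
    gamma: float = 3.0
    cost: float = 0.2
    gain_boost: float = 10.0
    gain_noboost: float = 1.0
    seed: int = 0
    # trial structure
    n_train: int = 150
    n_test: int = 50
    n_reps: int = 1000
    # conflict tasks
    delta: float = 0.8
    reward_easy: float = 1.0
    reward_difficult: float = 2.0
    block_trials: int = 200
    block_reps: int = 100
    # T-maze
    reward_lr: float = 1.0
    reward_hr: float = 2.0
    maze_trials: int = 200
    maze_reps: int = 100
    # variable-interval schedule
    schedule_gamma: float = 6.0
    schedule_bias: float = -3.0
    schedule_reward: float = 2.1
    press_cost: float = 4.5
    p_step: float = 0.02
    schedule_runs: int = 100
    schedule_trials: int = 200
    schedule_recorded: int = 50
    max_delay: int = 10
    persist_reinforcement: bool = True
    # io
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        checks = [
            ("alpha", 0.0 <= self.alpha <= 1.0, "must be in [0, 1]"),
            ("gamma", self.gamma >= 0, "must be >= 0"),
            ("cost", self.cost >= 0, "must be >= 0"),
            ("delta", 0.0 <= self.delta < 1.0, "must be in [0, 1)"),
            (
                "gain_boost",
                self.gain_boost > self.gain_noboost > 0,
                "must exceed gain_noboost (> 0)",
            ),
            ("p_step", 0.0 < self.p_step <= 1.0, "must be in (0, 1]"),
            ("max_delay", self.max_delay >= 1, "must be >= 1"),
            ("schedule_gamma", self.schedule_gamma >= 0, "must be >= 0"),
            (
                "schedule_recorded",
                0 < self.schedule_recorded <= self.schedule_trials,
                "must be in (0, schedule_trials]",
            ),
        ]
        for name in (
            "n_train",
            "n_test",
            "n_reps",
            "block_trials",
            "block_reps",
            "maze_trials",
            "maze_reps",
            "schedule_runs",
            "schedule_trials",
        ):
            checks.append((name, getattr(self, name) >= 0, "must be non-negative"))
        for name, ok, msg in checks:
            if not ok:
                raise ValueError(f"config value {name!r} {msg}, got {getattr(self, name)}")

    def model_params(self, **overrides) -> ModelParams:
        kw = dict(
            alpha=self.alpha,
            gamma=self.gamma,
            cost=self.cost,
            gain_boost=self.gain_boost,
            gain_noboost=self.gain_noboost,
            n_train=self.n_train,
            n_test=self.n_test,
            n_reps=self.n_reps,
            seed=self.seed,
        )
        kw.update(overrides)
        return ModelParams(**kw)

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Load a YAML config (or defaults) and apply keyword overrides."""
    data: dict = {}
    if path:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    return RunConfig(**data)
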