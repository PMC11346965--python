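"""Task and optimizer configuration objects.

All design constants of the bandit task live in :class:`TaskConfig`; the
nested-fit optimizer budget lives in :class:`OptimizerConfig`.  Both can be
round-tripped through YAML or JSON so that simulation and fitting runs are
fully described by a config file plus a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class TaskConfig:
    """Design constants of the three-armed bandit task.

    Defaults encode the published task: two runs of 240 choice trials
    (192 free, 48 guided) plus 16 estimation trials per run; three bandits
    whose means are equidistant with the low and high bandit 33.33 points
    apart; Gaussian components with SD 5.55; a bimodal mid bandit whose
    smaller (20%) mode sits 35 points below the main mode; rewards bounded
    to [0, 100].
    """

    n_choice_trials_per_run: int = 240
    n_free: int = 192
    n_guided: int = 48
    n_estimation: int = 16
    n_runs: int = 2
    low_high_distance: float = 33.33
    gaussian_sd: float = 5.55
    mix_weight_low_mode: float = 0.2
    mode_distance: float = 35.0
    reward_min: float = 0.0
    reward_max: float = 100.0
    run_shift_max: float = 14.8
    anchor_mid_mean: float = 50.0
    anchor_jitter: float = 0.0
    value_init: float = 50.0
    uncertainty_init: float = 0.0
    pe_max: float = 60.0
    estimation_min_gap: int = 10
    estimation_first_allowed: int = 11
    n_rigged_min: int = 4
    n_rigged_max: int = 5
    bound_margin_sds: float = 3.0

    @property
    def neighbor_distance(self) -> float:
        """Distance between neighboring bandit means (half the low-high gap)."""
        return self.low_high_distance / 2.0

    @property
    def reward_bounds(self) -> tuple[float, float]:
        return (self.reward_min, self.reward_max)

    def validate(self) -> None:
        if self.n_free + self.n_guided != self.n_choice_trials_per_run:
            raise ValueError("n_free + n_guided must equal n_choice_trials_per_run")
        if not 0.0 < self.mix_weight_low_mode < 1.0:
            raise ValueError("mix_weight_low_mode must lie in (0, 1)")
        if min(self.low_high_distance, self.mode_distance, self.gaussian_sd) <= 0:
            raise ValueError("distances and SD must be positive")
        if not self.reward_min <= self.value_init <= self.reward_max:
            raise ValueError("value_init must lie within the reward bounds")
        if self.n_rigged_min > self.n_rigged_max:
            raise ValueError("n_rigged_min must not exceed n_rigged_max")


@dataclass
class OptimizerConfig:
    """Budget for the outer DIRECT-L search over learning parameters.

    The search stops after ``max_evaluations`` objective calls or when the
    best hyper-rectangle shrinks below ``len_tol`` (relative side length),
    whichever comes first.
    """

    max_evaluations: int = 2000
    len_tol: float = 1e-4
    ridge: float = 1e-6  # tiny L2 penalty on betas; guards against separation

    def validate(self) -> None:
        if self.max_evaluations < 1:
            raise ValueError("max_evaluations must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


def _to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def save_config(cfg: TaskConfig, path: str | Path) -> None:
    path = Path(path)
    data = _to_dict(cfg)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_config(path: str | Path) -> TaskConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    cfg = TaskConfig(**data)
    cfg.validate()
    return cfg
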