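"""Trial-by-trial value and uncertainty updating for the candidate models.

All six candidate models share the delta-rule backbone

    V[k] <- V[k] + rate * PE,    PE = R - V[k],

and differ in how the rate is set and whether a per-bandit uncertainty
(associability) trace enters the choice model:

* ``RW``          — constant rate alpha.
* ``Valence``     — alpha_pos for PE >= 0, alpha_neg for PE < 0.
* ``Uncertainty`` — constant alpha; uncertainty U[k] <- (1-pi) U[k] + pi |PE|
  tracked for the sampled bandit and fed into choice.
* ``Surprise``    — rate is a logistic function of the scaled unsigned PE,
  interpolating between a lower bound ``l`` (PE = 0) and an upper bound
  ``u`` (maximal PE) with slope ``s``.
* ``UncValence`` / ``UncSurprise`` — the valence / surprise update combined
  with the uncertainty trace in choice.

Values are initialized to 50 and uncertainties to 0 at the start of each
run; only outcome-bearing trials (free choices and correctly executed
guided choices) trigger updates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TaskConfig
from .task_design import ROLES

UNIT = (0.0, 1.0)
SLOPE_BOUNDS = (1.0, 7.0)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    learning_param_names: tuple[str, ...]
    learning_param_bounds: tuple[tuple[float, float], ...]
    uses_uncertainty_in_choice: bool

    @property
    def n_learning_params(self) -> int:
        return len(self.learning_param_names)

    @property
    def n_betas(self) -> int:
        return 5 if self.uses_uncertainty_in_choice else 3

    @property
    def k_total(self) -> int:
        """Number of fitted quantities (learning parameters + betas)."""
        return self.n_learning_params + self.n_betas


MODEL_SPECS: dict[str, ModelSpec] = {
    "RW": ModelSpec("RW", ("alpha",), (UNIT,), False),
    "Valence": ModelSpec("Valence", ("alpha_pos", "alpha_neg"), (UNIT, UNIT), False),
    "Uncertainty": ModelSpec("Uncertainty", ("alpha", "pi"), (UNIT, UNIT), True),
    "Surprise": ModelSpec("Surprise", ("l", "u", "s"), (UNIT, UNIT, SLOPE_BOUNDS), False),
    "UncValence": ModelSpec(
        "UncValence", ("alpha_pos", "alpha_neg", "pi"), (UNIT, UNIT, UNIT), True
    ),
    "UncSurprise": ModelSpec(
        "UncSurprise", ("l", "u", "s", "pi"), (UNIT, UNIT, SLOPE_BOUNDS, UNIT), True
    ),
}

MODEL_NAMES = tuple(MODEL_SPECS)


def get_spec(name: str) -> ModelSpec:
    try:
        return MODEL_SPECS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}") from None


@dataclass
class ModelParams:
    """Learning parameters of one model, keyed by the spec's names."""

    values: dict[str, float]

    @classmethod
    def from_vector(cls, spec: ModelSpec, vec) -> "ModelParams":
        if len(vec) != spec.n_learning_params:
            raise ValueError("parameter vector length mismatch")
        return cls(dict(zip(spec.learning_param_names, (float(v) for v in vec))))

    def vector(self, spec: ModelSpec) -> np.ndarray:
        return np.array([self.values[n] for n in spec.learning_param_names])

    def check_bounds(self, spec: ModelSpec) -> None:
        for name, (lo, hi) in zip(spec.learning_param_names, spec.learning_param_bounds):
            v = self.values[name]
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def scaled_abs_pe(pe: float, pe_max: float = 60.0) -> float:
    """Scaled unsigned prediction error in [0, 1].

    The raw transform f(x) = 2 / (1 + exp(-0.1 x)) - 1 maps |PE| to (0, 1);
    dividing by f(pe_max) rescales so that the maximal possible prediction
    error maps to exactly 1.  |PE| is capped at ``pe_max`` first.
    """
    x = min(abs(pe), pe_max)

    def f(v: float) -> float:
        return 2.0 / (1.0 + math.exp(-0.1 * v)) - 1.0

    return f(x) / f(pe_max)


def surprise_learning_rate(pe_hat: float, l: float, u: float, s: float) -> float:
    """Surprise-dependent learning rate.

    alpha* = l + (u - l) * 2 / (1 + pe_hat**(-s)); equals ``l`` at
    pe_hat = 0 (the limit is taken explicitly) and ``u`` at pe_hat = 1.
    Increasing in surprise when u > l, decreasing when u < l.
    """
    if not 0.0 <= pe_hat <= 1.0:
        raise ValueError("pe_hat must lie in [0, 1]")
    if pe_hat == 0.0:
        return l
    return l + (u - l) * 2.0 / (1.0 + pe_hat ** (-s))


def learning_rate_for(spec: ModelSpec, params: ModelParams, pe: float, pe_max: float) -> float:
    """Rate applied to a given signed prediction error under a model."""
    name = spec.name
    if name in ("RW", "Uncertainty"):
        return params["alpha"]
    if name in ("Valence", "UncValence"):
        return params["alpha_pos"] if pe >= 0 else params["alpha_neg"]
    if name in ("Surprise", "UncSurprise"):
        return surprise_learning_rate(
            scaled_abs_pe(pe, pe_max), params["l"], params["u"], params["s"]
        )
    raise ValueError(f"unknown model {name!r}")


@dataclass
class BanditState:
    """Latent per-bandit state carried across trials within a run."""

    V: dict[str, float]
    U: dict[str, float]
    n_outcomes_seen: dict[str, int]

    @classmethod
    def fresh(cls, config: TaskConfig) -> "BanditState":
        return cls(
            V={r: config.value_init for r in ROLES},
            U={r: config.uncertainty_init for r in ROLES},
            n_outcomes_seen={r: 0 for r in ROLES},
        )


def update_value(
    state: BanditState,
    bandit: str,
    reward: float,
    spec: ModelSpec,
    params: ModelParams,
    pe_max: float = 60.0,
) -> float:
    """Delta-rule update of the chosen bandit's value; returns the rate used."""
    pe = reward - state.V[bandit]
    rate = learning_rate_for(spec, params, pe, pe_max)
    state.V[bandit] += rate * pe
    state.n_outcomes_seen[bandit] += 1
    return rate


def update_uncertainty(state: BanditState, bandit: str, pe: float, pi: float) -> None:
    """Recency-weighted unsigned-PE trace for the sampled bandit only."""
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    state.U[bandit] = (1.0 - pi) * state.U[bandit] + pi * abs(pe)


@dataclass
class Trajectory:
    """Latent-state record aligned with the trial table of a dataset.

    ``pre_V`` / ``pre_U`` hold, for every trial row (including estimation
    rows), the state *before* that trial's update — this is what the choice
    model sees.  Update fields are NaN on rows without an outcome.
    """

    trial_rows: pd.Index
    pre_V: pd.DataFrame  # columns low/mid/high
    pre_U: pd.DataFrame
    chosen: pd.Series
    reward: pd.Series
    pe: pd.Series
    pe_hat: pd.Series
    rate: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat(
            [
                self.pre_V.add_prefix("V_"),
                self.pre_U.add_prefix("U_"),
            ],
            axis=1,
        )
        out["chosen_bandit"] = self.chosen
        out["reward"] = self.reward
        out["pe"] = self.pe
        out["pe_hat"] = self.pe_hat
        out["learning_rate"] = self.rate
        return out


def run_model(
    trials: pd.DataFrame,
    spec: ModelSpec,
    params: ModelParams,
    config: TaskConfig | None = None,
) -> Trajectory:
    """Replay a participant's trial table under a model.

    ``trials`` must contain columns run, trial_type, chosen_bandit and
    reward (NaN where no outcome was shown).  Values and uncertainties are
    reset at every run boundary; updates happen on outcome-bearing rows
    only (free choices and complied guided choices).  Estimation rows and
    guided errors leave the state untouched.
    """
    config = config or TaskConfig()
    params.check_bounds(spec)
    needed = {"run", "trial_type", "chosen_bandit", "reward"}
    if not needed.issubset(trials.columns):
        raise ValueError(f"trial table missing columns {needed - set(trials.columns)}")

    n = len(trials)
    pre_V = np.empty((n, 3))
    pre_U = np.empty((n, 3))
    pe_arr = np.full(n, np.nan)
    pe_hat_arr = np.full(n, np.nan)
    rate_arr = np.full(n, np.nan)

    runs = trials["run"].to_numpy()
    types = trials["trial_type"].to_numpy()
    chosen = trials["chosen_bandit"].to_numpy(dtype=object)
    rewards = trials["reward"].to_numpy(dtype=float)

    tracks_u = spec.uses_uncertainty_in_choice
    pi = params.values.get("pi", 0.0)

    state = None
    current_run = None
    role_idx = {r: i for i, r in enumerate(ROLES)}
    for i in range(n):
        if runs[i] != current_run:
            current_run = runs[i]
            state = BanditState.fresh(config)
        pre_V[i] = [state.V[r] for r in ROLES]
        pre_U[i] = [state.U[r] for r in ROLES]
        if types[i] == "estimation":
            continue
        r = rewards[i]
        if not np.isfinite(r):  # guided error or timeout: no outcome shown
            continue
        k = chosen[i]
        if k not in role_idx:
            raise ValueError(f"malformed chosen_bandit {k!r} at row {i}")
        pe = r - state.V[k]
        rate = update_value(state, k, r, spec, params, config.pe_max)
        if tracks_u:
            update_uncertainty(state, k, pe, pi)
        pe_arr[i] = pe
        pe_hat_arr[i] = scaled_abs_pe(pe, config.pe_max)
        rate_arr[i] = rate

    idx = trials.index
    return Trajectory(
        trial_rows=idx,
        pre_V=pd.DataFrame(pre_V, index=idx, columns=list(ROLES)),
        pre_U=pd.DataFrame(pre_U, index=idx, columns=list(ROLES)),
        chosen=pd.Series(chosen, index=idx),
        reward=pd.Series(rewards, index=idx),
        pe=pd.Series(pe_arr, index=idx),
        pe_hat=pd.Series(pe_hat_arr, index=idx),
        rate=pd.Series(rate_arr, index=idx),
    )
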