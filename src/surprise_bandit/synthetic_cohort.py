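"""Synthetic cohorts of task participants.

Because no participant data accompany the study design, every analysis in
this package runs on simulated cohorts whose statistical structure matches
the task: 51 younger and 51 older adults, two runs of 240 choice trials
plus 16 estimation probes each, choices generated by one of the candidate
learning models plus logistic choice noise, and estimation responses as
noisy readouts of the agent's current values.

The age-group manipulation is carried by the surprise-sensitivity
parameters: older agents draw a larger ``u - l`` gap by default, so their
learning rate rises more steeply after surprising outcomes.  All other
defaults aim at a mid-performing human participant: moderately decisive
choice betas (|b1| = b2 = 0.15 per point of value), near-perfect guided
compliance (0.98), and slider noise of 5 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

import pandas as pd

from .choice_inference import ChoiceCoefficients, choice_probability
from .config import TaskConfig
from .datasets import ParticipantDataset, TRIAL_COLUMNS
from .learning_models import (
    BanditState,
    ModelParams,
    ModelSpec,
    get_spec,
    learning_rate_for,
)
from .task_design import (
    PAIR_MEMBERS,
    ROLES,
    build_run_schedule,
    make_bandit_set,
    sample_reward,
)


def default_param_sampler(
    spec: ModelSpec, group: str, older_u_shift: float = 0.2
) -> Callable[[np.random.Generator], ModelParams]:
    """Group-conditional parameter distributions for cohort generation.

    Learning rates are uniform over a mid range (0.1-0.5) rather than the
    full box, matching the magnitudes typical of human bandit learning.
    For surprise models the older group's ``u - l`` gap is shifted upward
    by ``older_u_shift`` so surprise boosts learning more in that group.
    """

    def sample(rng: np.random.Generator) -> ModelParams:
        vals: dict[str, float] = {}
        for name in spec.learning_param_names:
            if name == "s":
                vals["s"] = float(rng.uniform(2.0, 5.0))
            elif name == "pi":
                vals["pi"] = float(rng.uniform(0.2, 0.8))
            elif name == "l":
                vals["l"] = float(rng.uniform(0.1, 0.3))
            elif name == "u":
                delta_lo, delta_hi = (0.0, 0.25)
                if group == "older":
                    delta_lo += older_u_shift
                    delta_hi += older_u_shift
                vals["u"] = float(np.clip(vals["l"] + rng.uniform(delta_lo, delta_hi), 0.0, 1.0))
            else:  # alpha, alpha_pos, alpha_neg
                vals[name] = float(rng.uniform(0.1, 0.5))
        return ModelParams(vals)

    return sample


@dataclass
class CohortSpec:
    """Everything needed to generate a cohort, short of the seed."""

    n_younger: int = 51
    n_older: int = 51
    generating_model: str = "Surprise"
    older_u_shift: float = 0.2
    beta0: float = 0.0
    beta_left: float = -0.15
    beta_right: float = 0.15
    beta_u_left: float = 0.05
    beta_u_right: float = -0.05
    guided_compliance: float = 0.98
    estimation_noise_sd: float = 5.0
    range_readout_gain: float = 2.0
    range_noise_sd: float = 5.0
    param_sampler: Callable[[ModelSpec, str], Callable] | None = None

    def validate(self) -> None:
        if not 0.0 <= self.guided_compliance <= 1.0:
            raise ValueError("guided_compliance must lie in [0, 1]")
        get_spec(self.generating_model)

    def coefficients_for(self, spec: ModelSpec) -> ChoiceCoefficients:
        if spec.uses_uncertainty_in_choice:
            return ChoiceCoefficients(
                self.beta0, self.beta_left, self.beta_right,
                self.beta_u_left, self.beta_u_right,
            )
        return ChoiceCoefficients(self.beta0, self.beta_left, self.beta_right)

    def sampler_for(self, spec: ModelSpec, group: str):
        if self.param_sampler is not None:
            return self.param_sampler(spec, group)
        return default_param_sampler(spec, group, self.older_u_shift)


def generate_participant(
    participant_id: str,
    group: str,
    spec: ModelSpec,
    params: ModelParams,
    coeffs: ChoiceCoefficients,
    config: TaskConfig,
    rng: np.random.Generator,
    guided_compliance: float = 0.98,
    estimation_noise_sd: float = 5.0,
    range_readout_gain: float = 2.0,
    range_noise_sd: float = 5.0,
) -> ParticipantDataset:
    """Simulate one agent through both runs of the task.

    Free choices are Bernoulli draws from the logistic choice model on the
    agent's current latent state; guided choices comply with the frame at
    the given rate (errors reveal no outcome and trigger no update);
    estimation responses are the current values plus clipped Gaussian
    noise, and range responses a noisy linear readout of the uncertainty
    trace (reported for completeness; no analysis here consumes them).
    """
    params.check_bounds(spec)
    rows = []
    bandit_sets: dict[int, dict] = {}
    for run in range(1, config.n_runs + 1):
        bandits = make_bandit_set(config, run, rng)
        bandit_sets[run] = bandits
        schedule = build_run_schedule(config, rng, run_index=run)
        state = BanditState.fresh(config)
        track_u = spec.uses_uncertainty_in_choice
        pi = params.values.get("pi", 0.0)
        for i, t in enumerate(schedule.trials):
            row = {c: np.nan for c in TRIAL_COLUMNS}
            row.update(run=run, trial_index=i, trial_type=t.trial_type,
                       rigged_low_mode=bool(t.rigged_low_mode), guided_error=False)
            if t.trial_type == "estimation":
                for role in ROLES:
                    est = state.V[role] + rng.normal(0.0, estimation_noise_sd)
                    row[f"est_{role}"] = float(np.clip(est, 0.0, 100.0))
                    rg = range_readout_gain * state.U[role] + rng.normal(0.0, range_noise_sd)
                    row[f"range_{role}"] = float(np.clip(rg, -50.0, 50.0))
                rows.append(row)
                continue
            row.update(pair=t.pair, left_bandit=t.left, right_bandit=t.right,
                       guided_target=t.guided_target)
            if t.trial_type == "free":
                p_right = choice_probability(
                    state.V[t.left], state.V[t.right],
                    coeffs,
                    u_left=state.U[t.left] if track_u else None,
                    u_right=state.U[t.right] if track_u else None,
                )
                chosen = t.right if rng.random() < p_right else t.left
            else:  # guided
                if rng.random() < guided_compliance:
                    chosen = t.guided_target
                else:
                    chosen = None  # wrong pick: no outcome shown
            if chosen is None:
                other = t.left if t.left != t.guided_target else t.right
                row.update(chosen_bandit=other,
                           chosen_side="left" if other == t.left else "right",
                           guided_error=True)
                rows.append(row)
                continue
            reward = sample_reward(
                bandits[chosen], rng,
                forced_low_mode=(t.rigged_low_mode and chosen == "mid"),
            )
            pe = reward - state.V[chosen]
            rate = learning_rate_for(spec, params, pe, config.pe_max)
            state.V[chosen] += rate * pe
            state.n_outcomes_seen[chosen] += 1
            if track_u:
                state.U[chosen] = (1.0 - pi) * state.U[chosen] + pi * abs(pe)
            offered = PAIR_MEMBERS[t.pair]
            better = max(offered, key=lambda r: bandits[r].mean_total)
            row.update(
                chosen_bandit=chosen,
                chosen_side="left" if chosen == t.left else "right",
                reward=float(reward),
                correct=bool(chosen == better),
            )
            rows.append(row)
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return ParticipantDataset(
        participant_id=participant_id,
        group=group,
        trials=trials,
        bandits=bandit_sets,
    )


def generate_cohort(
    spec: CohortSpec,
    config: TaskConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[ParticipantDataset], dict]:
    """Generate a full cohort plus a ground-truth ledger for recovery scoring."""
    spec.validate()
    config = config or TaskConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    model_spec = get_spec(spec.generating_model)
    coeffs = spec.coefficients_for(model_spec)
    cohort: list[ParticipantDataset] = []
    ledger: dict = {"participants": {}}
    counts = {"younger": spec.n_younger, "older": spec.n_older}
    idx = 0
    for group in ("younger", "older"):
        sampler = spec.sampler_for(model_spec, group)
        for _ in range(counts[group]):
            idx += 1
            pid = f"sub-{idx:03d}"
            params = sampler(rng)
            ds = generate_participant(
                pid, group, model_spec, params, coeffs, config, rng,
                guided_compliance=spec.guided_compliance,
                estimation_noise_sd=spec.estimation_noise_sd,
                range_readout_gain=spec.range_readout_gain,
                range_noise_sd=spec.range_noise_sd,
            )
            cohort.append(ds)
            ledger["participants"][pid] = {
                "group": group,
                "model": model_spec.name,
                "params": dict(params.values),
                "betas": list(coeffs.vector()),
            }
    return cohort, ledger
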