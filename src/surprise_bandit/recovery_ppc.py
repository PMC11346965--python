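"""Validation of the fitting machinery: parameter/model recovery and PPC.

Parameter recovery simulates agents with known parameters, refits the same
model and reports generating-vs-recovered correlations.  Model recovery
simulates agents from each candidate model, fits all candidates and tallies
AICc winners into a confusion matrix — diagonal dominance is *not* expected
everywhere, because the Rescorla-Wagner model is a special case of every
other candidate and absorbs weakly-identified data.  The posterior
predictive check simulates one synthetic dataset per participant from the
fitted parameters on fresh matched schedules and reruns the surprise
pre/post analysis on the simulated behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .behavior_analysis import cohort_prepost_summary, surprise_prepost
from .choice_inference import ChoiceCoefficients, FitResult, fit_model
from .config import OptimizerConfig, TaskConfig
from .learning_models import ModelParams, ModelSpec, get_spec
from .model_comparison import build_comparison
from .synthetic_cohort import generate_participant

DECISIVE_BETAS = ChoiceCoefficients(0.0, -0.15, 0.15)


def _betas_for(spec: ModelSpec, betas: ChoiceCoefficients) -> ChoiceCoefficients:
    if spec.uses_uncertainty_in_choice and betas.b3 is None:
        return ChoiceCoefficients(betas.b0, betas.b1, betas.b2, 0.05, -0.05)
    return betas


def uniform_param_sampler(spec: ModelSpec) -> Callable[[np.random.Generator], ModelParams]:
    """Uniform draws over each learning parameter's declared box."""

    def sample(rng: np.random.Generator) -> ModelParams:
        vals = {
            name: float(rng.uniform(lo, hi))
            for name, (lo, hi) in zip(spec.learning_param_names, spec.learning_param_bounds)
        }
        return ModelParams(vals)

    return sample


@dataclass
class RecoveryReport:
    model: str
    generating: pd.DataFrame  # one row per agent, columns = parameter names
    recovered: pd.DataFrame
    correlations: dict[str, float]
    flags: list[str] = field(default_factory=list)


def parameter_recovery(
    spec: ModelSpec | str,
    n_agents: int,
    rng: np.random.Generator | int | None = None,
    config: TaskConfig | None = None,
    optimizer: OptimizerConfig | None = None,
    param_sampler: Callable | None = None,
    betas: ChoiceCoefficients = DECISIVE_BETAS,
) -> RecoveryReport:
    """Simulate-and-refit check of one model's parameter identifiability."""
    spec = get_spec(spec) if isinstance(spec, str) else spec
    config = config or TaskConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sampler = param_sampler or uniform_param_sampler(spec)
    coeffs = _betas_for(spec, betas)
    gen_rows, rec_rows, flags = [], [], []
    for a in range(n_agents):
        params = sampler(rng)
        ds = generate_participant(
            f"agent-{a:03d}", "younger", spec, params, coeffs, config, rng
        )
        fit = fit_model(ds.trials, spec, config=config, optimizer=optimizer)
        gen_rows.append(dict(params.values))
        rec_rows.append(dict(fit.params.values))
    generating = pd.DataFrame(gen_rows)
    recovered = pd.DataFrame(rec_rows)
    correlations = {}
    for name in spec.learning_param_names:
        g, r = generating[name], recovered[name]
        if g.std() == 0 or r.std() == 0:
            correlations[name] = float("nan")
            flags.append(f"degenerate variation in {name}; correlation undefined")
        else:
            correlations[name] = float(np.corrcoef(g, r)[0, 1])
    return RecoveryReport(spec.name, generating, recovered, correlations, flags)


def model_recovery(
    generating_specs: list[ModelSpec | str],
    n_agents_per_model: int,
    fit_specs: list[ModelSpec | str] | None = None,
    rng: np.random.Generator | int | None = None,
    config: TaskConfig | None = None,
    optimizer: OptimizerConfig | None = None,
    param_samplers: dict[str, Callable] | None = None,
    betas: ChoiceCoefficients = DECISIVE_BETAS,
) -> pd.DataFrame:
    """Confusion matrix: generating model (rows) x AICc-winning model (cols)."""
    gen = [get_spec(s) if isinstance(s, str) else s for s in generating_specs]
    if len(gen) < 2:
        raise ValueError("need at least two generating models")
    fit_list = [get_spec(s) if isinstance(s, str) else s for s in (fit_specs or generating_specs)]
    config = config or TaskConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    confusion = pd.DataFrame(
        0, index=[s.name for s in gen], columns=[s.name for s in fit_list]
    )
    for gspec in gen:
        sampler = (param_samplers or {}).get(gspec.name) or uniform_param_sampler(gspec)
        coeffs = _betas_for(gspec, betas)
        for a in range(n_agents_per_model):
            params = sampler(rng)
            ds = generate_participant(
                f"{gspec.name}-{a:03d}", "younger", gspec, params, coeffs, config, rng
            )
            fits = {
                fspec.name: fit_model(ds.trials, fspec, config=config, optimizer=optimizer)
                for fspec in fit_list
            }
            table = build_comparison({ds.participant_id: fits})
            confusion.loc[gspec.name, table.winners.iloc[0]] += 1
    return confusion


def posterior_predictive_check(
    fits: dict[str, dict[str, FitResult]],
    groups: dict[str, str],
    models: list[str],
    rng: np.random.Generator | int | None = None,
    config: TaskConfig | None = None,
    band: str = "below20",
    n_reps: int = 1,
) -> pd.DataFrame:
    """Rerun the surprise pre/post analysis on model-simulated behavior.

    For every participant and checked model, simulate ``n_reps`` synthetic
    datasets from the fitted parameters and betas on fresh schedules, then
    compute pre/post mid-choice proportions around surprising outcomes.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    config = config or TaskConfig()
    rows = []
    for pid, model_fits in sorted(fits.items()):
        for model in models:
            if model not in model_fits:
                raise ValueError(f"missing {model} fit for {pid}")
            fr = model_fits[model]
            spec = get_spec(model)
            for rep in range(n_reps):
                ds = generate_participant(
                    f"{pid}-ppc", groups.get(pid, "younger"), spec,
                    fr.params, fr.coefficients, config, rng,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pre, post = surprise_prepost(ds, band)
                rows.append(
                    {
                        "participant": pid,
                        "group": groups.get(pid, "younger"),
                        "model": model,
                        "rep": rep,
                        "pre": pre,
                        "post": post,
                    }
                )
    return pd.DataFrame(rows)
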