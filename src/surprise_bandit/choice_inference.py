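"""Choice probabilities and nested maximum-likelihood model fitting.

Choices are modeled with a logistic regression on the latent values (and,
for uncertainty-aware models, the associability traces) of the two offered
bandits:

    p(right) = sigma(b0 + b1 * V_left + b2 * V_right [+ b3 * U_left + b4 * U_right])

Fitting follows a nested (coordinate-descent-like) scheme: a deterministic
global DIRECT-L search over the learning parameters in their boxes, where
every outer evaluation replays the learning model over the participant's
trials and fits the betas by maximum likelihood in an inner loop.  The
likelihood uses only free choices in low-mid comparisons, excluding trials
where either offered bandit has fewer than three previously observed
outcomes in that run (values start at the fixed prior of 50, so early
unsigned prediction errors reflect initialization rather than surprise).
Model fits are compared through the small-sample corrected AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import direct

from .config import OptimizerConfig, TaskConfig
from .learning_models import (
    ModelParams,
    ModelSpec,
    learning_rate_for,
    scaled_abs_pe,
)
from .task_design import ROLES

_ROLE_IDX = {r: i for i, r in enumerate(ROLES)}


@dataclass
class ChoiceCoefficients:
    b0: float
    b1: float  # left value
    b2: float  # right value
    b3: float | None = None  # left uncertainty
    b4: float | None = None  # right uncertainty

    def vector(self) -> np.ndarray:
        vals = [self.b0, self.b1, self.b2]
        if self.b3 is not None:
            vals += [self.b3, self.b4]
        return np.array(vals)

    @classmethod
    def from_vector(cls, vec) -> "ChoiceCoefficients":
        vec = list(map(float, vec))
        if len(vec) == 3:
            return cls(*vec)
        if len(vec) == 5:
            return cls(*vec)
        raise ValueError("beta vector must have length 3 or 5")


@dataclass
class FitResult:
    model: str
    params: ModelParams
    coefficients: ChoiceCoefficients
    neg_log_likelihood: float
    n_likelihood_trials: int
    aicc: float
    n_evaluations: int = 0
    converged: bool = True
    separation_flag: bool = False


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def choice_probability(
    v_left: float,
    v_right: float,
    coeffs: ChoiceCoefficients,
    u_left: float | None = None,
    u_right: float | None = None,
) -> float:
    """Probability of choosing the right-hand option."""
    z = coeffs.b0 + coeffs.b1 * v_left + coeffs.b2 * v_right
    if coeffs.b3 is not None:
        if u_left is None or u_right is None:
            raise ValueError("uncertainty-aware coefficients need u_left/u_right")
        z += coeffs.b3 * u_left + coeffs.b4 * u_right
    return float(logistic(z))


def likelihood_trial_filter(trials: pd.DataFrame) -> pd.Series:
    """Boolean mask of trials entering the likelihood.

    Keeps free low-mid choices in which both offered bandits have already
    produced at least three observed outcomes earlier in the same run
    (outcomes from any trial type count, because guided trials also reveal
    rewards).
    """
    has_outcome = trials["reward"].notna()
    mask = np.zeros(len(trials), dtype=bool)
    counts_template = {r: 0 for r in ROLES}
    current_run = None
    counts = dict(counts_template)
    tt = trials["trial_type"].to_numpy()
    pair = trials["pair"].to_numpy(dtype=object)
    left = trials["left_bandit"].to_numpy(dtype=object)
    right = trials["right_bandit"].to_numpy(dtype=object)
    chosen = trials["chosen_bandit"].to_numpy(dtype=object)
    runs = trials["run"].to_numpy()
    outc = has_outcome.to_numpy()
    for i in range(len(trials)):
        if runs[i] != current_run:
            current_run = runs[i]
            counts = dict(counts_template)
        if tt[i] == "free" and pair[i] == "low-mid":
            if counts[left[i]] >= 3 and counts[right[i]] >= 3:
                mask[i] = True
        if outc[i]:
            counts[chosen[i]] += 1
    return pd.Series(mask, index=trials.index)


def aicc(neg_ll: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike Information Criterion."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined for n <= k + 1")
    return 2.0 * neg_ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _logistic_negll(beta: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float) -> float:
    z = X @ beta
    # log(1 + exp(z)) - y*z, computed stably
    ll = np.logaddexp(0.0, z) - y * z
    return float(ll.sum() + 0.5 * ridge * beta @ beta)


def fit_logistic_mle(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-6, max_iter: int = 100
) -> tuple[np.ndarray, float, bool]:
    """Ridge-stabilized Newton (IRLS) logistic fit.

    Returns (beta, unpenalized negLL, separation_flag).  The tiny ridge
    keeps the Hessian positive definite and the optimum finite under
    complete separation; the flag marks fits whose coefficients blew up.
    """
    n, p = X.shape
    beta = np.zeros(p)
    obj = _logistic_negll(beta, X, y, ridge)
    for _ in range(max_iter):
        z = X @ beta
        mu = logistic(z)
        grad = X.T @ (mu - y) + ridge * beta
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped Newton: halve until the penalized objective decreases
        t = 1.0
        for _ in range(40):
            new = beta - t * step
            new_obj = _logistic_negll(new, X, y, ridge)
            if new_obj <= obj + 1e-12:
                break
            t *= 0.5
        if abs(obj - new_obj) < 1e-10 and np.max(np.abs(t * step)) < 1e-8:
            beta, obj = new, new_obj
            break
        beta, obj = new, new_obj
    z = X @ beta
    raw = float((np.logaddexp(0.0, z) - y * z).sum())
    separated = bool(np.max(np.abs(beta)) > 50.0)
    return beta, raw, separated


class TrialReplayer:
    """Pre-compiled replay of one participant's trials for fast fitting.

    Extracts the trial arrays once so the outer optimizer's objective can
    rerun the learning model and rebuild the logistic design matrix without
    touching pandas.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        config: TaskConfig | None = None,
        mask: pd.Series | None = None,
    ):
        self.config = config or TaskConfig()
        if mask is None:
            mask = likelihood_trial_filter(trials)
        self.mask = mask.to_numpy()
        if self.mask.sum() == 0:
            raise ValueError("no trials pass the likelihood filter")
        self.runs = trials["run"].to_numpy()
        rewards = trials["reward"].to_numpy(dtype=float)
        self.rewards = rewards
        self.has_outcome = np.isfinite(rewards) & (
            trials["trial_type"].to_numpy() != "estimation"
        )
        chosen = trials["chosen_bandit"].to_numpy(dtype=object)
        self.chosen_idx = np.array(
            [_ROLE_IDX.get(c, -1) for c in chosen], dtype=np.int64
        )
        left = trials["left_bandit"].to_numpy(dtype=object)
        right = trials["right_bandit"].to_numpy(dtype=object)
        self.left_idx = np.array([_ROLE_IDX.get(c, -1) for c in left], dtype=np.int64)
        self.right_idx = np.array([_ROLE_IDX.get(c, -1) for c in right], dtype=np.int64)
        self.chose_right = (chosen == right).astype(float)
        self.n_trials = len(trials)

    @property
    def n_likelihood_trials(self) -> int:
        return int(self.mask.sum())

    def design_matrix(self, spec: ModelSpec, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
        """Replay the model; return (X, y) for the filtered trials."""
        cfg = self.config
        v_init, u_init, pe_max = cfg.value_init, cfg.uncertainty_init, cfg.pe_max
        pi = params.values.get("pi", 0.0)
        track_u = spec.uses_uncertainty_in_choice
        p = 5 if track_u else 3
        X = np.empty((self.n_likelihood_trials, p))
        y = np.empty(self.n_likelihood_trials)
        V = [v_init] * 3
        U = [u_init] * 3
        current_run = None
        row = 0
        for i in range(self.n_trials):
            if self.runs[i] != current_run:
                current_run = self.runs[i]
                V = [v_init] * 3
                U = [u_init] * 3
            if self.mask[i]:
                li, ri = self.left_idx[i], self.right_idx[i]
                X[row, 0] = 1.0
                X[row, 1] = V[li]
                X[row, 2] = V[ri]
                if track_u:
                    X[row, 3] = U[li]
                    X[row, 4] = U[ri]
                y[row] = self.chose_right[i]
                row += 1
            if self.has_outcome[i]:
                k = self.chosen_idx[i]
                pe = self.rewards[i] - V[k]
                rate = learning_rate_for(spec, params, pe, pe_max)
                V[k] += rate * pe
                if track_u:
                    U[k] = (1.0 - pi) * U[k] + pi * abs(pe)
        return X, y


def fit_betas_given_params(
    replayer: TrialReplayer,
    spec: ModelSpec,
    params: ModelParams,
    ridge: float = 1e-6,
) -> tuple[ChoiceCoefficients, float, bool]:
    """Inner loop: maximum-likelihood betas for fixed learning parameters."""
    X, y = replayer.design_matrix(spec, params)
    beta, neg_ll, separated = fit_logistic_mle(X, y, ridge=ridge)
    return ChoiceCoefficients.from_vector(beta), neg_ll, separated


def fit_model(
    trials: pd.DataFrame,
    spec: ModelSpec,
    config: TaskConfig | None = None,
    optimizer: OptimizerConfig | None = None,
) -> FitResult:
    """Nested fit of one model to one participant's choices.

    Outer: deterministic DIRECT-L over the learning-parameter box.  Inner:
    ridge-stabilized logistic MLE for the betas.  Refitting with identical
    inputs reproduces the result exactly.
    """
    optimizer = optimizer or OptimizerConfig()
    optimizer.validate()
    replayer = TrialReplayer(trials, config=config)
    n = replayer.n_likelihood_trials
    k = spec.k_total
    if n <= k + 1:
        raise ValueError(f"too few likelihood trials ({n}) for model {spec.name}")

    nfev = 0

    def objective(theta) -> float:
        nonlocal nfev
        nfev += 1
        params = ModelParams.from_vector(spec, theta)
        X, y = replayer.design_matrix(spec, params)
        _, neg_ll, _ = fit_logistic_mle(X, y, ridge=optimizer.ridge)
        return neg_ll

    res = direct(
        objective,
        bounds=list(spec.learning_param_bounds),
        maxfun=optimizer.max_evaluations,
        maxiter=10000,
        len_tol=optimizer.len_tol,
        locally_biased=True,
    )
    best = ModelParams.from_vector(spec, res.x)
    coeffs, neg_ll, separated = fit_betas_given_params(
        replayer, spec, best, ridge=optimizer.ridge
    )
    return FitResult(
        model=spec.name,
        params=best,
        coefficients=coeffs,
        neg_log_likelihood=neg_ll,
        n_likelihood_trials=n,
        aicc=aicc(neg_ll, k, n),
        n_evaluations=nfev,
        converged=bool(res.success),
        separation_flag=separated,
    )
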