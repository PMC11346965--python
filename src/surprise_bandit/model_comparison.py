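"""Group-level model comparison: AICc tables and random-effects BMS.

Per-participant AICc scores are collected into a comparison table
(deltas relative to the Rescorla-Wagner baseline, per-participant winners)
and fed into random-effects Bayesian model selection.  The population is
modeled as a Dirichlet distribution over model frequencies; variational
inference yields the posterior Dirichlet weights, Monte-Carlo sampling the
exceedance probabilities (EP), and a free-energy comparison against the
equal-frequency null the Bayes omnibus risk (BOR).  Protected exceedance
probabilities follow as PXP = (1 - BOR) * EP + BOR / K.

Log model evidence is approximated as -AICc/2 by default (-AIC/2 is
available through the ``evidence`` switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .choice_inference import FitResult
from .learning_models import MODEL_SPECS


@dataclass
class ComparisonTable:
    aicc: pd.DataFrame  # participants x models
    delta_vs_rw: pd.DataFrame
    winners: pd.Series  # participant -> model name
    groups: pd.Series | None = None  # participant -> group label

    def winner_counts(self, group: str | None = None) -> pd.Series:
        winners = self.winners
        if group is not None:
            if self.groups is None:
                raise ValueError("no group labels available")
            winners = winners[self.groups == group]
        return winners.value_counts().reindex(self.aicc.columns, fill_value=0)


def _tie_break_winner(row: pd.Series) -> str:
    """Row-wise argmin AICc; ties go to the model with fewer parameters."""
    best = row.min()
    tied = [m for m in row.index if row[m] <= best + 1e-12]
    return min(tied, key=lambda m: (MODEL_SPECS[m].k_total if m in MODEL_SPECS else 99))


def build_comparison(
    fits: dict[str, dict[str, FitResult]],
    groups: dict[str, str] | None = None,
    baseline: str = "RW",
) -> ComparisonTable:
    """Assemble the participants x models AICc matrix and winners.

    ``fits`` maps participant id -> model name -> FitResult and must be
    complete (every participant fitted under every model).
    """
    participants = sorted(fits)
    models = sorted({m for f in fits.values() for m in f})
    gaps = [
        (p, m) for p in participants for m in models if m not in fits[p]
    ]
    if gaps:
        raise ValueError(f"missing fits for {gaps}")
    aicc = pd.DataFrame(
        [[fits[p][m].aicc for m in models] for p in participants],
        index=participants,
        columns=models,
    )
    if baseline not in aicc.columns:
        raise ValueError(f"baseline model {baseline!r} not among fits")
    delta = aicc.sub(aicc[baseline], axis=0)
    winners = aicc.apply(_tie_break_winner, axis=1)
    group_series = pd.Series(groups).reindex(participants) if groups else None
    return ComparisonTable(aicc=aicc, delta_vs_rw=delta, winners=winners, groups=group_series)


def log_evidence_matrix(
    fits: dict[str, dict[str, FitResult]], evidence: str = "aicc"
) -> pd.DataFrame:
    """Per-participant log model evidence proxy (-AICc/2 or -AIC/2)."""
    if evidence not in ("aicc", "aic"):
        raise ValueError("evidence must be 'aicc' or 'aic'")
    participants = sorted(fits)
    models = sorted({m for f in fits.values() for m in f})
    rows = []
    for p in participants:
        row = []
        for m in models:
            fr = fits[p][m]
            if evidence == "aicc":
                row.append(-fr.aicc / 2.0)
            else:
                k = MODEL_SPECS[m].k_total
                row.append(-(fr.neg_log_likelihood + k))
        rows.append(row)
    return pd.DataFrame(rows, index=participants, columns=models)


@dataclass
class BmsResult:
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    bor: float
    protected_exceedance_probabilities: np.ndarray
    alpha: np.ndarray
    n_samples: int
    models: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "models": list(self.models),
            "expected_frequencies": self.expected_frequencies.tolist(),
            "exceedance_probabilities": self.exceedance_probabilities.tolist(),
            "bor": self.bor,
            "protected_exceedance_probabilities": self.protected_exceedance_probabilities.tolist(),
        }


def _vb_dirichlet(L: np.ndarray, alpha0: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Variational posterior Dirichlet(alpha) for random-effects BMS.

    Iterates the standard updates: responsibilities g_nk proportional to
    exp(L_nk + E[log r_k]) and alpha = alpha0 + sum_n g_n.
    """
    n, K = L.shape
    alpha = alpha0.copy()
    for _ in range(max_iter):
        e_log_r = digamma(alpha) - digamma(alpha.sum())
        logu = L + e_log_r
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    logu = L + e_log_r
    g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
    return alpha, g


def _log_dirichlet_const(a: np.ndarray) -> float:
    return float(gammaln(a.sum()) - gammaln(a).sum())


def _free_energy(L: np.ndarray, alpha0: np.ndarray, alpha: np.ndarray, g: np.ndarray) -> float:
    """Variational free energy (ELBO) of the random-effects model."""
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.where(g > 0, g * np.log(g), 0.0).sum()
    data_term = float((g * (L + e_log_r)).sum())
    prior_term = _log_dirichlet_const(alpha0) + float(((alpha0 - 1) * e_log_r).sum())
    q_term = _log_dirichlet_const(alpha) + float(((alpha - 1) * e_log_r).sum())
    return data_term + entropy + prior_term - q_term


def _free_energy_null(L: np.ndarray) -> float:
    """Log evidence of the fixed equal-frequency null (r_k = 1/K)."""
    K = L.shape[1]
    return float(logsumexp(L - np.log(K), axis=1).sum())


def protected_exceedance(
    log_evidence: pd.DataFrame | np.ndarray,
    n_samples: int = 100_000,
    rng: np.random.Generator | int | None = None,
    alpha0: float = 1.0,
) -> BmsResult:
    """Random-effects Bayesian model selection with protected EP.

    Parameters
    ----------
    log_evidence
        participants x models matrix of log model evidence (e.g. -AICc/2).
    n_samples
        Monte-Carlo samples from the posterior Dirichlet for the EP.
    """
    models: tuple[str, ...] = ()
    if isinstance(log_evidence, pd.DataFrame):
        models = tuple(log_evidence.columns)
        L = log_evidence.to_numpy(dtype=float)
    else:
        L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need a participants x models matrix with K >= 2")
    if not np.isfinite(L).all():
        raise ValueError("log evidence matrix contains non-finite values")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    n, K = L.shape
    # center rows for numerical comfort; EP/BOR are invariant to row shifts
    L = L - L.mean(axis=1, keepdims=True)
    a0 = np.full(K, float(alpha0))
    alpha, g = _vb_dirichlet(L, a0)

    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    ep = np.bincount(winners, minlength=K) / n_samples

    f1 = _free_energy(L, a0, alpha, g)
    f0 = _free_energy_null(L)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * ep + bor / K
    return BmsResult(
        expected_frequencies=alpha / alpha.sum(),
        exceedance_probabilities=ep,
        bor=bor,
        protected_exceedance_probabilities=pxp,
        alpha=alpha,
        n_samples=n_samples,
        models=models,
    )
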