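"""Reward distributions and run schedules for the three-armed bandit task.

The task offers three bandits: *low* and *high* draw rewards from Gaussians
(SD 5.55) whose means are 33.33 points apart, while *mid* draws from an
asymmetric two-component Gaussian mixture whose total mean is equidistant
from the other two.  The smaller (20%) mode of the mid bandit sits 35 points
below the main mode — below the mean of the low bandit — so that rare mid
outcomes elicit large negative prediction errors without being improbable
outliers of the task as a whole.

Schedules interleave free choices (192 per run, balanced over the three
bandit pairs), guided choices (48 per run) and 16 estimation probes per run,
with 4-5 estimation probes immediately preceded by a guided mid trial rigged
to produce a low-mode outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .config import TaskConfig

ROLES = ("low", "mid", "high")
PAIRS = ("low-mid", "mid-high", "low-high")
PAIR_MEMBERS = {
    "low-mid": ("low", "mid"),
    "mid-high": ("mid", "high"),
    "low-high": ("low", "high"),
}


class InvalidMixtureError(ValueError):
    pass


class ScheduleConstructionError(RuntimeError):
    pass


def mid_mixture_components(
    mean_total: float, weight_low: float, mode_distance: float
) -> tuple[float, float]:
    """Solve for the (main, low) component means of the mid bandit's mixture.

    The two linear constraints are that the weighted component means equal
    the total mean and that the components are ``mode_distance`` apart:

        weight_low * m_low + (1 - weight_low) * m_main = mean_total
        m_main - m_low = mode_distance

    Returns
    -------
    (m_main, m_low)
    """
    if weight_low >= 1.0:
        raise InvalidMixtureError("weight_low must be < 1")
    if weight_low < 0.0 or mode_distance < 0.0:
        raise InvalidMixtureError("weight_low and mode_distance must be non-negative")
    m_main = mean_total + weight_low * mode_distance
    m_low = m_main - mode_distance
    return m_main, m_low


@dataclass(frozen=True)
class BanditDistribution:
    """One bandit's reward distribution (Gaussian or two-component mixture)."""

    role: str
    kind: str  # "gaussian" | "bimodal"
    mean_total: float
    sd_component: float
    component_means: tuple[float, float] | None = None  # (main, low)
    weight_low_mode: float | None = None

    def __post_init__(self):
        if self.kind == "bimodal":
            if self.component_means is None or self.weight_low_mode is None:
                raise InvalidMixtureError("bimodal bandit needs components and weight")
            m_main, m_low = self.component_means
            w = self.weight_low_mode
            if abs(w * m_low + (1 - w) * m_main - self.mean_total) > 1e-9:
                raise InvalidMixtureError("mixture mean does not match total mean")
        elif self.kind != "gaussian":
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    def cdf(self, x):
        """Untruncated CDF of the reward distribution."""
        if self.kind == "gaussian":
            return norm.cdf(x, self.mean_total, self.sd_component)
        m_main, m_low = self.component_means
        w = self.weight_low_mode
        return w * norm.cdf(x, m_low, self.sd_component) + (1 - w) * norm.cdf(
            x, m_main, self.sd_component
        )


def make_bandit_set(
    config: TaskConfig,
    run_index: int,
    rng: np.random.Generator,
    shift: float | None = None,
) -> dict[str, BanditDistribution]:
    """Build the low/mid/high distributions for one run.

    Run 1 anchors the mid mean at ``config.anchor_mid_mean`` (optionally
    jittered); later runs shift all means by a common uniform draw in
    [-run_shift_max, +run_shift_max].  A shift that would push any component
    mean within ``bound_margin_sds`` SDs of the reward bounds is resampled,
    so rejection-sampled rewards stay essentially untruncated.
    """
    if not 1 <= run_index <= config.n_runs:
        raise ValueError(f"run_index must be in 1..{config.n_runs}")
    anchor = config.anchor_mid_mean
    if config.anchor_jitter > 0:
        anchor = anchor + rng.uniform(-config.anchor_jitter, config.anchor_jitter)
    margin = config.bound_margin_sds * config.gaussian_sd

    def _set_for(mid_mean: float) -> dict[str, BanditDistribution] | None:
        half = config.low_high_distance / 2.0
        low_mean, high_mean = mid_mean - half, mid_mean + half
        m_main, m_low = mid_mixture_components(
            mid_mean, config.mix_weight_low_mode, config.mode_distance
        )
        extremes = (m_low, low_mean, m_main, high_mean)
        if min(extremes) < config.reward_min + margin:
            return None
        if max(extremes) > config.reward_max - margin:
            return None
        sd = config.gaussian_sd
        return {
            "low": BanditDistribution("low", "gaussian", low_mean, sd),
            "mid": BanditDistribution(
                "mid", "bimodal", mid_mean, sd,
                component_means=(m_main, m_low),
                weight_low_mode=config.mix_weight_low_mode,
            ),
            "high": BanditDistribution("high", "gaussian", high_mean, sd),
        }

    if run_index == 1:
        bandits = _set_for(anchor)
        if bandits is None:
            raise ScheduleConstructionError("anchor mean violates bound margin")
        return bandits

    for _ in range(1000):
        s = shift if shift is not None else rng.uniform(-config.run_shift_max, config.run_shift_max)
        bandits = _set_for(anchor + s)
        if bandits is not None:
            return bandits
        if shift is not None:
            raise ScheduleConstructionError("requested shift violates bound margin")
    raise ScheduleConstructionError("could not find admissible between-run shift")


def sample_reward(
    dist: BanditDistribution,
    rng: np.random.Generator,
    forced_low_mode: bool = False,
    return_component: bool = False,
):
    """Draw one bounded reward; out-of-bounds draws are rejected and redrawn.

    For the bimodal bandit the mixture component is chosen first (low mode
    with probability ``weight_low_mode``, or always when ``forced_low_mode``)
    and the component label can be returned alongside the reward.
    """
    for _ in range(10000):
        if dist.kind == "bimodal":
            low = forced_low_mode or (rng.random() < dist.weight_low_mode)
            mean = dist.component_means[1] if low else dist.component_means[0]
        else:
            low, mean = False, dist.mean_total
        x = rng.normal(mean, dist.sd_component)
        if 0.0 <= x <= 100.0:
            return (x, "low" if low else "main") if return_component else x
    raise RuntimeError("reward rejection sampling failed to terminate")


def sample_rewards(
    dist: BanditDistribution,
    size: int,
    rng: np.random.Generator,
    forced_low_mode: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized counterpart of :func:`sample_reward`.

    Returns ``(rewards, from_low_mode)`` arrays of length ``size``.
    Rejected (out-of-bounds) draws are redrawn component and all, matching
    the per-draw semantics exactly.
    """
    rewards = np.empty(size)
    low_flags = np.zeros(size, dtype=bool)
    pending = np.arange(size)
    while pending.size:
        if dist.kind == "bimodal":
            low = (
                np.ones(pending.size, dtype=bool)
                if forced_low_mode
                else rng.random(pending.size) < dist.weight_low_mode
            )
            means = np.where(low, dist.component_means[1], dist.component_means[0])
        else:
            low = np.zeros(pending.size, dtype=bool)
            means = np.full(pending.size, dist.mean_total)
        draws = rng.normal(means, dist.sd_component)
        ok = (draws >= 0.0) & (draws <= 100.0)
        rewards[pending[ok]] = draws[ok]
        low_flags[pending[ok]] = low[ok]
        pending = pending[~ok]
    return rewards, low_flags


def distribution_percentile(dist: BanditDistribution, q: float) -> float:
    """Invert the theoretical (untruncated) CDF at probability ``q``."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    if dist.kind == "gaussian":
        return float(norm.ppf(q, dist.mean_total, dist.sd_component))
    lo = min(dist.component_means) - 10 * dist.sd_component
    hi = max(dist.component_means) + 10 * dist.sd_component
    return float(brentq(lambda x: dist.cdf(x) - q, lo, hi, xtol=1e-10))


@dataclass
class TrialSpec:
    """One scheduled trial (before any agent behavior)."""

    trial_type: str  # "free" | "guided" | "estimation"
    pair: str | None = None  # bandit pair for choice trials, None for estimation
    left: str | None = None
    right: str | None = None
    guided_target: str | None = None
    rigged_low_mode: bool = False


@dataclass
class RunSchedule:
    run_index: int
    trials: list[TrialSpec] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.trials):
            rows.append(
                {
                    "run": self.run_index,
                    "trial_index": i,
                    "trial_type": t.trial_type,
                    "pair": t.pair,
                    "left_bandit": t.left,
                    "right_bandit": t.right,
                    "guided_target": t.guided_target,
                    "rigged_low_mode": t.rigged_low_mode,
                }
            )
        return pd.DataFrame(rows)


def _estimation_positions(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Choose how many choice trials precede each estimation probe.

    Positions p_1 <= ... <= p_16 must satisfy p_1 >= first_allowed and
    p_{i+1} - p_i >= min_gap.  Subtracting the cumulative minimum gaps maps
    admissible positions onto order statistics of a uniform sample, which are
    drawn directly instead of by rejection.
    """
    n = config.n_estimation
    gap = config.estimation_min_gap
    first = config.estimation_first_allowed
    top = config.n_choice_trials_per_run - gap * (n - 1)
    if top < first:
        raise ScheduleConstructionError("estimation constraints are infeasible")
    base = np.sort(rng.integers(first, top + 1, size=n))
    return base + gap * np.arange(n)


def build_run_schedule(
    config: TaskConfig, rng: np.random.Generator, run_index: int = 1
) -> RunSchedule:
    """Assemble one run: choice trials, estimation probes, rigging.

    Free trials are balanced over the three pairs; guided trials are
    balanced over pairs and, within pair, over the two possible targets.
    4-5 estimation probes are preceded immediately by a guided mid trial
    forced to the low mixture component.  Left/right assignment is a fair
    coin per choice trial.
    """
    config.validate()
    if config.n_free % len(PAIRS) or config.n_guided % len(PAIRS):
        raise ScheduleConstructionError("free and guided counts must divide by 3")

    free_per_pair = config.n_free // 3
    guided_per_pair = config.n_guided // 3

    pool: list[TrialSpec] = []
    for pair in PAIRS:
        pool.extend(TrialSpec("free", pair=pair) for _ in range(free_per_pair))
    guided_mid: list[TrialSpec] = []
    for pair in PAIRS:
        a, b = PAIR_MEMBERS[pair]
        half = guided_per_pair // 2
        targets = [a] * half + [b] * (guided_per_pair - half)
        for tgt in targets:
            spec = TrialSpec("guided", pair=pair, guided_target=tgt)
            (guided_mid if tgt == "mid" else pool).append(spec)

    n_rigged = int(rng.integers(config.n_rigged_min, config.n_rigged_max + 1))
    if n_rigged > len(guided_mid):
        raise ScheduleConstructionError("not enough guided mid trials to rig")
    rng.shuffle(guided_mid)
    rigged = guided_mid[:n_rigged]
    for spec in rigged:
        spec.rigged_low_mode = True
    pool.extend(guided_mid[n_rigged:])

    positions = _estimation_positions(config, rng)
    rigged_est = rng.choice(config.n_estimation, size=n_rigged, replace=False)

    # choice-slot -> fixed rigged trial (the slot just before its estimation probe)
    fixed: dict[int, TrialSpec] = {}
    for spec, est_idx in zip(rigged, sorted(rigged_est)):
        fixed[int(positions[est_idx]) - 1] = spec

    rng.shuffle(pool)
    free_slots = [i for i in range(config.n_choice_trials_per_run) if i not in fixed]
    if len(free_slots) != len(pool):
        raise ScheduleConstructionError("slot bookkeeping mismatch")
    choice_trials: list[TrialSpec | None] = [None] * config.n_choice_trials_per_run
    for slot, spec in fixed.items():
        choice_trials[slot] = spec
    for slot, spec in zip(free_slots, pool):
        choice_trials[slot] = spec

    for spec in choice_trials:
        a, b = PAIR_MEMBERS[spec.pair]
        if rng.random() < 0.5:
            spec.left, spec.right = a, b
        else:
            spec.left, spec.right = b, a

    trials: list[TrialSpec] = []
    est_after = set(int(p) for p in positions)
    for i, spec in enumerate(choice_trials):
        trials.append(spec)
        if (i + 1) in est_after:
            trials.append(TrialSpec("estimation"))
    schedule = RunSchedule(run_index=run_index, trials=trials)
    check_schedule(schedule, config)
    return schedule


def check_schedule(schedule: RunSchedule, config: TaskConfig) -> None:
    """Raise if any schedule invariant is violated."""
    counts = {"free": 0, "guided": 0, "estimation": 0}
    pair_free: dict[str, int] = {p: 0 for p in PAIRS}
    pair_guided: dict[str, int] = {p: 0 for p in PAIRS}
    choice_seen = 0
    last_est_pos = None
    rigged_before_est = 0
    prev: TrialSpec | None = None
    for t in schedule.trials:
        counts[t.trial_type] += 1
        if t.trial_type == "estimation":
            if choice_seen < config.estimation_first_allowed:
                raise ScheduleConstructionError("estimation probe too early")
            if last_est_pos is not None and choice_seen - last_est_pos < config.estimation_min_gap:
                raise ScheduleConstructionError("estimation probes too close")
            last_est_pos = choice_seen
            if prev is not None and prev.trial_type == "guided" and prev.rigged_low_mode:
                rigged_before_est += 1
        else:
            choice_seen += 1
            (pair_free if t.trial_type == "free" else pair_guided)[t.pair] += 1
            if t.rigged_low_mode and not (
                t.trial_type == "guided" and t.guided_target == "mid"
            ):
                raise ScheduleConstructionError("rigged flag on a non-guided-mid trial")
        prev = t
    if counts["free"] != config.n_free or counts["guided"] != config.n_guided:
        raise ScheduleConstructionError("wrong free/guided counts")
    if counts["estimation"] != config.n_estimation:
        raise ScheduleConstructionError("wrong estimation count")
    if len(set(pair_free.values())) != 1 or len(set(pair_guided.values())) != 1:
        raise ScheduleConstructionError("pair frequencies unbalanced")
    if not config.n_rigged_min <= rigged_before_est <= config.n_rigged_max:
        raise ScheduleConstructionError("rigged guided mid trials not before estimations")
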