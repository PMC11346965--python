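"""Behavioral pipeline: exclusions, performance, surprise windows, estimation.

Implements the participant-level behavioral analyses of the task:

* exclusion rules (chance-level performance on the easiest comparison,
  outlying guided-error counts, degenerate estimation responses),
* proportion of correct free choices per bandit pair / run / trial bin,
* the pre/post analysis of mid-bandit choices around surprising mid
  outcomes (below the mid distribution's 20th percentile, with the 20th-40th
  percentile band as a control),
* distortion of perceived bandit distances on estimation trials, and
* simple within/between-group contrasts of the per-participant summaries
  (paired and two-sample t-tests with effect sizes; a deliberate
  replacement for full mixed-effects machinery, which any external tool can
  run on the exported long-format tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ParticipantDataset
from .task_design import distribution_percentile

BANDS = ("below20", "20to40")


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    kept: list[str]
    excluded: dict[str, str]  # participant -> reason
    excluded_estimation_runs: dict[str, list[int]]  # participant -> runs dropped

    def kept_datasets(self, cohort: list[ParticipantDataset]) -> list[ParticipantDataset]:
        keep = set(self.kept)
        return [ds for ds in cohort if ds.participant_id in keep]


def _low_high_correct(ds: ParticipantDataset) -> tuple[int, int]:
    ct = ds.choice_trials()
    lh = ct[(ct["trial_type"] == "free") & (ct["pair"] == "low-high")]
    answered = lh[lh["chosen_bandit"].notna()]
    return int(answered["correct"].sum()), len(answered)


def apply_exclusions(
    cohort: list[ParticipantDataset], alpha: float = 0.05
) -> ExclusionReport:
    """Participant- and run-level exclusions.

    Choice-level: a one-sided binomial test of correct low-high free
    choices against chance (pooled over runs) must be significant.
    Guided errors: participants with more errors than cohort mean + 3 SD
    are dropped.  Estimation runs: a run is excluded from estimation
    analyses when low vs high estimates do not differ (paired t-test) or
    the submitted estimates have no variance at all.
    """
    if not cohort:
        raise ValueError("empty cohort")
    excluded: dict[str, str] = {}

    for ds in cohort:
        k, n = _low_high_correct(ds)
        if n == 0 or stats.binomtest(k, n, 0.5, alternative="greater").pvalue >= alpha:
            excluded[ds.participant_id] = "chance-level low-high performance"

    err_counts = {
        ds.participant_id: int(ds.choice_trials()["guided_error"].fillna(False).sum())
        for ds in cohort
    }
    vals = np.array(list(err_counts.values()), dtype=float)
    if len(cohort) > 1:
        cut = vals.mean() + 3.0 * vals.std(ddof=1)
        for pid, c in err_counts.items():
            if c > cut and pid not in excluded:
                excluded[pid] = "guided-error count > mean + 3 SD"
    else:
        warnings.warn("cohort of one: skipping SD-based guided-error rule")

    est_runs: dict[str, list[int]] = {}
    for ds in cohort:
        if ds.participant_id in excluded:
            continue
        dropped = []
        est = ds.estimation_trials()
        for run in ds.runs:
            er = est[est["run"] == run]
            low, high = er["est_low"].to_numpy(), er["est_high"].to_numpy()
            allv = er[["est_low", "est_mid", "est_high"]].to_numpy().ravel()
            if len(er) < 2 or np.var(allv) == 0:
                dropped.append(run)
                continue
            diff = high - low
            if np.all(diff == diff[0]):
                # identical differences: paired t-test undefined or p=nan
                if diff[0] == 0:
                    dropped.append(run)
                continue
            if stats.ttest_rel(high, low).pvalue >= alpha:
                dropped.append(run)
        if dropped:
            est_runs[ds.participant_id] = dropped

    kept = [ds.participant_id for ds in cohort if ds.participant_id not in excluded]
    return ExclusionReport(kept=kept, excluded=excluded, excluded_estimation_runs=est_runs)


# ---------------------------------------------------------------------------
# Performance
# ---------------------------------------------------------------------------

def performance_by_condition(
    ds: ParticipantDataset, bin_size: int = 40
) -> pd.DataFrame:
    """Proportion of correct free choices per (pair, run, trial bin)."""
    ct = ds.choice_trials().copy()
    ct["choice_pos"] = ct.groupby("run").cumcount()
    free = ct[(ct["trial_type"] == "free") & ct["chosen_bandit"].notna()].copy()
    free["bin"] = free["choice_pos"] // bin_size
    out = (
        free.groupby(["run", "pair", "bin"])["correct"]
        .agg(n="count", prop_correct="mean")
        .reset_index()
    )
    return out


def overall_accuracy_by_pair(ds: ParticipantDataset) -> pd.Series:
    """Per-pair proportion correct over all free choices (both runs)."""
    ct = ds.choice_trials()
    free = ct[(ct["trial_type"] == "free") & ct["chosen_bandit"].notna()]
    return free.groupby("pair")["correct"].mean()


# ---------------------------------------------------------------------------
# Surprise pre/post analysis
# ---------------------------------------------------------------------------

@dataclass
class SurpriseEventWindow:
    run: int
    event_row: int  # positional index into the trial table
    band: str
    pre_rows: list[int]  # up to 1 preceding free low-mid trial
    post_rows: list[int]  # up to 2 following free low-mid trials
    pre_mid_chosen: list[bool] = field(default_factory=list)
    post_mid_chosen: list[bool] = field(default_factory=list)


def find_surprise_events(
    ds: ParticipantDataset, band: str = "below20"
) -> list[SurpriseEventWindow]:
    """Windows around observed mid-bandit outcomes in a percentile band.

    Thresholds come from the theoretical mixture CDF of each run's mid
    bandit.  An outcome exactly at the 20th percentile belongs to the
    20-40 band (left-closed bands).  The window holds the nearest
    preceding free low-mid choice and the next two following ones, never
    crossing a run boundary; overlapping windows are kept independently.
    """
    if band not in BANDS:
        raise ValueError(f"band must be one of {BANDS}")
    trials = ds.trials
    windows: list[SurpriseEventWindow] = []
    for run in ds.runs:
        mid = ds.bandits[run]["mid"]
        q20 = distribution_percentile(mid, 0.2)
        q40 = distribution_percentile(mid, 0.4)
        tr = trials[trials["run"] == run]
        pos = tr.index.to_numpy()
        rewards = tr["reward"].to_numpy(dtype=float)
        chosen = tr["chosen_bandit"].to_numpy(dtype=object)
        is_lm_free = (
            (tr["trial_type"] == "free") & (tr["pair"] == "low-mid")
        ).to_numpy()
        answered = tr["chosen_bandit"].notna().to_numpy()
        lm_free = is_lm_free & answered
        mid_outcome = (chosen == "mid") & np.isfinite(rewards)
        if band == "below20":
            in_band = mid_outcome & (rewards < q20)
        else:
            in_band = mid_outcome & (rewards >= q20) & (rewards < q40)
        lm_idx = np.where(lm_free)[0]
        for i in np.where(in_band)[0]:
            pre = lm_idx[lm_idx < i]
            post = lm_idx[lm_idx > i]
            w = SurpriseEventWindow(
                run=run,
                event_row=int(pos[i]),
                band=band,
                pre_rows=[int(pos[j]) for j in pre[-1:]],
                post_rows=[int(pos[j]) for j in post[:2]],
            )
            w.pre_mid_chosen = [bool(chosen[j] == "mid") for j in pre[-1:]]
            w.post_mid_chosen = [bool(chosen[j] == "mid") for j in post[:2]]
            windows.append(w)
    return windows


def surprise_prepost(
    ds: ParticipantDataset, band: str = "below20"
) -> tuple[float, float]:
    """Pooled (pre, post) proportions of mid choices around band events."""
    windows = find_surprise_events(ds, band)
    pre = [f for w in windows for f in w.pre_mid_chosen]
    post = [f for w in windows for f in w.post_mid_chosen]
    if not pre or not post:
        warnings.warn(f"no qualifying {band} windows for {ds.participant_id}")
        return (float("nan"), float("nan"))
    return float(np.mean(pre)), float(np.mean(post))


# ---------------------------------------------------------------------------
# Estimation distortion
# ---------------------------------------------------------------------------

def estimation_distortion(ds: ParticipantDataset, run: int | None = None) -> pd.DataFrame:
    """Distortion of perceived bandit distances on estimation trials.

    For every estimation trial, the objective difference of a pair is the
    difference of running means of experienced outcomes up to that trial;
    distortion = estimated difference - objective difference, averaged over
    the second half of a run's estimation trials.  Pairs are ordered
    low->mid and mid->high, so negative values mean the distance was
    underestimated.  Trials where a bandit was never sampled are skipped;
    runs with fewer than two usable second-half trials yield NaN.
    """
    runs = [run] if run is not None else ds.runs
    out = []
    for r in runs:
        tr = ds.trials[ds.trials["run"] == r]
        sums = {b: 0.0 for b in ("low", "mid", "high")}
        counts = {b: 0 for b in ("low", "mid", "high")}
        rows = []  # (obj_lm, obj_mh, est_lm, est_mh)
        for _, t in tr.iterrows():
            if t["trial_type"] == "estimation":
                if min(counts.values()) == 0:
                    continue
                means = {b: sums[b] / counts[b] for b in sums}
                rows.append(
                    (
                        means["mid"] - means["low"],
                        means["high"] - means["mid"],
                        t["est_mid"] - t["est_low"],
                        t["est_high"] - t["est_mid"],
                    )
                )
            elif np.isfinite(t["reward"]):
                sums[t["chosen_bandit"]] += t["reward"]
                counts[t["chosen_bandit"]] += 1
        second_half = rows[len(rows) // 2:] if len(rows) >= 2 else []
        if len(second_half) >= 2:
            arr = np.array(second_half)
            d_lm = float(np.mean(arr[:, 2] - arr[:, 0]))
            d_mh = float(np.mean(arr[:, 3] - arr[:, 1]))
        else:
            d_lm = d_mh = float("nan")
        out.append({"run": r, "pair": "low-mid", "distortion": d_lm})
        out.append({"run": r, "pair": "mid-high", "distortion": d_mh})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Group contrasts
# ---------------------------------------------------------------------------

def _cohens_d(x: np.ndarray, y: np.ndarray | None = None) -> float:
    if y is None:
        return float(np.mean(x) / np.std(x, ddof=1)) if len(x) > 1 else float("nan")
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2))
    return float((np.mean(x) - np.mean(y)) / sp) if sp > 0 else float("nan")


def group_contrasts(summaries: pd.DataFrame) -> dict:
    """Simple test report over per-participant pre/post summaries.

    ``summaries`` needs columns participant, group, pre, post.  Within each
    group a paired t-test compares pre vs post; between groups a Welch
    t-test compares the pre-post drops.
    """
    report: dict = {"within": {}, "between": None}
    for group, sub in summaries.groupby("group"):
        sub = sub.dropna(subset=["pre", "post"])
        if len(sub) < 2:
            continue
        t = stats.ttest_rel(sub["pre"], sub["post"])
        drop = (sub["pre"] - sub["post"]).to_numpy()
        report["within"][group] = {
            "n": len(sub),
            "mean_pre": float(sub["pre"].mean()),
            "mean_post": float(sub["post"].mean()),
            "mean_drop": float(drop.mean()),
            "t": float(t.statistic),
            "p": float(t.pvalue),
            "d": _cohens_d(drop),
        }
    groups = sorted(summaries["group"].dropna().unique())
    if len(groups) == 2:
        drops = {}
        for g in groups:
            sub = summaries[summaries["group"] == g].dropna(subset=["pre", "post"])
            drops[g] = (sub["pre"] - sub["post"]).to_numpy()
        if all(len(v) >= 2 for v in drops.values()):
            t = stats.ttest_ind(drops[groups[0]], drops[groups[1]], equal_var=False)
            report["between"] = {
                "groups": groups,
                "mean_drops": {g: float(np.mean(v)) for g, v in drops.items()},
                "t": float(t.statistic),
                "p": float(t.pvalue),
                "d": _cohens_d(drops[groups[0]], drops[groups[1]]),
            }
    return report


def cohort_prepost_summary(
    cohort: list[ParticipantDataset], band: str = "below20"
) -> pd.DataFrame:
    """Per-participant pre/post mid-choice proportions for a band."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ds in cohort:
            pre, post = surprise_prepost(ds, band)
            rows.append(
                {
                    "participant": ds.participant_id,
                    "group": ds.group,
                    "band": band,
                    "pre": pre,
                    "post": post,
                }
            )
    return pd.DataFrame(rows)
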