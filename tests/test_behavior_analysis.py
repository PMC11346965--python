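"""Exclusions, performance summaries, surprise windows, distortion."""

import numpy as np
import pandas as pd
import pytest

import surprise_bandit as sb
from conftest import toy_dataset


def _free_lh(chosen, n, start=0, run=1):
    """n low-high free-choice rows, `chosen` of them picking high (correct)."""
    rows = []
    for i in range(n):
        pick_high = i < chosen
        rows.append(
            dict(run=run, trial_index=start + i, trial_type="free", pair="low-high",
                 left_bandit="low", right_bandit="high",
                 chosen_bandit="high" if pick_high else "low",
                 chosen_side="right" if pick_high else "left",
                 reward=70.0 if pick_high else 33.0, correct=pick_high)
        )
    return rows


def _estimations(n, run=1, low=30.0, mid=50.0, high=70.0, start=500):
    return [
        dict(run=run, trial_index=start + i, trial_type="estimation",
             est_low=low, est_mid=mid, est_high=high,
             range_low=5.0, range_mid=8.0, range_high=5.0)
        for i in range(n)
    ]


class TestExclusions:
    def test_strong_performer_kept(self):
        ds = toy_dataset(_free_lh(120, 128) + _estimations(4) + _estimations(4, run=2))
        report = sb.apply_exclusions([ds, ds])
        assert report.kept == ["toy", "toy"]

    def test_coin_flip_performer_excluded(self):
        ds = toy_dataset(_free_lh(64, 128))
        report = sb.apply_exclusions([ds])
        assert "toy" in report.excluded
        assert "chance" in report.excluded["toy"]

    def test_borderline_binomial_threshold(self):
        # 74/128 is the smallest count significant at one-sided alpha=.05
        from scipy.stats import binomtest

        assert binomtest(74, 128, 0.5, alternative="greater").pvalue < 0.05
        assert binomtest(73, 128, 0.5, alternative="greater").pvalue >= 0.05
        kept = toy_dataset(_free_lh(74, 128), participant_id="a")
        dropped = toy_dataset(_free_lh(73, 128), participant_id="b")
        report = sb.apply_exclusions([kept, dropped])
        assert report.kept == ["a"]
        assert "b" in report.excluded

    def test_zero_variance_estimation_run_dropped(self):
        rows = _free_lh(120, 128) + _estimations(4, low=50.0, mid=50.0, high=50.0)
        rows += _estimations(4, run=2)
        ds = toy_dataset(rows)
        report = sb.apply_exclusions([ds, ds])
        assert report.excluded_estimation_runs.get("toy") == [1]

    def test_indistinguishable_low_high_estimates_drop_run(self):
        noisy = [
            dict(run=1, trial_index=500 + i, trial_type="estimation",
                 est_low=50.0 + d, est_mid=50.0, est_high=50.0 - d)
            for i, d in enumerate([1.0, -1.0, 0.5, -0.5])
        ]
        ds = toy_dataset(_free_lh(120, 128) + noisy + _estimations(4, run=2))
        report = sb.apply_exclusions([ds, ds])
        assert 1 in report.excluded_estimation_runs.get("toy", [])
        assert 2 not in report.excluded_estimation_runs.get("toy", [])

    def test_guided_error_outlier_excluded(self, config):
        normal = toy_dataset(_free_lh(120, 128), participant_id="ok")
        rows = _free_lh(120, 128)
        for i in range(40):
            rows.append(
                dict(run=1, trial_index=300 + i, trial_type="guided", pair="low-mid",
                     left_bandit="low", right_bandit="mid", guided_target="mid",
                     chosen_bandit="low", chosen_side="left", guided_error=True)
            )
        sloppy = toy_dataset(rows, participant_id="sloppy")
        cohort = [toy_dataset(_free_lh(120, 128), participant_id=f"ok{i}") for i in range(15)]
        report = sb.apply_exclusions(cohort + [sloppy])
        assert "sloppy" in report.excluded
        assert "guided-error" in report.excluded["sloppy"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            sb.apply_exclusions([])


class TestPerformance:
    def test_perfect_agent_scores_100_everywhere(self):
        ds = toy_dataset(_free_lh(80, 80) + _free_lh(80, 80, run=2))
        perf = sb.performance_by_condition(ds)
        assert (perf["prop_correct"] == 1.0).all()

    def test_bins_of_40_choice_trials(self):
        ds = toy_dataset(_free_lh(80, 80))
        perf = sb.performance_by_condition(ds)
        assert perf["bin"].tolist() == [0, 1]
        assert perf["n"].tolist() == [40, 40]

    def test_empty_cells_absent_not_zero(self):
        ds = toy_dataset(_free_lh(10, 10))
        perf = sb.performance_by_condition(ds)
        assert set(perf["pair"]) == {"low-high"}


def _surprise_run(event_reward, pre=1, post=2):
    """low-mid free trials around one guided mid outcome."""
    rows = []
    i = 0
    for _ in range(pre):
        rows.append(
            dict(run=1, trial_index=i, trial_type="free", pair="low-mid",
                 left_bandit="low", right_bandit="mid", chosen_bandit="mid",
                 chosen_side="right", reward=55.0, correct=True)
        )
        i += 1
    rows.append(
        dict(run=1, trial_index=i, trial_type="guided", pair="low-mid",
             left_bandit="low", right_bandit="mid", guided_target="mid",
             chosen_bandit="mid", chosen_side="right", reward=event_reward,
             correct=True)
    )
    i += 1
    for _ in range(post):
        rows.append(
            dict(run=1, trial_index=i, trial_type="free", pair="low-mid",
                 left_bandit="low", right_bandit="mid", chosen_bandit="low",
                 chosen_side="left", reward=33.0, correct=False)
        )
        i += 1
    return rows


class TestSurpriseEvents:
    def test_window_geometry(self):
        ds = toy_dataset(_surprise_run(25.0))
        windows = sb.find_surprise_events(ds, "below20")
        assert len(windows) == 1
        w = windows[0]
        assert len(w.pre_rows) == 1 and len(w.post_rows) == 2
        assert all(r < w.event_row for r in w.pre_rows)
        assert all(r > w.event_row for r in w.post_rows)
        assert w.pre_mid_chosen == [True]
        assert w.post_mid_chosen == [False, False]

    def test_threshold_boundary_goes_to_control_band(self):
        ds_probe = toy_dataset([])
        q20 = sb.distribution_percentile(ds_probe.bandits[1]["mid"], 0.2)
        ds = toy_dataset(_surprise_run(q20))
        assert sb.find_surprise_events(ds, "below20") == []
        control = sb.find_surprise_events(ds, "20to40")
        assert len(control) == 1

    def test_free_mid_outcomes_also_count_as_events(self):
        rows = _surprise_run(25.0)
        rows[1]["trial_type"] = "free"
        rows[1]["guided_target"] = None
        ds = toy_dataset(rows)
        # the event trial is itself a low-mid free mid choice with a low
        # outcome; it is an event AND a candidate window trial for others
        assert len(sb.find_surprise_events(ds, "below20")) == 1

    def test_window_without_post_trials_retained(self):
        ds = toy_dataset(_surprise_run(25.0, post=0))
        windows = sb.find_surprise_events(ds, "below20")
        assert len(windows) == 1
        assert windows[0].post_rows == []

    def test_prepost_proportions(self):
        ds = toy_dataset(_surprise_run(25.0))
        pre, post = sb.surprise_prepost(ds, "below20")
        assert (pre, post) == (1.0, 0.0)

    def test_agent_never_choosing_mid(self):
        rows = _surprise_run(25.0)
        for r in rows:
            if r["trial_type"] == "free":
                r.update(chosen_bandit="low", chosen_side="left", reward=33.0, correct=False)
        ds = toy_dataset(rows)
        pre, post = sb.surprise_prepost(ds, "below20")
        assert (pre, post) == (0.0, 0.0)

    def test_event_rate_tracks_mixture_weight(self, small_cohort):
        # below-20th-percentile outcomes should cover ~20% of *natural* mid
        # samples; rigged guided trials force the low mode and are excluded
        cohort, _ = small_cohort
        n_events = n_mid = 0
        for ds in cohort:
            rigged_rows = set(ds.trials.index[ds.trials["rigged_low_mode"]])
            n_events += sum(
                w.event_row not in rigged_rows
                for w in sb.find_surprise_events(ds, "below20")
            )
            ct = ds.choice_trials()
            natural = (
                (ct["chosen_bandit"] == "mid")
                & ct["reward"].notna()
                & ~ct["rigged_low_mode"]
            )
            n_mid += int(natural.sum())
        assert n_events / n_mid == pytest.approx(0.20, abs=0.02)

    def test_windows_never_cross_runs(self, small_cohort):
        cohort, _ = small_cohort
        ds = cohort[0]
        for band in ("below20", "20to40"):
            for w in sb.find_surprise_events(ds, band):
                run_rows = set(ds.trials.index[ds.trials["run"] == w.run])
                assert w.event_row in run_rows
                assert set(w.pre_rows) <= run_rows and set(w.post_rows) <= run_rows


class TestEstimationDistortion:
    def _learning_rows(self):
        rows = []
        outcomes = {"low": [30.0, 32.0], "mid": [50.0, 48.0], "high": [70.0, 72.0]}
        i = 0
        for j in range(2):
            for b, pair in (("low", "low-mid"), ("mid", "low-mid"), ("high", "mid-high")):
                rows.append(
                    dict(run=1, trial_index=i, trial_type="free", pair=pair,
                         left_bandit=pair.split("-")[0], right_bandit=pair.split("-")[1],
                         chosen_bandit=b, chosen_side="left", reward=outcomes[b][j],
                         correct=True)
                )
                i += 1
        return rows, outcomes

    def test_exact_running_mean_estimates_give_zero_distortion(self):
        rows, outcomes = self._learning_rows()
        means = {b: float(np.mean(v)) for b, v in outcomes.items()}
        rows += _estimations(4, low=means["low"], mid=means["mid"], high=means["high"])
        ds = toy_dataset(rows)
        d = sb.estimation_distortion(ds, run=1)
        assert d["distortion"].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_mid_bias_splits_across_pairs(self):
        rows, outcomes = self._learning_rows()
        means = {b: float(np.mean(v)) for b, v in outcomes.items()}
        rows += _estimations(4, low=means["low"], mid=means["mid"] - 3.0, high=means["high"])
        ds = toy_dataset(rows)
        d = sb.estimation_distortion(ds, run=1).set_index("pair")["distortion"]
        assert d["low-mid"] == pytest.approx(-3.0)
        assert d["mid-high"] == pytest.approx(+3.0)

    def test_too_few_estimation_trials_yield_nan(self):
        rows, _ = self._learning_rows()
        rows += _estimations(1)
        ds = toy_dataset(rows)
        d = sb.estimation_distortion(ds, run=1)
        assert d["distortion"].isna().all()

    def test_unsampled_bandit_skips_trial(self):
        rows = _free_lh(4, 4) + _estimations(4)  # mid never sampled
        ds = toy_dataset(rows)
        d = sb.estimation_distortion(ds, run=1)
        assert d["distortion"].isna().all()

    def test_unbiased_estimates_are_mean_zero_across_cohort(self, small_cohort):
        cohort, _ = small_cohort
        vals = []
        for ds in cohort:
            d = sb.estimation_distortion(ds)
            vals.extend(d["distortion"].dropna().tolist())
        # noisy-but-unbiased slider readouts of V under moderate learning
        assert abs(np.mean(vals)) < 2.0


class TestGroupContrasts:
    def test_identical_groups_show_no_between_effect(self):
        base = pd.DataFrame(
            {
                "participant": [f"p{i}" for i in range(10)],
                "group": ["younger"] * 5 + ["older"] * 5,
                "pre": [0.8, 0.7, 0.9, 0.75, 0.85] * 2,
                "post": [0.6, 0.5, 0.7, 0.55, 0.65] * 2,
            }
        )
        report = sb.group_contrasts(base)
        assert report["between"]["t"] == pytest.approx(0.0, abs=1e-9)
        assert report["within"]["older"]["mean_drop"] == pytest.approx(0.2)

    def test_small_group_skipped(self):
        df = pd.DataFrame(
            {"participant": ["a"], "group": ["younger"], "pre": [0.8], "post": [0.6]}
        )
        report = sb.group_contrasts(df)
        assert report["within"] == {}
        assert report["between"] is None
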