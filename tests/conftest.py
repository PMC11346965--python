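"""Shared fixtures: configs, toy trial tables, small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import surprise_bandit as sb
from surprise_bandit.datasets import TRIAL_COLUMNS


@pytest.fixture(scope="session")
def config() -> sb.TaskConfig:
    return sb.TaskConfig()


@pytest.fixture(scope="session")
def bandit_set(config):
    return sb.make_bandit_set(config, 1, np.random.default_rng(0))


def random_trial_table(
    rng: np.random.Generator,
    n_trials: int = 120,
    n_runs: int = 2,
    pair: str = "low-mid",
) -> pd.DataFrame:
    """Minimal trial table (free choices, random rewards) for run_model tests."""
    a, b = pair.split("-")
    rows = []
    for run in range(1, n_runs + 1):
        for i in range(n_trials):
            chosen = a if rng.random() < 0.5 else b
            left, right = (a, b) if rng.random() < 0.5 else (b, a)
            rows.append(
                {
                    "run": run,
                    "trial_index": i,
                    "trial_type": "free",
                    "pair": pair,
                    "left_bandit": left,
                    "right_bandit": right,
                    "chosen_bandit": chosen,
                    "reward": float(rng.uniform(0.0, 100.0)),
                }
            )
    return pd.DataFrame(rows)


def toy_dataset(
    trial_rows: list[dict],
    config: sb.TaskConfig | None = None,
    group: str = "younger",
    participant_id: str = "toy",
) -> sb.ParticipantDataset:
    """Build a ParticipantDataset from sparse row dicts; fills NaN columns."""
    config = config or sb.TaskConfig()
    rng = np.random.default_rng(0)
    bandits = {run: sb.make_bandit_set(config, 1, rng) for run in (1, 2)}
    rows = []
    for r in trial_rows:
        row = {c: np.nan for c in TRIAL_COLUMNS}
        row.update({"rigged_low_mode": False, "guided_error": False})
        row.update(r)
        rows.append(row)
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return sb.ParticipantDataset(
        participant_id=participant_id, group=group, trials=trials, bandits=bandits
    )


@pytest.fixture(scope="session")
def small_cohort(config):
    """8 + 8 Surprise agents with the default older u-l shift."""
    spec = sb.CohortSpec(n_younger=8, n_older=8)
    cohort, ledger = sb.generate_cohort(spec, config, np.random.default_rng(2024))
    return cohort, ledger
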