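"""Participant datasets and their on-disk representation.

A cohort lives in a directory holding one delimited trial file per
participant, a ``manifest.json`` describing groups and the per-run bandit
distributions, and (for synthetic cohorts) a ``ground_truth.json`` ledger
with the generating model and parameters of every participant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task_design import BanditDistribution, ROLES

TRIAL_COLUMNS = [
    "run",
    "trial_index",
    "trial_type",
    "pair",
    "left_bandit",
    "right_bandit",
    "guided_target",
    "rigged_low_mode",
    "chosen_side",
    "chosen_bandit",
    "reward",
    "correct",
    "guided_error",
    "est_low",
    "est_mid",
    "est_high",
    "range_low",
    "range_mid",
    "range_high",
]

GROUPS = ("younger", "older")


@dataclass
class ParticipantDataset:
    """All recorded behavior of one participant (both runs)."""

    participant_id: str
    group: str
    trials: pd.DataFrame
    bandits: dict[int, dict[str, BanditDistribution]]

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        missing = set(TRIAL_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")

    @property
    def runs(self) -> list[int]:
        return sorted(self.trials["run"].unique())

    def choice_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["trial_type"] != "estimation"]

    def estimation_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["trial_type"] == "estimation"]

    def validate(self) -> None:
        ct = self.choice_trials()
        offered = ct.apply(
            lambda r: r["chosen_bandit"] in (r["left_bandit"], r["right_bandit"]),
            axis=1,
        )
        answered = ct["chosen_bandit"].notna()
        if not offered[answered].all():
            raise ValueError("chosen bandit not among the offered pair")
        err = ct["guided_error"].fillna(False).astype(bool)
        if ct.loc[err, "reward"].notna().any():
            raise ValueError("reward recorded on a guided error trial")


def _bandit_to_dict(b: BanditDistribution) -> dict:
    return {
        "role": b.role,
        "kind": b.kind,
        "mean_total": b.mean_total,
        "sd_component": b.sd_component,
        "component_means": list(b.component_means) if b.component_means else None,
        "weight_low_mode": b.weight_low_mode,
    }


def _bandit_from_dict(d: dict) -> BanditDistribution:
    return BanditDistribution(
        role=d["role"],
        kind=d["kind"],
        mean_total=d["mean_total"],
        sd_component=d["sd_component"],
        component_means=tuple(d["component_means"]) if d["component_means"] else None,
        weight_low_mode=d["weight_low_mode"],
    )


def write_cohort(
    cohort: list[ParticipantDataset],
    out_dir: str | Path,
    ground_truth: dict | None = None,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"participants": []}
    for ds in cohort:
        fname = f"{ds.participant_id}.csv"
        ds.trials.to_csv(out_dir / fname, index=False, float_format="%.17g")
        manifest["participants"].append(
            {
                "participant_id": ds.participant_id,
                "group": ds.group,
                "file": fname,
                "bandits": {
                    str(run): {role: _bandit_to_dict(b) for role, b in bs.items()}
                    for run, bs in ds.bandits.items()
                },
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if ground_truth is not None:
        (out_dir / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2))


def read_cohort(in_dir: str | Path) -> list[ParticipantDataset]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    cohort = []
    for entry in manifest["participants"]:
        trials = pd.read_csv(in_dir / entry["file"], float_precision="round_trip")
        trials["rigged_low_mode"] = trials["rigged_low_mode"].astype(bool)
        trials["guided_error"] = trials["guided_error"].fillna(False).astype(bool)
        bandits = {
            int(run): {role: _bandit_from_dict(d) for role, d in bs.items()}
            for run, bs in entry["bandits"].items()
        }
        cohort.append(
            ParticipantDataset(
                participant_id=entry["participant_id"],
                group=entry["group"],
                trials=trials,
                bandits=bandits,
            )
        )
    return cohort
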