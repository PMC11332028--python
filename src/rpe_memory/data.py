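"""In-memory containers and tidy-CSV I/O for simulated behavioral data.

All CSV files are comma-separated UTF-8 with a header row and '.' decimals.
Each writer drops a JSON sidecar (``<name>.params.json``) recording the
generating parameters so every artifact is traceable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .task import TaskConfig, TaskSchedule

__all__ = [
    "ChoiceDataset",
    "RECOGNITION_COLUMNS",
    "choices_to_frame",
    "frame_to_choices",
    "write_choices",
    "read_choices",
    "write_table",
]


@dataclass
class ChoiceDataset:
    """One subject's bandit run: choices, 0/1 rewards, per-trial stimulus PM.

    ``pm`` is the normed memorability d-prime of the trial-unique stimulus
    shown with the outcome. ``true_rpe``/``true_q`` hold the generative
    teaching signal when the data were simulated by a value-learning agent.
    """

    subject: str
    choices: np.ndarray
    rewards: np.ndarray
    pm: np.ndarray
    schedule: TaskSchedule
    agent: dict[str, Any] | None = None
    true_rpe: np.ndarray | None = None
    true_q: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)
        self.rewards = np.asarray(self.rewards, dtype=int)
        self.pm = np.asarray(self.pm, dtype=float)
        n = len(self.choices)
        if not (len(self.rewards) == len(self.pm) == n == self.schedule.n_trials):
            raise ValueError("choices, rewards, pm and schedule lengths differ")
        if not np.isin(self.choices, [0, 1]).all():
            raise ValueError("choices must be coded 0/1")
        if not np.isin(self.rewards, [0, 1]).all():
            raise ValueError("rewards must be coded 0/1 (points/100)")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def total_reward(self) -> int:
        """Total reward in 0/1 units (multiply by reward_points for points)."""
        return int(self.rewards.sum())

    @property
    def accuracy(self) -> float:
        """Proportion of choices of the currently better arm."""
        return float((self.choices == self.schedule.good_arm).mean())


#: canonical column order for recognition-phase tables
RECOGNITION_COLUMNS = [
    "subject",
    "probe",
    "is_old",
    "pm",
    "rpe",
    "encoding_trial",
    "response",
    "rt",
    "confidence",
]


def choices_to_frame(cohort: Sequence[ChoiceDataset]) -> pd.DataFrame:
    """Tidy one-row-per-trial frame for a cohort of bandit runs."""
    rows = []
    for ds in cohort:
        sched = ds.schedule
        frame = pd.DataFrame(
            {
                "subject": ds.subject,
                "trial": np.arange(1, ds.n_trials + 1),
                "choice": ds.choices,
                "reward": ds.rewards,
                "pm": ds.pm,
                "good_arm": sched.good_arm,
                "within_block_trial": sched.within_block_trial,
                "p_win_chosen": sched.p_win[np.arange(ds.n_trials), ds.choices],
            }
        )
        if ds.true_rpe is not None:
            frame["true_rpe"] = ds.true_rpe
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def frame_to_choices(frame: pd.DataFrame, config: TaskConfig | None = None) -> list[ChoiceDataset]:
    """Rebuild per-subject :class:`ChoiceDataset` objects from a tidy frame."""
    config = config or TaskConfig()
    out = []
    for subject, grp in frame.groupby("subject", sort=False):
        grp = grp.sort_values("trial")
        good = grp["good_arm"].to_numpy(dtype=int)
        reversal_trials = list(np.flatnonzero(np.diff(good) != 0) + 1)
        sched = TaskSchedule(
            good_arm=good,
            p_win=np.where(
                good[:, None] == np.arange(2)[None, :],
                config.p_win_good,
                config.p_win_bad,
            ),
            within_block_trial=grp["within_block_trial"].to_numpy(dtype=int),
            reversal_trials=[int(r) for r in reversal_trials],
            config=config,
        )
        out.append(
            ChoiceDataset(
                subject=str(subject),
                choices=grp["choice"].to_numpy(),
                rewards=grp["reward"].to_numpy(),
                pm=grp["pm"].to_numpy(),
                schedule=sched,
                true_rpe=grp["true_rpe"].to_numpy() if "true_rpe" in grp else None,
            )
        )
    return out


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_table(frame: pd.DataFrame, path: str | Path, params: dict | None = None) -> Path:
    """Write a tidy CSV plus a JSON sidecar of generating parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".params.json")
        sidecar.write_text(json.dumps(_jsonable(params), indent=2, sort_keys=True))
    return path


def write_choices(cohort: Sequence[ChoiceDataset], path: str | Path, params: dict | None = None) -> Path:
    return write_table(choices_to_frame(cohort), path, params)


def read_choices(path: str | Path, config: TaskConfig | None = None) -> list[ChoiceDataset]:
    return frame_to_choices(pd.read_csv(path), config)
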