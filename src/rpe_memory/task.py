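"""Two-arm reversal bandit: task configuration and trial schedules.

The task is a 60-trial two-arm bandit in which one arm pays reward with
probability 0.8 and the other with probability 0.2 (probabilities are
negatively yoked), and the good arm reverses 4 times, every 12 +/- 1 trials.
Rewards are coded 0/1 internally; the 100-point display scale is cosmetic
and recoverable as ``reward * reward_points``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScheduleInfeasibleError",
    "TaskConfig",
    "TaskSchedule",
    "generate_task_schedule",
]


class ScheduleInfeasibleError(ValueError):
    """Raised when n_trials cannot accommodate the requested reversals."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the reversal bandit.

    Defaults reproduce the study design: 60 trials, 4 reversals placed
    every ``12 +/- 1`` trials, win probabilities 0.8/0.2, 100-point wins.
    """

    n_trials: int = 60
    n_reversals: int = 4
    block_length_mean: int = 12
    block_length_jitter: int = 1
    p_win_good: float = 0.8
    p_win_bad: float = 0.2
    reward_points: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < self.n_reversals + 1:
            raise ScheduleInfeasibleError(
                f"n_trials={self.n_trials} cannot hold {self.n_reversals} reversals"
            )
        if not (0.0 < self.p_win_bad < self.p_win_good < 1.0):
            raise ValueError("require 0 < p_win_bad < p_win_good < 1")
        if self.block_length_jitter < 0 or self.block_length_mean <= 0:
            raise ValueError("block lengths must be positive")
        min_block = max(1, self.block_length_mean - self.block_length_jitter)
        # the final block only needs >= 1 trial (it absorbs the remainder)
        if self.n_reversals > 0 and self.n_reversals * min_block + 1 > self.n_trials:
            raise ScheduleInfeasibleError(
                "minimal block lengths exceed n_trials: "
                f"{self.n_reversals} blocks of >= {min_block} trials + 1 > {self.n_trials}"
            )


@dataclass
class TaskSchedule:
    """Per-trial arm contingencies for one run of the bandit.

    ``good_arm[t]`` is the arm (0/1) currently at ``p_win_good``;
    ``p_win[t, arm]`` the scheduled win probability; ``reversal_trials``
    the (0-based) indices of the first trial of each new block;
    ``within_block_trial`` restarts at 1 on every reversal and at trial 1.
    """

    good_arm: np.ndarray
    p_win: np.ndarray
    within_block_trial: np.ndarray
    reversal_trials: list[int]
    config: TaskConfig = field(default_factory=TaskConfig)

    @property
    def n_trials(self) -> int:
        return len(self.good_arm)


def generate_task_schedule(
    config: TaskConfig | None = None, rng: np.random.Generator | None = None
) -> TaskSchedule:
    """Draw a reversal schedule.

    Block lengths are sampled uniformly from
    ``{mean - jitter, ..., mean + jitter}``; the final block absorbs the
    remainder so the total is exactly ``n_trials``. Deterministic given
    ``config.seed`` (or an explicit ``rng``).
    """
    config = config or TaskConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    lo = max(1, config.block_length_mean - config.block_length_jitter)
    hi = config.block_length_mean + config.block_length_jitter
    for _ in range(1000):
        lengths = rng.integers(lo, hi + 1, size=config.n_reversals)
        if config.n_trials - int(lengths.sum()) >= 1:
            break
    else:  # pragma: no cover - guarded by TaskConfig feasibility check
        raise ScheduleInfeasibleError("could not place reversals within n_trials")

    reversal_trials = list(np.cumsum(lengths).astype(int)) if config.n_reversals else []

    good_arm = np.empty(config.n_trials, dtype=int)
    within = np.empty(config.n_trials, dtype=int)
    arm = int(rng.integers(2))
    block_start = 0
    bounds = reversal_trials + [config.n_trials]
    for end in bounds:
        good_arm[block_start:end] = arm
        within[block_start:end] = np.arange(1, end - block_start + 1)
        arm = 1 - arm
        block_start = end

    p_win = np.where(
        good_arm[:, None] == np.arange(2)[None, :],
        config.p_win_good,
        config.p_win_bad,
    )
    return TaskSchedule(
        good_arm=good_arm,
        p_win=p_win,
        within_block_trial=within,
        reversal_trials=reversal_trials,
        config=config,
    )
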