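import numpy as np
import pytest

import rpe_memory as rm
from rpe_memory.data import ChoiceDataset
from rpe_memory.task import TaskConfig, TaskSchedule


def make_dataset(choices, rewards, subject="toy") -> ChoiceDataset:
    """Build a minimal ChoiceDataset around explicit choice/reward arrays."""
    choices = np.asarray(choices, dtype=int)
    T = len(choices)
    sched = TaskSchedule(
        good_arm=np.zeros(T, dtype=int),
        p_win=np.tile([0.8, 0.2], (T, 1)),
        within_block_trial=np.arange(1, T + 1),
        reversal_trials=[],
        config=TaskConfig(n_trials=max(T, 1), n_reversals=0),
    )
    return ChoiceDataset(
        subject=subject,
        choices=choices,
        rewards=np.asarray(rewards, dtype=int),
        pm=np.full(T, 2.0),
        schedule=sched,
    )


@pytest.fixture(scope="session")
def rw_cohort():
    """20 value-learning agents on the default task, with true RPEs."""
    cohort = []
    for i in range(20):
        sched = rm.generate_task_schedule(rm.TaskConfig(seed=1000 + i))
        ds = rm.simulate_agent(
            rm.AgentSpec("rw", {"alpha": 0.7, "beta": 5.0}),
            sched,
            seed=2000 + i,
            subject=f"s{i:02d}",
        )
        cohort.append(ds)
    return cohort


@pytest.fixture(scope="session")
def recognition_frame(rw_cohort):
    """Recognition phase for the session cohort with a strong RPE effect."""
    return rm.simulate_recognition(
        rw_cohort,
        [ds.true_rpe for ds in rw_cohort],
        rm.GenerativeMemoryParams(b_rpe=0.5),
        seed=77,
    )
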