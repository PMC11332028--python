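"""Simulate the study cohort and apply the chance-performance exclusion.

Generates 30 value-learning agents on the 60-trial reversal bandit
(cohort learning rates ~ N(0.73, 0.19), inverse temperatures
~ N(4.9, 2.9)), their recognition phase (60 old probes + 60 lures per
subject), and subject traits. Writes tidy CSVs under results/data/.
"""

import sys
from pathlib import Path

import pandas as pd

from rpe_memory.data import write_choices, write_table
from rpe_memory.pipeline import RunConfig, exclude_at_chance, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main(seed: int = 7) -> None:
    config = RunConfig(seed=seed, n_subjects=30, n_survey_extra=60)
    cohort, subjects, recog = simulate_cohort(config)

    retained, excl_log = exclude_at_chance(cohort, config.exclusion_threshold)
    n_excl = len(cohort) - len(retained)
    print(f"simulated {len(cohort)} subjects; excluded {n_excl} at chance "
          f"({excl_log.loc[~excl_log['retained'], 'subject'].tolist()})")
    acc = [ds.accuracy for ds in retained]
    print(f"retained accuracy: mean {sum(acc)/len(acc):.2f} "
          f"(range {min(acc):.2f}-{max(acc):.2f})")

    config.to_json(OUT / "run_config.json")
    write_choices(cohort, OUT / "choices.csv", params={"task": config.task})
    write_table(subjects, OUT / "subjects.csv")
    write_table(recog, OUT / "recognition.csv", params={"memory": config.memory})
    write_table(excl_log, OUT / "exclusions.csv")
    print(f"wrote cohort data to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
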