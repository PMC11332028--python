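"""Does positive affect moderate the link between RPE-reliance and memory?

Regresses subject-level memory sensitivity (d-prime) on each subject's
reliance on RPE (or memorability) for memory — the random slope exported
from the mixed-effects regression — its interaction with the
positive-affect factor score, and accompanies every null coefficient
with a TOST equivalence test against the prespecified [-0.1, 0.1]
bounds.
"""

import dataclasses
import json
import sys
from pathlib import Path

import pandas as pd

from rpe_memory.subject_level import interaction_regression, tost_equivalence

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    table = pd.read_csv(OUT / "subject_table.csv")
    results = {}
    for slope in ("beta_rpe", "beta_pm"):
        terms = interaction_regression(table, "dprime", slope, "f1")
        print(f"d' ~ {slope} * f1:")
        entry = []
        for t in terms:
            rec = dataclasses.asdict(t)
            line = (f"  {t.term:>14}: B={t.B:+.3f} (SE {t.SE:.3f}), p={t.p:.3f}")
            if t.term != "const" and t.p >= 0.05:
                eq = tost_equivalence(t.B, t.SE, t.df_resid)
                rec["tost_p_eq"] = eq.p_eq
                rec["tost_equivalent"] = eq.equivalent
                verdict = "equivalent to 0" if eq.equivalent else "inconclusive"
                line += f"; TOST p_eq={eq.p_eq:.3f} ({verdict})"
            print(line)
            entry.append(rec)
        results[slope] = entry

    (OUT / "moderation.json").write_text(json.dumps(results, indent=2))
    print(f"wrote moderation results to {OUT / 'moderation.json'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
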