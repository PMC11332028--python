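"""Drift-diffusion models of recognition: does RPE or memorability drive
evidence accumulation?

Applies the RT exclusions (300 ms / 10 s absolute bounds, 3-SD
subject-level filter), then fits two hierarchical drift-regression
models on old-probe trials — drift ~ RPE and drift ~ PM, each with a
random intercept and slope per subject and pooled boundary/start/
non-decision parameters — and ranks them by WAIC.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from rpe_memory.data import write_table
from rpe_memory.ddm import DriftRegressionSpec, compare_ddm_models, filter_rts, fit_hier_ddm
from rpe_memory.sampling import MCMCConfig

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 27) -> None:
    recog = pd.read_csv(DATA / "recognition_fitted.csv")
    filtered, report = filter_rts(recog)
    print(f"RT filter: {report.n_input} -> {report.n_retained} trials "
          f"(fast {report.n_excluded_fast}, slow {report.n_excluded_slow}, "
          f"3-SD {report.n_excluded_sd})")

    fits = {}
    for j, cov in enumerate(("rpe", "pm")):
        fits[cov] = fit_hier_ddm(
            filtered, DriftRegressionSpec(covariate=cov), MCMCConfig(4, 800, 800, seed=seed + j)
        )
        lo, hi = fits[cov].hdi("v_slope")
        mean = fits[cov].summary.set_index("parameter").loc["v_slope", "mean"]
        print(f"drift ~ {cov}: slope {mean:.3f} [95% HDI {lo:.3f}, {hi:.3f}], "
              f"WAIC {fits[cov].waic:.1f}, max R-hat {fits[cov].max_rhat:.3f}")

    ranking = compare_ddm_models(fits)
    print(f"preferred drift model: {ranking.iloc[0]['model']} "
          f"(dWAIC to runner-up {ranking.iloc[1]['d_waic']:.1f} "
          f"+/- {ranking.iloc[1]['d_se']:.1f})")

    write_table(
        pd.concat([f.summary.assign(model=m) for m, f in fits.items()], ignore_index=True),
        OUT / "ddm_summary.csv",
    )
    (OUT / "ddm_comparison.json").write_text(
        json.dumps(
            {
                "ranking": ranking.to_dict(orient="records"),
                "rt_exclusions": {
                    "n_input": report.n_input,
                    "fast": report.n_excluded_fast,
                    "slow": report.n_excluded_slow,
                    "sd": report.n_excluded_sd,
                },
            },
            indent=2,
        )
    )
    print(f"wrote DDM results to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 27)
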