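"""Mixed-effects logistic regression of memory success.

Codes hits and correct rejections as correct, misses and false alarms as
incorrect, and regresses correctness on trial-level RPE, memorability
and within-block trial plus subject-level traits (age, sex, fitted RL
parameters, total reward, positive-affect factor score), with random
intercepts and random RPE/PM slopes per subject. Effects are declared
meaningful when the 95% HDI excludes zero. Also computes per-subject
d-prime and exports the per-subject random slopes for the moderation
analysis.
"""

import sys
from pathlib import Path

import pandas as pd

from rpe_memory.data import write_table
from rpe_memory.memory_glm import GLMDesign, categorize_responses, compute_dprime, fit_memory_glm
from rpe_memory.sampling import MCMCConfig

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 47) -> None:
    recog = pd.read_csv(DATA / "recognition_fitted.csv")
    subjects = pd.read_csv(DATA / "subjects.csv")
    rl_params = pd.read_csv(OUT / "rl_params.csv")
    scores = pd.read_csv(OUT / "factor_scores.csv")

    labeled = categorize_responses(recog)
    subj_cov = (
        subjects.merge(rl_params[["subject", "alpha", "beta"]], on="subject")
        .merge(scores[["subject", "f1"]], on="subject")
    )
    design = GLMDesign(
        fixed=("rpe", "pm", "within_block_trial", "age", "sex", "alpha", "beta",
               "total_reward", "f1")
    )
    fit = fit_memory_glm(labeled, design, subjects=subj_cov,
                         mcmc=MCMCConfig(4, 2000, 2000, seed=seed))

    print("fixed effects (mean [95% HDI], * = excludes zero):")
    for _, row in fit.fixed_effects.iterrows():
        star = " *" if row["meaningful"] else ""
        print(f"  {row['term']:>20}: {row['mean']:+.3f} "
              f"[{row['hdi_low']:+.3f}, {row['hdi_high']:+.3f}]{star}")
    print(f"max R-hat {fit.max_rhat:.3f}, WAIC {fit.waic:.1f}")

    dprimes = (
        labeled.groupby("subject")
        .apply(compute_dprime, include_groups=False)
        .rename("dprime")
        .reset_index()
    )
    print(f"cohort d': mean {dprimes['dprime'].mean():.2f} "
          f"(range {dprimes['dprime'].min():.2f}-{dprimes['dprime'].max():.2f})")

    subj_table = (
        pd.DataFrame(
            {
                "subject": fit.subject_beta_rpe.index,
                "beta_rpe": fit.subject_beta_rpe.to_numpy(),
                "beta_pm": fit.subject_beta_pm.to_numpy(),
            }
        )
        .merge(dprimes, on="subject")
        .merge(scores[["subject", "f1"]], on="subject")
    )
    write_table(fit.fixed_effects, OUT / "glm_summary.csv")
    write_table(subj_table, OUT / "subject_table.csv")
    print(f"wrote GLM results to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 47)
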