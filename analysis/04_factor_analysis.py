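"""Transdiagnostic factor analysis of the symptom surveys.

Generates Likert responses for the task cohort plus extra survey-only
respondents, checks sampling adequacy (KMO) and sphericity (Bartlett),
selects the factor count with the CNG scree test, extracts factors by
maximum likelihood with a promax rotation, and computes ten Berge
(correlation-preserving) factor scores for the task subjects.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from rpe_memory.data import write_table
from rpe_memory.factors import bartlett, cng_nfactors, fit_factor_model, kmo, score_tenberge
from rpe_memory.surveys import default_survey_params, generate_surveys, recode_reverse

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 37) -> None:
    subjects = pd.read_csv(DATA / "subjects.csv")
    params = default_survey_params(n_respondents=len(subjects) + 290, seed=seed)
    surveys = generate_surveys(params)
    recoded = recode_reverse(surveys, params.likert_levels)
    print(f"surveys: {recoded.shape[0]} respondents x {recoded.shape[1]} items "
          f"({len(subjects)} task subjects + {recoded.shape[0]-len(subjects)} survey-only)")

    kmo_overall, _ = kmo(recoded)
    chi2, dfree, pval = bartlett(recoded)
    print(f"KMO = {kmo_overall:.2f}; Bartlett chi2({dfree}) = {chi2:.0f}, p = {pval:.2g}")

    ev = np.sort(np.linalg.eigvalsh(np.corrcoef(recoded.to_numpy().T)))[::-1]
    k = cng_nfactors(ev)
    print(f"CNG factor count: {k} (leading eigenvalues {np.round(ev[:5], 2).tolist()})")

    sol = fit_factor_model(recoded, k)
    scores = score_tenberge(sol, recoded).iloc[: len(subjects)].set_index(subjects["subject"])
    offdiag = sol.factor_corr[~np.eye(k, dtype=bool)]
    print(f"factor correlations (off-diagonal): {np.round(np.unique(offdiag.round(2)), 2).tolist()}")

    write_table(sol.loadings.reset_index(names="item"), OUT / "factor_loadings.csv")
    write_table(scores.reset_index(), OUT / "factor_scores.csv")
    (OUT / "factor_adequacy.json").write_text(
        json.dumps(
            {"kmo": kmo_overall, "bartlett_chi2": chi2, "bartlett_df": dfree,
             "bartlett_p": pval, "k": int(k), "factor_corr": sol.factor_corr.tolist(),
             "heywood": sol.heywood},
            indent=2,
        )
    )
    print(f"wrote factor solution to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 37)
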