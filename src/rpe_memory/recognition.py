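"""Generative model of the recognition-memory phase.

For every bandit trial the encoded stimulus returns as an "old" probe,
accompanied by an equal number of novel lures whose memorability ratings
are drawn from the same stimulus pool. The probability of a correct
old/new judgment follows a logistic model in standardized encoding RPE,
stimulus memorability and within-block trial (RPE and trial are defined
for old probes only and zero-imputed — i.e. held at the mean — for
lures), with per-subject random intercepts and RPE/PM slopes. Reaction
times come from a drift-diffusion process whose drift is modulated by
the same standardized covariates; the baseline drift points toward the
"old" boundary for old probes and toward "new" for lures.

Two coupling modes:

* default — the response is drawn from the logistic model and the RT is
  the (unconditional) diffusion first-passage time;
* ``couple_rt_to_response=True`` — response and RT are generated jointly
  by the diffusion (response = boundary reached), for studies of the
  choice/RT model itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .agents import sample_memorability
from .data import RECOGNITION_COLUMNS, ChoiceDataset
from .memory_glm import standardize
from .wfpt import simulate_wfpt

__all__ = ["DDMGenParams", "GenerativeMemoryParams", "simulate_recognition"]


@dataclass(frozen=True)
class DDMGenParams:
    """Diffusion parameters of the recognition RT process."""

    a: float = 1.8          # boundary separation (evidence units)
    z: float = 0.5          # relative start point
    t: float = 0.35         # non-decision time (s)
    v0: float = 0.8         # baseline drift toward the correct boundary
    v_rpe: float = 0.046    # drift slope per standardized RPE unit
    v_pm: float = 0.038     # drift slope per standardized PM unit

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if not 0 < self.z < 1:
            raise ValueError("z must lie in (0, 1)")
        if self.t < 0:
            raise ValueError("t must be >= 0")


@dataclass(frozen=True)
class GenerativeMemoryParams:
    """Log-odds coefficients of memory success (on 2-SD standardized
    covariates) plus the RT diffusion parameters. Defaults follow the
    fitted group-level effects the design is meant to emulate."""

    b0: float = 1.0
    b_rpe: float = 0.17
    b_pm: float = 0.16
    b_trial: float = -0.12
    subject_sd: float = 0.5
    b_rpe_sd: float = 0.2   # SD of per-subject RPE slopes
    b_pm_sd: float = 0.2    # SD of per-subject PM slopes
    ddm: DDMGenParams = field(default_factory=DDMGenParams)


def simulate_recognition(
    choices: ChoiceDataset | Sequence[ChoiceDataset],
    rpes: np.ndarray | Sequence[np.ndarray],
    params: GenerativeMemoryParams | None = None,
    seed: int | np.random.Generator | None = None,
    couple_rt_to_response: bool = False,
    return_truth: bool = False,
    rt_dt: float = 1e-3,
):
    """Generate old/new probes, responses, RTs and confidence ratings.

    ``rpes`` must align with ``choices`` (one per-trial array per
    subject). Covariates are standardized across the supplied cohort, so
    pass the full cohort at once. Returns a tidy frame (one row per
    probe, order randomized within subject); with ``return_truth=True``
    also returns the per-subject generative effects.
    """
    params = params or GenerativeMemoryParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cohort = [choices] if isinstance(choices, ChoiceDataset) else list(choices)
    rpe_list = [np.asarray(rpes)] if isinstance(choices, ChoiceDataset) else [np.asarray(r) for r in rpes]
    if len(rpe_list) != len(cohort):
        raise ValueError("rpes must align with choices (one array per subject)")
    for ds, r in zip(cohort, rpe_list):
        if len(r) != ds.n_trials:
            raise ValueError(f"subject {ds.subject}: {len(r)} RPEs for {ds.n_trials} trials")

    rows = []
    for s_i, (ds, rpe) in enumerate(zip(cohort, rpe_list)):
        n = ds.n_trials
        rows.append(
            pd.DataFrame(
                {
                    "subject": ds.subject,
                    "subject_index": s_i,
                    "probe": [f"{ds.subject}_old_{t+1:03d}" for t in range(n)],
                    "is_old": True,
                    "pm": ds.pm,
                    "rpe": rpe,
                    "encoding_trial": ds.schedule.within_block_trial,
                    "encoding_index": np.arange(1, n + 1),
                }
            )
        )
        rows.append(
            pd.DataFrame(
                {
                    "subject": ds.subject,
                    "subject_index": s_i,
                    "probe": [f"{ds.subject}_lure_{t+1:03d}" for t in range(n)],
                    "is_old": False,
                    "pm": sample_memorability(rng, n),
                    "rpe": np.nan,
                    "encoding_trial": np.nan,
                    "encoding_index": np.nan,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    is_old = df["is_old"].to_numpy()

    rpe_std = np.zeros(len(df))
    trial_std = np.zeros(len(df))
    rpe_std[is_old] = standardize(df.loc[is_old, "rpe"].to_numpy())
    trial_std[is_old] = standardize(df.loc[is_old, "encoding_trial"].to_numpy())
    pm_std = standardize(df["pm"].to_numpy())

    n_subj = len(cohort)
    u0 = rng.normal(0.0, params.subject_sd, size=n_subj) if params.subject_sd > 0 else np.zeros(n_subj)
    u_rpe = rng.normal(0.0, params.b_rpe_sd, size=n_subj) if params.b_rpe_sd > 0 else np.zeros(n_subj)
    u_pm = rng.normal(0.0, params.b_pm_sd, size=n_subj) if params.b_pm_sd > 0 else np.zeros(n_subj)
    sidx = df["subject_index"].to_numpy()

    eta = (
        params.b0
        + u0[sidx]
        + (params.b_rpe + u_rpe[sidx]) * rpe_std
        + (params.b_pm + u_pm[sidx]) * pm_std
        + params.b_trial * trial_std
    )
    correct = rng.random(len(df)) < expit(eta)

    d = params.ddm
    drift = np.where(is_old, d.v0, -d.v0) + d.v_rpe * rpe_std + d.v_pm * pm_std
    rt, boundary = simulate_wfpt(len(df), drift, d.a, d.z, d.t, rng, dt=rt_dt)

    if couple_rt_to_response:
        response = np.where(boundary == 1, "old", "new")
    else:
        response = np.where(correct == is_old, "old", "new")
    df["response"] = response
    df["rt"] = rt
    df["confidence"] = rng.integers(1, 5, size=len(df))

    # randomize probe order within subject
    df = (
        df.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31 - 1)))
        .sort_values("subject_index", kind="stable")
        .reset_index(drop=True)[RECOGNITION_COLUMNS + ["encoding_index"]]
    )

    if return_truth:
        truth = pd.DataFrame(
            {
                "subject": [ds.subject for ds in cohort],
                "u_intercept": u0,
                "beta_rpe": params.b_rpe + u_rpe,
                "beta_pm": params.b_pm + u_pm,
            }
        )
        return df, truth
    return df
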