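"""End-to-end orchestration on synthetic cohorts.

``run_pipeline`` simulates a cohort (bandit behavior, recognition phase,
surveys), applies the chance-performance exclusion, fits and compares
the three decision models, extracts RPEs from the winning value-learning
model, fits the drift-regression DDMs and the memory GLM, runs the
factor analysis, and finishes with the subject-level moderation and
equivalence analyses. Every stage is seeded from the run seed, logged,
and written to its own artifact file; the final report is assembled by
reading those artifact files only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .agents import AgentSpec, simulate_agent
from .data import ChoiceDataset, write_choices, write_table
from .ddm import DriftRegressionSpec, compare_ddm_models, filter_rts, fit_hier_ddm
from .factors import bartlett, cng_nfactors, fit_factor_model, kmo, score_tenberge
from .memory_glm import (
    GLMDesign,
    categorize_responses,
    compute_dprime,
    fit_memory_glm,
)
from .recognition import GenerativeMemoryParams, simulate_recognition
from .rl import compare_models, extract_rpes, fit_model
from .sampling import MCMCConfig
from .subject_level import interaction_regression, tost_equivalence
from .surveys import SurveyGenParams, default_survey_params, generate_surveys, recode_reverse
from .task import TaskConfig, generate_task_schedule

__all__ = [
    "CohortParams",
    "SamplerSettings",
    "RunConfig",
    "PipelineStageError",
    "ReportBundle",
    "exclude_at_chance",
    "simulate_cohort",
    "attach_model_rpes",
    "run_pipeline",
]

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage


@dataclass(frozen=True)
class CohortParams:
    """Distributions of subject traits and generative RL parameters."""

    alpha_mean: float = 0.73
    alpha_sd: float = 0.19
    beta_mean: float = 4.9
    beta_sd: float = 2.9
    age_mean: float = 40.0
    age_sd: float = 14.0


@dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000

    def mcmc(self, seed: int) -> MCMCConfig:
        return MCMCConfig(self.chains, self.draws, self.warmup, seed=seed)


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 30
    n_survey_extra: int = 60
    task: TaskConfig = field(default_factory=TaskConfig)
    memory: GenerativeMemoryParams = field(default_factory=GenerativeMemoryParams)
    cohort: CohortParams = field(default_factory=CohortParams)
    rl_sampler: SamplerSettings = field(default_factory=lambda: SamplerSettings(4, 1000, 1000))
    ddm_sampler: SamplerSettings = field(default_factory=lambda: SamplerSettings(4, 800, 800))
    glm_sampler: SamplerSettings = field(default_factory=lambda: SamplerSettings(4, 800, 800))
    exclusion_threshold: float = 0.05
    n_factors: int | None = None  # None = select by CNG

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=_default))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        from .recognition import DDMGenParams

        d["task"] = TaskConfig(**d["task"])
        mem = d["memory"]
        mem["ddm"] = DDMGenParams(**mem["ddm"])
        d["memory"] = GenerativeMemoryParams(**mem)
        d["cohort"] = CohortParams(**d["cohort"])
        for k in ("rl_sampler", "ddm_sampler", "glm_sampler"):
            d[k] = SamplerSettings(**d[k])
        return cls(**d)


def _default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(type(o))


# ---------------------------------------------------------------------------
# simulation + exclusion
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: RunConfig,
) -> tuple[list[ChoiceDataset], pd.DataFrame, pd.DataFrame]:
    """Simulate bandit behavior, subject traits and the recognition phase.

    Returns (choice datasets, subjects table, recognition table). The
    recognition phase is generated from the agents' true RPE series; the
    analysis pipeline later replaces them with model-derived estimates,
    mirroring the real workflow.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    c = config.cohort
    cohort: list[ChoiceDataset] = []
    subj_rows = []
    for i in range(config.n_subjects):
        alpha = float(np.clip(rng.normal(c.alpha_mean, c.alpha_sd), 0.05, 0.98))
        beta = float(np.clip(rng.normal(c.beta_mean, c.beta_sd), 0.5, 12.0))
        sched = generate_task_schedule(config.task, rng)
        ds = simulate_agent(
            AgentSpec("rw", {"alpha": alpha, "beta": beta}), sched, rng, subject=f"s{i:03d}"
        )
        cohort.append(ds)
        subj_rows.append(
            {
                "subject": ds.subject,
                "true_alpha": alpha,
                "true_beta": beta,
                "age": float(np.clip(rng.normal(c.age_mean, c.age_sd), 18, 80)),
                "sex": "female" if rng.random() < 0.5 else "male",
                "total_reward": ds.total_reward,
            }
        )
    subjects = pd.DataFrame(subj_rows)
    recog = simulate_recognition(
        cohort,
        [ds.true_rpe for ds in cohort],
        config.memory,
        seed=rng,
    )
    return cohort, subjects, recog


def exclude_at_chance(
    cohort: list[ChoiceDataset], threshold: float = 0.05
) -> tuple[list[ChoiceDataset], pd.DataFrame]:
    """Drop subjects whose decision accuracy is not above chance.

    Accuracy is the proportion of higher-probability-arm choices; a
    subject is retained when a one-sided exact binomial test rejects
    p = 0.5 in the above-chance direction at ``threshold``.
    """
    rows = []
    retained = []
    for ds in cohort:
        k = int((ds.choices == ds.schedule.good_arm).sum())
        n = ds.n_trials
        p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
        keep = p <= threshold
        rows.append(
            {"subject": ds.subject, "n_good": k, "n_trials": n, "p_value": float(p), "retained": bool(keep)}
        )
        if keep:
            retained.append(ds)
    return retained, pd.DataFrame(rows)


def attach_model_rpes(
    recog: pd.DataFrame,
    cohort: list[ChoiceDataset],
    rw_fits: dict[str, "object"],
) -> pd.DataFrame:
    """Replace generative RPEs with model-derived estimates.

    ``rw_fits`` maps subject id to an RW ModelFit; old probes get the
    RPE of their encoding trial under the posterior-mean learning rate,
    mirroring how the analysis sees real data (the generative teaching
    signal is not observable)."""
    frames = []
    by_subject = {ds.subject: ds for ds in cohort}
    for subject, fit in rw_fits.items():
        ds = by_subject[subject]
        series = extract_rpes(fit, ds)
        sub = recog[recog["subject"] == subject].copy()
        old = sub["is_old"].astype(bool)
        enc = sub.loc[old, "encoding_index"].astype(int).to_numpy() - 1
        sub.loc[old, "rpe"] = series.rpe[enc]
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    report: dict
    outdir: Path
    artifacts: dict[str, Path]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s ...", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig, outdir: str | Path) -> ReportBundle:
    """Run every stage on a synthetic cohort and write all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(12)]

    config.to_json(outdir / "run_config.json")
    artifacts["config"] = outdir / "run_config.json"

    # -- simulate ----------------------------------------------------------
    simulate = _stage("simulate")(simulate_cohort)
    cohort, subjects, recog = simulate(config)
    artifacts["choices"] = write_choices(
        cohort, outdir / "choices.csv", params={"task": config.task, "cohort": config.cohort}
    )
    artifacts["recognition"] = write_table(
        recog, outdir / "recognition.csv", params={"memory": config.memory}
    )
    artifacts["subjects"] = write_table(subjects, outdir / "subjects.csv")

    # -- chance-level exclusion -------------------------------------------
    excl = _stage("exclude")(exclude_at_chance)
    retained, excl_log = excl(cohort, config.exclusion_threshold)
    artifacts["exclusions"] = write_table(excl_log, outdir / "exclusions.csv")
    if len(retained) < 3:
        raise PipelineStageError("exclude", RuntimeError("fewer than 3 subjects retained"))
    kept_ids = {ds.subject for ds in retained}
    subjects = subjects[subjects["subject"].isin(kept_ids)].reset_index(drop=True)
    recog = recog[recog["subject"].isin(kept_ids)].reset_index(drop=True)

    # -- decision models ---------------------------------------------------
    @_stage("fit_rl")
    def fit_rl():
        rng = np.random.default_rng(seeds[1])
        fits_by_subject = []
        for ds in retained:
            fits = {
                m: fit_model(
                    m, ds, config.rl_sampler.mcmc(int(rng.integers(2**31 - 1))),
                    keep_pointwise=False,
                )
                for m in ("rw", "wsls", "bayes")
            }
            fits_by_subject.append(fits)
        comparison = compare_models(fits_by_subject)
        return fits_by_subject, comparison

    fits_by_subject, comparison = fit_rl()
    rl_params = pd.DataFrame(
        [
            {
                "subject": fits["rw"].subject,
                "alpha": fits["rw"].point_estimate["alpha"],
                "beta": fits["rw"].point_estimate["beta"],
                "max_rhat": max(f.max_rhat for f in fits.values()),
                "winner": comparison.winners[fits["rw"].subject],
            }
            for fits in fits_by_subject
        ]
    )
    artifacts["rl_params"] = write_table(rl_params, outdir / "rl_params.csv")
    rl_report = {
        "winner_counts": comparison.counts,
        "chi2": comparison.chi2,
        "chi2_p": comparison.chi2_p,
        "max_rhat": float(rl_params["max_rhat"].max()),
    }
    (outdir / "rl_comparison.json").write_text(json.dumps(rl_report, indent=2))
    artifacts["rl_comparison"] = outdir / "rl_comparison.json"

    # -- model-derived RPEs into the recognition table ---------------------
    recog_fitted = _stage("extract_rpes")(attach_model_rpes)(
        recog, retained, {fits["rw"].subject: fits["rw"] for fits in fits_by_subject}
    )

    # -- drift-diffusion models -------------------------------------------
    @_stage("fit_ddm")
    def fit_ddms():
        filtered, rt_report = filter_rts(recog_fitted)
        fits = {}
        for i, cov in enumerate(("rpe", "pm")):
            fits[cov] = fit_hier_ddm(
                filtered,
                DriftRegressionSpec(covariate=cov),
                config.ddm_sampler.mcmc(seeds[2 + i]),
            )
        ranking = compare_ddm_models(fits)
        return fits, ranking, rt_report

    ddm_fits, ddm_ranking, rt_report = fit_ddms()
    artifacts["ddm_summary"] = write_table(
        pd.concat(
            [f.summary.assign(model=name) for name, f in ddm_fits.items()], ignore_index=True
        ),
        outdir / "ddm_summary.csv",
    )
    ddm_report = {
        "ranking": ddm_ranking.to_dict(orient="records"),
        "rt_exclusions": {
            "n_input": rt_report.n_input,
            "n_excluded_fast": rt_report.n_excluded_fast,
            "n_excluded_slow": rt_report.n_excluded_slow,
            "n_excluded_sd": rt_report.n_excluded_sd,
        },
        "max_rhat": float(max(f.max_rhat for f in ddm_fits.values())),
    }
    (outdir / "ddm_comparison.json").write_text(json.dumps(ddm_report, indent=2))
    artifacts["ddm_comparison"] = outdir / "ddm_comparison.json"

    # -- factor analysis ----------------------------------------------------
    @_stage("factors")
    def run_factors():
        params = default_survey_params(
            n_respondents=len(subjects) + config.n_survey_extra, seed=seeds[5]
        )
        surveys = generate_surveys(params)
        recoded = recode_reverse(surveys, params.likert_levels)
        kmo_overall, _ = kmo(recoded)
        if len(recoded) > recoded.shape[1]:
            chi2, dfree, pval = bartlett(recoded)
        else:  # too few respondents for the sphericity test
            chi2 = dfree = pval = None
        ev = np.sort(np.linalg.eigvalsh(np.corrcoef(recoded.to_numpy().T)))[::-1]
        k = config.n_factors or cng_nfactors(ev)
        sol = fit_factor_model(recoded, k)
        scores = score_tenberge(sol, recoded).iloc[: len(subjects)]
        scores = scores.set_index(subjects["subject"])
        return surveys, {"kmo": kmo_overall, "bartlett_chi2": chi2, "bartlett_df": dfree,
                         "bartlett_p": pval, "k": int(k)}, sol, scores

    surveys, adequacy, sol, scores = run_factors()
    artifacts["surveys"] = write_table(surveys.responses, outdir / "surveys.csv")
    artifacts["factor_loadings"] = write_table(
        sol.loadings.reset_index(names="item"), outdir / "factor_loadings.csv"
    )
    artifacts["factor_scores"] = write_table(
        scores.reset_index(), outdir / "factor_scores.csv"
    )
    adequacy["factor_corr"] = sol.factor_corr.tolist()
    (outdir / "factor_adequacy.json").write_text(json.dumps(adequacy, indent=2))
    artifacts["factor_adequacy"] = outdir / "factor_adequacy.json"

    # -- memory GLM ---------------------------------------------------------
    @_stage("memory_glm")
    def run_glm():
        labeled = categorize_responses(recog_fitted)
        subj_cov = subjects.merge(
            rl_params[["subject", "alpha", "beta"]], on="subject"
        ).merge(scores.reset_index()[["subject", "f1"]], on="subject")
        design = GLMDesign(
            fixed=("rpe", "pm", "within_block_trial", "age", "sex", "alpha", "beta",
                   "total_reward", "f1")
        )
        fit = fit_memory_glm(
            labeled, design, subjects=subj_cov, mcmc=config.glm_sampler.mcmc(seeds[4])
        )
        dprimes = labeled.groupby("subject").apply(compute_dprime, include_groups=False)
        return labeled, fit, dprimes.rename("dprime")

    labeled, glm_fit, dprimes = run_glm()
    artifacts["glm_summary"] = write_table(glm_fit.fixed_effects, outdir / "glm_summary.csv")

    # -- subject-level moderation ------------------------------------------
    @_stage("subject_level")
    def run_subject_level():
        table = (
            pd.DataFrame(
                {
                    "subject": glm_fit.subject_beta_rpe.index,
                    "beta_rpe": glm_fit.subject_beta_rpe.to_numpy(),
                    "beta_pm": glm_fit.subject_beta_pm.to_numpy(),
                }
            )
            .merge(dprimes.reset_index(), on="subject")
            .merge(scores.reset_index()[["subject", "f1"]], on="subject")
        )
        results = {}
        for slope in ("beta_rpe", "beta_pm"):
            terms = interaction_regression(table, "dprime", slope, "f1")
            entry = []
            for t in terms:
                rec = dataclasses.asdict(t)
                if t.term != "const" and t.p >= 0.05:
                    eq = tost_equivalence(t.B, t.SE, t.df_resid)
                    rec["tost_p_eq"] = eq.p_eq
                    rec["tost_equivalent"] = eq.equivalent
                entry.append(rec)
            results[slope] = entry
        return table, results

    subj_table, moderation = run_subject_level()
    artifacts["subject_table"] = write_table(subj_table, outdir / "subject_table.csv")
    (outdir / "moderation.json").write_text(json.dumps(moderation, indent=2))
    artifacts["moderation"] = outdir / "moderation.json"

    # -- final report: assembled strictly from artifact files ---------------
    @_stage("report")
    def build_report() -> dict:
        report = {
            "seed": config.seed,
            "n_simulated": config.n_subjects,
            "n_retained": int(
                pd.read_csv(artifacts["exclusions"])["retained"].sum()
            ),
            "decision_models": json.loads(artifacts["rl_comparison"].read_text()),
            "ddm": json.loads(artifacts["ddm_comparison"].read_text()),
            "memory_glm": pd.read_csv(artifacts["glm_summary"]).to_dict(orient="records"),
            "factors": json.loads(artifacts["factor_adequacy"].read_text()),
            "moderation": json.loads(artifacts["moderation"].read_text()),
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        return report

    report = build_report()
    artifacts["report"] = outdir / "report.json"
    return ReportBundle(report=report, outdir=outdir, artifacts=artifacts)
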