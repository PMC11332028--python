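"""Recognition-memory analysis: response labels, d-prime, the 2-SD
standardization rule, and the Bayesian mixed-effects logistic regression
of memory success.

Memory outcomes are coded correct (hits and correct rejections) versus
incorrect (misses and false alarms). The log-odds of a correct response
are modeled as fixed effects of trial-level predictors (encoding RPE,
stimulus memorability PM, within-block trial) and optional subject-level
traits, plus a per-subject random intercept and random RPE/PM slopes.
All numeric predictors are standardized by centering and dividing by two
standard deviations, so binary and continuous predictors are on a
comparable scale. An effect is called meaningful when its 95% highest
density interval excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .sampling import MCMCConfig, ParamSpec, hier_remix, rhat_max, run_hier_mh

__all__ = [
    "GLMDesign",
    "GLMFit",
    "categorize_responses",
    "compute_dprime",
    "standardize",
    "fit_memory_glm",
    "SeparationError",
]

log = logging.getLogger(__name__)


class SeparationError(ValueError):
    """Outcome is degenerate (all correct or all incorrect)."""


def categorize_responses(data: pd.DataFrame) -> pd.DataFrame:
    """Add 4-way response labels and a correct flag.

    hits and correct rejections are correct; misses and false alarms are
    incorrect. Rows with a missing response are dropped with a log entry.
    """
    out = data.copy()
    missing = out["response"].isna()
    if missing.any():
        log.warning("dropping %d probes with missing responses", int(missing.sum()))
        out = out.loc[~missing].copy()
    is_old = out["is_old"].astype(bool)
    said_old = out["response"].astype(str) == "old"
    out["label"] = np.select(
        [is_old & said_old, is_old & ~said_old, ~is_old & ~said_old, ~is_old & said_old],
        ["hit", "miss", "correct_rejection", "false_alarm"],
        default="",
    )
    out["correct"] = out["label"].isin(["hit", "correct_rejection"]).astype(int)
    return out


def compute_dprime(labeled: pd.DataFrame) -> float:
    """Signal-detection sensitivity from labeled probes of one subject.

    d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate). Extreme rates are
    clamped to [1/(2N), 1 - 1/(2N)] before inversion, with N the number
    of old probes (for the hit rate) or lures (for the FA rate).
    """
    is_old = labeled["is_old"].astype(bool)
    n_old = int(is_old.sum())
    n_new = int((~is_old).sum())
    if n_old == 0 or n_new == 0:
        raise ValueError("d' requires at least one old probe and one lure")
    hit_rate = (labeled.loc[is_old, "label"] == "hit").mean()
    fa_rate = (labeled.loc[~is_old, "label"] == "false_alarm").mean()
    hit_rate = float(np.clip(hit_rate, 1 / (2 * n_old), 1 - 1 / (2 * n_old)))
    fa_rate = float(np.clip(fa_rate, 1 / (2 * n_new), 1 - 1 / (2 * n_new)))
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


def standardize(x: np.ndarray) -> np.ndarray:
    """Center and divide by twice the sample SD (n-1 denominator).

    The output has mean 0 and SD 0.5, putting numeric predictors on the
    scale of a +/-0.5 coded binary predictor.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / (2.0 * sd)


@dataclass(frozen=True)
class GLMDesign:
    """Predictors of the memory regression.

    ``fixed`` lists trial-level columns ('rpe', 'pm', 'within_block_trial')
    and/or subject-level columns present in the subjects table; numeric
    predictors are 2-SD standardized, 'sex' is coded +/-0.5. Random
    effects: per-subject intercept and optional RPE/PM slopes.
    """

    fixed: tuple[str, ...] = ("rpe", "pm", "within_block_trial")
    random_intercept: bool = True
    random_rpe: bool = True
    random_pm: bool = True


@dataclass
class GLMFit:
    fixed_effects: pd.DataFrame        # term, mean, hdi_low, hdi_high, meaningful
    draws: dict[str, np.ndarray]       # (chains, draws) per fixed effect and SD
    subject_beta_rpe: pd.Series | None  # total per-subject RPE slope
    subject_beta_pm: pd.Series | None
    rhat: dict[str, float]
    waic: float
    waic_se: float
    design: GLMDesign

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


def _hdi(d: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    arr = az.hdi(np.asarray(d).reshape(-1), hdi_prob=prob)
    return float(arr[0]), float(arr[1])


def build_design_matrix(
    labeled: pd.DataFrame,
    design: GLMDesign,
    subjects: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Assemble the standardized fixed-effect matrix (with intercept).

    Trial-level RPE and within-block trial are standardized over old
    probes and zero-imputed (i.e. set to the mean) on lures; PM is
    standardized over all probes. Subject-level numeric covariates are
    standardized across subjects; sex is sum-coded (+/-0.5).
    """
    df = labeled.copy()
    if subjects is not None:
        df = df.merge(subjects, on="subject", how="left", suffixes=("", "_subj"))
    is_old = df["is_old"].astype(bool).to_numpy()
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    std_cols: dict[str, np.ndarray] = {}
    for term in design.fixed:
        if term in ("rpe", "within_block_trial", "encoding_trial"):
            col = term
            if col not in df.columns and term == "within_block_trial":
                col = "encoding_trial"
            vals = df[col].to_numpy(dtype=float)
            out = np.zeros(len(df))
            out[is_old] = standardize(vals[is_old])
            std_cols[term] = out
        elif term == "sex":
            sex = df["sex"].astype(str).to_numpy()
            levels = sorted(pd.unique(sex))
            if len(levels) != 2:
                raise ValueError("sex must be a two-level categorical")
            out = np.where(sex == levels[0], -0.5, 0.5)
            std_cols[term] = out
        else:
            std_cols[term] = standardize(df[term].to_numpy(dtype=float))
        cols.append(std_cols[term])
        names.append(term)
    X = np.column_stack(cols)
    return X, names, df


def fit_memory_glm(
    labeled: pd.DataFrame,
    design: GLMDesign | None = None,
    subjects: pd.DataFrame | None = None,
    mcmc: MCMCConfig | None = None,
) -> GLMFit:
    """Bayesian mixed-effects logistic regression of memory success.

    Priors: Normal(0, 2.5) on standardized fixed effects,
    HalfNormal(1) on random-effect SDs. Sampling is by
    Metropolis-within-Gibbs with 4 chains; R-hat is reported per
    parameter and flagged above the configured bound.
    """
    design = design or GLMDesign()
    mcmc = mcmc or MCMCConfig(draws=1000, warmup=1000)
    if "correct" not in labeled:
        raise ValueError("run categorize_responses first (missing 'correct' column)")
    y_all = labeled["correct"].to_numpy(dtype=float)
    if y_all.min() == y_all.max():
        raise SeparationError("outcome is constant; the logistic model is degenerate")

    X, names, df = build_design_matrix(labeled, design, subjects)
    order = np.argsort(df["subject"].astype(str).to_numpy(), kind="stable")
    X = X[order]
    df = df.iloc[order]
    y = df["correct"].to_numpy(dtype=float)
    subjects_list = [str(s) for s in df["subject"].astype(str).unique()]
    subj_idx = df["subject"].astype(str).map({s: i for i, s in enumerate(subjects_list)}).to_numpy()
    n_subj = len(subjects_list)
    p = X.shape[1]

    x_rpe = X[:, names.index("rpe")] if "rpe" in names else None
    x_pm = X[:, names.index("pm")] if "pm" in names else None

    rand_cols: list[str] = []
    if design.random_intercept:
        rand_cols.append("intercept")
    if design.random_rpe and x_rpe is not None:
        rand_cols.append("rpe")
    if design.random_pm and x_pm is not None:
        rand_cols.append("pm")
    k = len(rand_cols)

    sd_specs = [
        ParamSpec(f"sd_{c}", "log", logprior=lambda v: -0.5 * v**2,
                  init_lo=np.log(0.2), init_hi=np.log(0.8))
        for c in rand_cols
    ]

    def unpack(xs: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        betas = xs[:, :p]
        sds = {
            s.name: s.to_natural(xs[:, p + j]) for j, s in enumerate(sd_specs)
        }
        return betas, sds

    def linpred(betas: np.ndarray, sds: dict[str, np.ndarray], xu: np.ndarray) -> np.ndarray:
        # non-centered random effects: deviation = sd * raw, raw ~ N(0, 1)
        eta = betas @ X.T
        for j, c in enumerate(rand_cols):
            dev = sds[f"sd_{c}"][:, None] * xu[:, subj_idx, j]
            if c == "intercept":
                eta = eta + dev
            elif c == "rpe":
                eta = eta + dev * x_rpe[None, :]
            else:
                eta = eta + dev * x_pm[None, :]
        return eta

    seg = np.flatnonzero(np.r_[1, np.diff(subj_idx)])

    def loglik(xs: np.ndarray, xu: np.ndarray) -> np.ndarray:
        betas, sds = unpack(xs)
        eta = linpred(betas, sds, xu)
        # Bernoulli log-likelihood: y*eta - log(1 + exp(eta))
        lp = y[None, :] * eta - np.logaddexp(0.0, eta)
        return np.add.reduceat(lp, seg, axis=1)

    def shared_logprior(xs: np.ndarray) -> np.ndarray:
        betas, sds = unpack(xs)
        lp = (-0.5 * (betas / 2.5) ** 2).sum(axis=1)
        for j, s in enumerate(sd_specs):
            lp += s.logprior(sds[s.name]) + s.log_jacobian(xs[:, p + j])
        return lp

    def subj_logprior(xs: np.ndarray, xu: np.ndarray) -> np.ndarray:
        # non-centered: raw deviations are standard normal
        return -0.5 * (xu**2).sum(axis=2)

    rng = np.random.default_rng(mcmc.seed)
    xs0 = np.column_stack(
        [rng.uniform(-0.3, 0.3, size=mcmc.chains) for _ in range(p)]
        + [s.init(rng, mcmc.chains) for s in sd_specs]
    )
    xu0 = 0.1 * rng.standard_normal((mcmc.chains, n_subj, max(k, 1)))
    if k == 0:
        xu0 = np.zeros((mcmc.chains, n_subj, 1))

        def subj_logprior(xs, xu):  # noqa: F811
            return np.zeros((xs.shape[0], n_subj))

    trans_links = []
    scale_links = []
    for j, c in enumerate(rand_cols):
        sd_col = p + j
        trans_links.append((names.index(c), 2.5**2, j, sd_col, 1.0))
        scale_links.append((sd_col, j))
    # subject-constant fixed effects trade off against the random
    # intercepts; weighted translation moves decorrelate them
    if design.random_intercept:
        j_int = rand_cols.index("intercept")
        sd_col_int = p + j_int
        for j, term in enumerate(names):
            if term == "intercept":
                continue
            col = X[:, j]
            per_subj = col[seg]
            if np.allclose(col, per_subj[subj_idx]):
                trans_links.append((j, 2.5**2, j_int, sd_col_int, per_subj.copy()))

    def remix(xs, xu, r):
        hier_remix(xs, xu, r, trans_links, scale_links)

    out_s, out_u = run_hier_mh(
        loglik=loglik,
        shared_logprior=shared_logprior,
        subj_logprior=subj_logprior,
        x_shared0=xs0,
        x_subj0=xu0,
        warmup=mcmc.warmup,
        draws=mcmc.draws,
        rng=rng,
        remix=remix if k else None,
    )

    draws: dict[str, np.ndarray] = {names[j]: out_s[:, :, j] for j in range(p)}
    for j, s in enumerate(sd_specs):
        draws[s.name] = s.to_natural(out_s[:, :, p + j])
    rhat = rhat_max(draws, bound=mcmc.rhat_bound, context="memory GLM")

    rows = []
    for j, term in enumerate(names):
        d = draws[term]
        lo, hi = _hdi(d)
        rows.append(
            {
                "term": term,
                "mean": float(d.mean()),
                "hdi_low": lo,
                "hdi_high": hi,
                "meaningful": bool(lo > 0 or hi < 0),
            }
        )
    fixed_effects = pd.DataFrame(rows)

    # total per-subject slopes: group fixed effect + sd * raw deviation
    subject_beta_rpe = subject_beta_pm = None
    if "rpe" in rand_cols:
        j = rand_cols.index("rpe")
        dev = (draws["sd_rpe"][:, :, None] * out_u[:, :, :, j]).mean(axis=(0, 1))
        subject_beta_rpe = pd.Series(
            draws["rpe"].mean() + dev, index=subjects_list, name="beta_rpe"
        )
    if "pm" in rand_cols:
        j = rand_cols.index("pm")
        dev = (draws["sd_pm"][:, :, None] * out_u[:, :, :, j]).mean(axis=(0, 1))
        subject_beta_pm = pd.Series(
            draws["pm"].mean() + dev, index=subjects_list, name="beta_pm"
        )

    # WAIC from thinned pointwise log-likelihood
    n_thin = min(250, mcmc.draws)
    idx = np.linspace(0, mcmc.draws - 1, n_thin).astype(int)
    pw = np.empty((mcmc.chains, n_thin, len(y)), dtype=np.float32)
    for jj, di in enumerate(idx):
        betas, sds = unpack(out_s[:, di, :])
        eta = linpred(betas, sds, out_u[:, di, :, :])
        pw[:, jj, :] = y[None, :] * eta - np.logaddexp(0.0, eta)
    from .rl import waic_deviance

    waic, waic_se, _ = waic_deviance(pw)

    return GLMFit(
        fixed_effects=fixed_effects,
        draws=draws,
        subject_beta_rpe=subject_beta_rpe,
        subject_beta_pm=subject_beta_pm,
        rhat=rhat,
        waic=waic,
        waic_se=waic_se,
        design=design,
    )
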