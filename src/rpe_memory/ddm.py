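"""Hierarchical drift-diffusion modeling of recognition choices and RTs.

Reaction times are cleaned with the study's exclusion rules (absolute
300 ms / 10 s bounds, then a 3-SD subject-level filter). Drift rate is
regressed on a trial-level covariate (the reward prediction error at
encoding, or the stimulus' perceptual memorability) with a group
intercept/slope and per-subject random deviations; boundary separation
``a``, start point ``z`` and non-decision time ``t`` are pooled across
subjects. The upper boundary codes an "old" response.

Fits run on old-probe trials by default (the RPE covariate is undefined
for lures); ``old_only=False`` includes lures with zero-imputed
covariates on the standardized scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .memory_glm import standardize
from .sampling import MCMCConfig, ParamSpec, hier_remix, rhat_max, run_hier_mh
from .wfpt import wfpt_logpdf

__all__ = [
    "DDMParams",
    "DriftRegressionSpec",
    "RTFilterReport",
    "HierDDMFit",
    "filter_rts",
    "fit_hier_ddm",
    "compare_ddm_models",
]

RT_MIN, RT_MAX, RT_SD_BOUND = 0.3, 10.0, 3.0


@dataclass(frozen=True)
class DDMParams:
    """Scalar diffusion parameters (drift may be per-trial downstream)."""

    a: float
    z: float
    t: float
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if not 0 < self.z < 1:
            raise ValueError("start point z must lie in (0, 1)")
        if self.t < 0:
            raise ValueError("non-decision time t must be >= 0")


@dataclass(frozen=True)
class DriftRegressionSpec:
    """Which covariate drives drift, through which link, with which
    random effects. ``link='log'`` uses log(x - min(x) + 1) since signed
    RPEs make a raw logarithm undefined."""

    covariate: str = "rpe"          # 'rpe' or 'pm'
    link: str = "linear"            # 'linear' | 'quadratic' | 'log'
    random_slope: bool = True
    random_intercept: bool = True

    def __post_init__(self) -> None:
        if self.covariate not in ("rpe", "pm"):
            raise ValueError("covariate must be 'rpe' or 'pm'")
        if self.link not in ("linear", "quadratic", "log"):
            raise ValueError("link must be linear, quadratic or log")

    def apply_link(self, x: np.ndarray) -> np.ndarray:
        if self.link == "quadratic":
            return x**2
        if self.link == "log":
            return np.log(x - np.min(x) + 1.0)
        return x


@dataclass
class RTFilterReport:
    n_input: int
    n_excluded_fast: int
    n_excluded_slow: int
    n_excluded_sd: int
    n_retained: int
    subject_stats: pd.DataFrame      # per-subject mean/SD used for the 3-SD rule
    flagged_subjects: list[str]      # fewer than 2 surviving trials


def filter_rts(data: pd.DataFrame) -> tuple[pd.DataFrame, RTFilterReport]:
    """Apply the RT exclusion rules.

    Rows with rt < 300 ms or rt > 10 s are dropped first; subject-level
    mean/SD are then computed on the survivors and rows beyond 3 SD from
    the subject mean are dropped. Subjects left with fewer than 2 trials
    are flagged and removed (they cannot enter a hierarchical fit).
    """
    if (data["rt"] <= 0).any():
        raise ValueError("all RTs must be positive")
    n_input = len(data)
    fast = data["rt"] < RT_MIN
    slow = data["rt"] > RT_MAX
    surv = data.loc[~(fast | slow)].copy()

    stats_ = surv.groupby("subject")["rt"].agg(["mean", "std", "count"])
    mu = surv["subject"].map(stats_["mean"])
    sd = surv["subject"].map(stats_["std"]).fillna(0.0)
    outlier = (surv["rt"] - mu).abs() > RT_SD_BOUND * sd
    kept = surv.loc[~outlier].copy()

    counts = kept.groupby("subject").size()
    flagged = sorted(str(s) for s in counts.index[counts < 2])
    flagged += sorted(
        str(s) for s in data["subject"].unique() if s not in set(counts.index)
    )
    kept = kept.loc[~kept["subject"].astype(str).isin(flagged)]

    report = RTFilterReport(
        n_input=n_input,
        n_excluded_fast=int(fast.sum()),
        n_excluded_slow=int(slow.sum()),
        n_excluded_sd=int(outlier.sum()),
        n_retained=len(kept),
        subject_stats=stats_.rename(columns={"mean": "rt_mean", "std": "rt_sd"}),
        flagged_subjects=flagged,
    )
    return kept, report


@dataclass
class HierDDMFit:
    spec: DriftRegressionSpec
    summary: pd.DataFrame                 # mean + 95% HDI per group-level parameter
    draws: dict[str, np.ndarray]          # (chains, draws) per group parameter
    subject_intercepts: np.ndarray | None  # posterior-mean deviation per subject
    subject_slopes: np.ndarray | None
    subjects: list[str]
    rhat: dict[str, float]
    waic: float
    waic_se: float
    pointwise_elpd: np.ndarray            # per-trial elpd contributions
    rt: np.ndarray                        # trial set (for comparison checks)
    n_trials: int

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def hdi(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        return _hdi(self.draws[name], prob)


def _hdi(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    import arviz as az

    arr = az.hdi(np.asarray(draws).reshape(-1), hdi_prob=prob)
    return float(arr[0]), float(arr[1])


def fit_hier_ddm(
    data: pd.DataFrame,
    spec: DriftRegressionSpec | None = None,
    mcmc: MCMCConfig | None = None,
    old_only: bool = True,
) -> HierDDMFit:
    """Fit the drift-regression DDM by Metropolis-within-Gibbs MCMC.

    ``data`` must be RT-filtered and carry columns ``subject``,
    ``rt`` (s), ``response`` ('old'/'new' or 1/0), ``is_old`` and the
    covariate column named by ``spec.covariate``.

    Priors: group intercept/slope ~ Normal(0, 2) on the 2-SD-standardized
    covariate, a ~ Gamma(2, 1) on (0, 5), z ~ Beta(2, 2),
    t ~ Uniform(0.05, 0.99 * min RT), random-effect SDs ~ HalfNormal(1).
    """
    spec = spec or DriftRegressionSpec()
    mcmc = mcmc or MCMCConfig(draws=1000, warmup=1000)

    df = data.loc[data["is_old"].astype(bool)].copy() if old_only else data.copy()
    raw = df[spec.covariate].to_numpy(dtype=float)
    if old_only:
        x = standardize(spec.apply_link(raw))
    else:
        old_mask = df["is_old"].to_numpy(dtype=bool)
        x = np.zeros(len(df))
        x[old_mask] = standardize(spec.apply_link(raw[old_mask]))
        pm_like = spec.covariate == "pm"
        if pm_like:
            x = standardize(spec.apply_link(raw))
    df["_x"] = x
    df = df.sort_values("subject", kind="stable")
    subjects = [str(s) for s in df["subject"].unique()]
    subj_idx = df["subject"].astype(str).map({s: i for i, s in enumerate(subjects)}).to_numpy()
    n_subj = len(subjects)
    seg = np.flatnonzero(np.r_[1, np.diff(subj_idx)])

    rt = df["rt"].to_numpy(dtype=float)
    resp_raw = df["response"].to_numpy()
    resp = (
        (resp_raw == "old").astype(float)
        if resp_raw.dtype.kind in "OUS"
        else resp_raw.astype(float)
    )
    xcov = df["_x"].to_numpy(dtype=float)
    t_hi = 0.99 * float(rt.min())

    shared_specs: list[ParamSpec] = [
        ParamSpec("v_intercept", "identity", logprior=lambda v: -v**2 / 8.0,
                  init_lo=-0.5, init_hi=1.0),
        ParamSpec("v_slope", "identity", logprior=lambda v: -v**2 / 8.0,
                  init_lo=-0.3, init_hi=0.3),
        ParamSpec("a", "interval", 0.01, 5.0,
                  logprior=lambda v: np.log(v) - v, init_lo=-0.8, init_hi=0.5),
        ParamSpec("z", "interval", 0.0, 1.0,
                  logprior=lambda v: np.log(v) + np.log1p(-v), init_lo=-0.5, init_hi=0.5),
        ParamSpec("t", "interval", 0.05, t_hi,
                  logprior=lambda v: np.zeros_like(v), init_lo=-2.0, init_hi=-0.5),
    ]
    k = 0
    int_col = slope_col = None
    if spec.random_intercept:
        int_col = k
        k += 1
        shared_specs.append(
            ParamSpec("sd_intercept", "log", logprior=lambda v: -0.5 * v**2,
                      init_lo=np.log(0.1), init_hi=np.log(0.5))
        )
    if spec.random_slope:
        slope_col = k
        k += 1
        shared_specs.append(
            ParamSpec("sd_slope", "log", logprior=lambda v: -0.5 * v**2,
                      init_lo=np.log(0.05), init_hi=np.log(0.3))
        )

    def unpack(xs: np.ndarray) -> dict[str, np.ndarray]:
        return {s.name: s.to_natural(xs[:, j]) for j, s in enumerate(shared_specs)}

    def trial_logp(nat: dict[str, np.ndarray], xu: np.ndarray) -> np.ndarray:
        # non-centered random effects: deviation = sd * raw
        drift = nat["v_intercept"][:, None] + nat["v_slope"][:, None] * xcov[None, :]
        if int_col is not None:
            drift = drift + nat["sd_intercept"][:, None] * xu[:, subj_idx, int_col]
        if slope_col is not None:
            drift = drift + nat["sd_slope"][:, None] * xu[:, subj_idx, slope_col] * xcov[None, :]
        return wfpt_logpdf(
            rt[None, :], resp[None, :], drift,
            nat["a"][:, None], nat["z"][:, None], nat["t"][:, None], err=1e-7,
        )

    def loglik(xs: np.ndarray, xu: np.ndarray) -> np.ndarray:
        lp = trial_logp(unpack(xs), xu)
        return np.add.reduceat(lp, seg, axis=1)

    def shared_logprior(xs: np.ndarray) -> np.ndarray:
        nat = unpack(xs)
        lp = np.zeros(xs.shape[0])
        for j, s in enumerate(shared_specs):
            lp += s.logprior(nat[s.name]) + s.log_jacobian(xs[:, j])
        return lp

    def subj_logprior(xs: np.ndarray, xu: np.ndarray) -> np.ndarray:
        # non-centered: raw deviations are standard normal
        return -0.5 * (xu**2).sum(axis=2)

    rng = np.random.default_rng(mcmc.seed)
    xs0 = np.column_stack([s.init(rng, mcmc.chains) for s in shared_specs])
    xu0 = 0.05 * rng.standard_normal((mcmc.chains, n_subj, max(k, 1)))
    if k == 0:
        xu0 = np.zeros((mcmc.chains, n_subj, 1))

        def subj_logprior(xs, xu):  # noqa: F811 - no random effects
            return np.zeros((xs.shape[0], n_subj))

    trans_links = []
    scale_links = []
    name_to_col = {sp_.name: j for j, sp_ in enumerate(shared_specs)}
    if int_col is not None:
        trans_links.append((name_to_col["v_intercept"], 4.0, int_col, name_to_col["sd_intercept"], 1.0))
        scale_links.append((name_to_col["sd_intercept"], int_col))
    if slope_col is not None:
        trans_links.append((name_to_col["v_slope"], 4.0, slope_col, name_to_col["sd_slope"], 1.0))
        scale_links.append((name_to_col["sd_slope"], slope_col))

    def remix(xs_, xu_, r):
        hier_remix(xs_, xu_, r, trans_links, scale_links)

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

    draws = {
        s.name: s.to_natural(out_s[:, :, j]) for j, s in enumerate(shared_specs)
    }
    rhat = rhat_max(draws, bound=mcmc.rhat_bound, context=f"hier DDM ({spec.covariate}/{spec.link})")

    rows = []
    for name, d in draws.items():
        lo, hi = _hdi(d)
        rows.append({"parameter": name, "mean": float(d.mean()), "hdi_low": lo, "hdi_high": hi})
    summary = pd.DataFrame(rows)

    # pointwise elpd for WAIC via thinned draws
    n_thin = min(250, mcmc.draws)
    idx = np.linspace(0, mcmc.draws - 1, n_thin).astype(int)
    pw = np.empty((mcmc.chains, n_thin, len(rt)), dtype=np.float32)
    for j, di in enumerate(idx):
        pw[:, j, :] = trial_logp(unpack(out_s[:, di, :]), out_u[:, di, :, :])
    from .rl import waic_deviance

    waic, waic_se, _ = waic_deviance(pw)
    from scipy.special import logsumexp

    flat = pw.reshape(-1, len(rt)).astype(float)
    pointwise_elpd_lpd = logsumexp(flat, axis=0) - np.log(flat.shape[0])
    pointwise_p = flat.var(axis=0, ddof=1)
    pointwise_elpd = pointwise_elpd_lpd - pointwise_p

    subj_int = (
        (draws["sd_intercept"][:, :, None] * out_u[:, :, :, int_col]).mean(axis=(0, 1))
        if int_col is not None
        else None
    )
    subj_slope = (
        (draws["sd_slope"][:, :, None] * out_u[:, :, :, slope_col]).mean(axis=(0, 1))
        if slope_col is not None
        else None
    )

    return HierDDMFit(
        spec=spec,
        summary=summary,
        draws=draws,
        subject_intercepts=subj_int,
        subject_slopes=subj_slope,
        subjects=subjects,
        rhat=rhat,
        waic=waic,
        waic_se=waic_se,
        pointwise_elpd=pointwise_elpd,
        rt=rt,
        n_trials=len(rt),
    )


def compare_ddm_models(fits: dict[str, HierDDMFit]) -> pd.DataFrame:
    """Rank drift-regression models by WAIC (deviance scale).

    Reports each model's WAIC, the difference to the best model and the
    SE of that difference from the paired pointwise elpd contributions.
    Requires identical trial sets.
    """
    names = list(fits)
    ref_rt = fits[names[0]].rt
    for n in names[1:]:
        if fits[n].n_trials != len(ref_rt) or not np.allclose(fits[n].rt, ref_rt):
            raise ValueError("DDM fits must share an identical trial set")
    order = sorted(names, key=lambda n: fits[n].waic)
    best = order[0]
    rows = []
    for n in order:
        diff_pw = fits[best].pointwise_elpd - fits[n].pointwise_elpd
        d_se = 2.0 * float(np.sqrt(len(diff_pw) * diff_pw.var(ddof=1)))
        rows.append(
            {
                "model": n,
                "waic": fits[n].waic,
                "waic_se": fits[n].waic_se,
                "d_waic": fits[n].waic - fits[best].waic,
                "d_se": 0.0 if n == best else d_se,
            }
        )
    return pd.DataFrame(rows)
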