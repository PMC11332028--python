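"""Decision models for the reversal bandit: likelihoods, Bayesian fitting,
WAIC comparison, RPE extraction, parameter recovery and identifiability.

Three candidate models of trial-level choice:

* Rescorla–Wagner (``rw``): delta-rule value learning,
  ``Q_{t+1}^c = Q_t^c + alpha * (r_t - Q_t^c)``, with softmax choice
  ``p_t^c = exp(beta Q_t^c) / sum_i exp(beta Q_t^i)``. Q values start at
  0.5, the uninformative midpoint of the 0/1 reward scale.
* Win-stay/lose-shift (``wsls``): the rule-consistent action (repeat after
  a win, switch after a loss) is emitted with probability ``epsilon``;
  the first trial has probability 0.5.
* Bayesian filter (``bayes``): a two-hidden-state forward filter over
  which arm is currently correct. Each trial the belief is mixed by the
  transition matrix ``[[1-p_switch, p_switch], [p_switch, 1-p_switch]]``,
  the action probability is the predictive probability that the chosen
  arm is correct (probability matching), and the belief is updated by the
  reward likelihood (``p_reward`` for the state-correct arm).

Fitting is per-subject (no pooling) by adaptive-Metropolis MCMC with
4 chains; priors are weakly informative and bound-respecting:
alpha ~ Beta(1,1), beta ~ HalfNormal(10), epsilon ~ Beta(1,1),
p_reward ~ Uniform(0.5,1), p_switch ~ Uniform(0,0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logsumexp

from .agents import AgentSpec, simulate_agent
from .data import ChoiceDataset
from .sampling import MCMCConfig, ParamSpec, rhat_max, run_mh
from .task import TaskConfig, generate_task_schedule

__all__ = [
    "RWParams",
    "WSLSParams",
    "BayesParams",
    "ModelFit",
    "RPESeries",
    "ModelComparison",
    "DegenerateDataError",
    "rw_loglik",
    "wsls_loglik",
    "bayes_filter_loglik",
    "fit_model",
    "compare_models",
    "extract_rpes",
    "parameter_recovery",
    "identifiability",
    "reward_landscape",
    "waic_deviance",
    "default_true_sampler",
]


class DegenerateDataError(ValueError):
    """Choice data carry no information (fewer than 2 distinct choices)."""


@dataclass(frozen=True)
class RWParams:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class WSLSParams:
    epsilon: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")


@dataclass(frozen=True)
class BayesParams:
    p_reward: float
    p_switch: float

    def __post_init__(self) -> None:
        if not 0.5 < self.p_reward < 1.0:
            raise ValueError("p_reward must lie in (0.5, 1)")
        if not 0.0 < self.p_switch < 0.5:
            raise ValueError("p_switch must lie in (0, 0.5)")


def _check_coding(data: ChoiceDataset) -> tuple[np.ndarray, np.ndarray]:
    choices = np.asarray(data.choices)
    rewards = np.asarray(data.rewards)
    if not np.isin(rewards, [0, 1]).all():
        raise ValueError("rewards must be coded 0/1")
    return choices, rewards


# ---------------------------------------------------------------------------
# per-trial log-likelihoods, vectorized over a batch of parameter vectors
# ---------------------------------------------------------------------------

def _rw_logp_trials(alpha: np.ndarray, beta: np.ndarray, choices: np.ndarray, rewards: np.ndarray) -> np.ndarray:
    B = alpha.shape[0]
    T = len(choices)
    q = np.full((B, 2), 0.5)
    out = np.empty((B, T))
    for t in range(T):
        c = choices[t]
        d = q[:, c] - q[:, 1 - c]
        out[:, t] = -np.logaddexp(0.0, -beta * d)
        q[:, c] += alpha * (rewards[t] - q[:, c])
    return out


def _wsls_logp_trials(eps: np.ndarray, choices: np.ndarray, rewards: np.ndarray) -> np.ndarray:
    B = eps.shape[0]
    T = len(choices)
    out = np.empty((B, T))
    log_eps = np.log(np.clip(eps, 1e-12, None))
    log_1meps = np.log(np.clip(1.0 - eps, 1e-12, None))
    out[:, 0] = np.log(0.5)
    for t in range(1, T):
        rule = choices[t - 1] if rewards[t - 1] == 1 else 1 - choices[t - 1]
        out[:, t] = log_eps if choices[t] == rule else log_1meps
    return out


def _bayes_logp_trials(
    p_reward: np.ndarray, p_switch: np.ndarray, choices: np.ndarray, rewards: np.ndarray
) -> np.ndarray:
    B = p_reward.shape[0]
    T = len(choices)
    belief = np.full(B, 0.5)  # P(arm 0 correct)
    out = np.empty((B, T))
    for t in range(T):
        belief = belief * (1 - p_switch) + (1 - belief) * p_switch
        c = choices[t]
        p_choice = belief if c == 0 else 1 - belief
        out[:, t] = np.log(np.clip(p_choice, 1e-300, None))
        lik_c = p_reward if rewards[t] == 1 else 1 - p_reward
        lik_i = 1 - p_reward if rewards[t] == 1 else p_reward
        l0, l1 = (lik_c, lik_i) if c == 0 else (lik_i, lik_c)
        num = belief * l0
        belief = num / (num + (1 - belief) * l1)
    return out


# ---------------------------------------------------------------------------
# public scalar likelihoods (with trajectories)
# ---------------------------------------------------------------------------

@dataclass
class RWLoglikResult:
    total: float
    per_trial_logp: np.ndarray
    q: np.ndarray          # (T, 2) values *before* the trial's update
    rpe: np.ndarray        # r_t - Q_t^c, before the update


def rw_loglik(params: RWParams, data: ChoiceDataset) -> RWLoglikResult:
    """Rescorla–Wagner log-likelihood with Q and RPE trajectories."""
    choices, rewards = _check_coding(data)
    T = len(choices)
    q = np.array([0.5, 0.5])
    qs = np.empty((T, 2))
    rpe = np.empty(T)
    logp = np.empty(T)
    for t in range(T):
        qs[t] = q
        c = choices[t]
        logp[t] = -np.logaddexp(0.0, -params.beta * (q[c] - q[1 - c]))
        rpe[t] = rewards[t] - q[c]
        q[c] += params.alpha * rpe[t]
    return RWLoglikResult(float(logp.sum()), logp, qs, rpe)


def wsls_loglik(params: WSLSParams, data: ChoiceDataset) -> tuple[float, np.ndarray]:
    """Win-stay/lose-shift log-likelihood (total, per-trial)."""
    choices, rewards = _check_coding(data)
    logp = _wsls_logp_trials(np.array([params.epsilon]), choices, rewards)[0]
    return float(logp.sum()), logp


@dataclass
class BayesFilterResult:
    total: float
    per_trial_logp: np.ndarray
    predictive: np.ndarray  # P(arm 0 correct) after transition, before outcome
    posterior: np.ndarray   # P(arm 0 correct) after the outcome update


def bayes_filter_loglik(
    params: BayesParams,
    data: ChoiceDataset,
    action_rule: str = "match",
    softmax_gain: float = 10.0,
) -> BayesFilterResult:
    """Two-state forward-filter log-likelihood with the belief trajectory.

    ``action_rule='match'`` (default, and the rule used by the fitted
    model) probability-matches the predictive state posterior;
    ``'softmax'`` instead passes each arm's expected reward through a
    softmax with gain ``softmax_gain``.
    """
    if action_rule not in ("match", "softmax"):
        raise ValueError("action_rule must be 'match' or 'softmax'")
    choices, rewards = _check_coding(data)
    T = len(choices)
    belief = 0.5
    pred = np.empty(T)
    post = np.empty(T)
    logp = np.empty(T)
    for t in range(T):
        belief = belief * (1 - params.p_switch) + (1 - belief) * params.p_switch
        pred[t] = belief
        if action_rule == "match":
            p_arm0 = belief
        else:
            er0 = belief * params.p_reward + (1 - belief) * (1 - params.p_reward)
            er1 = (1 - belief) * params.p_reward + belief * (1 - params.p_reward)
            p_arm0 = float(expit(softmax_gain * (er0 - er1)))
        p_choice = p_arm0 if choices[t] == 0 else 1 - p_arm0
        logp[t] = np.log(max(p_choice, 1e-300))
        lik_c = params.p_reward if rewards[t] == 1 else 1 - params.p_reward
        lik_i = 1 - params.p_reward if rewards[t] == 1 else params.p_reward
        l0, l1 = (lik_c, lik_i) if choices[t] == 0 else (lik_i, lik_c)
        belief = belief * l0 / (belief * l0 + (1 - belief) * l1)
        post[t] = belief
    return BayesFilterResult(float(logp.sum()), logp, pred, post)


# ---------------------------------------------------------------------------
# Bayesian fitting
# ---------------------------------------------------------------------------

_MODEL_PARAMS: dict[str, list[ParamSpec]] = {
    "rw": [
        ParamSpec("alpha", "interval", 0.0, 1.0, logprior=lambda v: np.zeros_like(v),
                  init_lo=-1.5, init_hi=1.5),
        ParamSpec("beta", "log", logprior=lambda v: -0.5 * (v / 10.0) ** 2,
                  init_lo=np.log(0.5), init_hi=np.log(8.0)),
    ],
    "wsls": [
        ParamSpec("epsilon", "interval", 0.0, 1.0, logprior=lambda v: np.zeros_like(v),
                  init_lo=-1.5, init_hi=1.5),
    ],
    "bayes": [
        ParamSpec("p_reward", "interval", 0.5, 1.0, logprior=lambda v: np.zeros_like(v),
                  init_lo=-1.5, init_hi=1.5),
        ParamSpec("p_switch", "interval", 0.0, 0.5, logprior=lambda v: np.zeros_like(v),
                  init_lo=-2.5, init_hi=0.5),
    ],
}

_BATCH_LOGP = {
    "rw": lambda nat, c, r: _rw_logp_trials(nat["alpha"], nat["beta"], c, r),
    "wsls": lambda nat, c, r: _wsls_logp_trials(nat["epsilon"], c, r),
    "bayes": lambda nat, c, r: _bayes_logp_trials(nat["p_reward"], nat["p_switch"], c, r),
}


@dataclass
class ModelFit:
    """Posterior fit of one decision model to one subject's data."""

    model: str
    subject: str
    draws: dict[str, np.ndarray]            # name -> (chains, draws), natural scale
    point_estimate: dict[str, float]        # posterior means
    rhat: dict[str, float]
    waic: float                             # deviance scale (-2 * elpd)
    waic_se: float
    p_waic: float
    n_trials: int
    pointwise_loglik: np.ndarray | None = None  # (chains, draws, trials)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


def waic_deviance(pointwise: np.ndarray) -> tuple[float, float, float]:
    """WAIC on the deviance scale from a (chains, draws, n_obs) table.

    Returns (waic, se, p_waic); with a single posterior draw the penalty
    is zero and WAIC reduces to -2 * sum(log p).
    """
    pw = np.asarray(pointwise, dtype=float)
    if pw.shape[0] * pw.shape[1] == 1:
        return float(-2.0 * pw.sum()), 0.0, 0.0
    flat = pw.reshape(-1, pw.shape[-1])
    n_draws, n_obs = flat.shape
    lppd_i = logsumexp(flat, axis=0) - np.log(n_draws)
    p_i = flat.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    waic = -2.0 * float(elpd_i.sum())
    se = 2.0 * float(np.sqrt(n_obs * elpd_i.var(ddof=1)))
    return waic, se, float(p_i.sum())


def fit_model(
    model: str,
    data: ChoiceDataset,
    mcmc: MCMCConfig | None = None,
    keep_pointwise: bool = True,
) -> ModelFit:
    """Fit one decision model to one subject by adaptive-Metropolis MCMC."""
    mcmc = mcmc or MCMCConfig()
    if model not in _MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    choices, rewards = _check_coding(data)
    if len(np.unique(choices)) < 2:
        raise DegenerateDataError("constant-choice data cannot constrain the models")

    specs = _MODEL_PARAMS[model]
    batch_logp = _BATCH_LOGP[model]

    def logpost(x: np.ndarray) -> np.ndarray:
        nat = {s.name: s.to_natural(x[:, j]) for j, s in enumerate(specs)}
        lp = batch_logp(nat, choices, rewards).sum(axis=1)
        for j, s in enumerate(specs):
            lp = lp + s.logprior(nat[s.name]) + s.log_jacobian(x[:, j])
        return lp

    rng = np.random.default_rng(mcmc.seed)
    x0 = np.column_stack([s.init(rng, mcmc.chains) for s in specs])
    unc, _ = run_mh(logpost, x0, warmup=mcmc.warmup, draws=mcmc.draws, rng=rng)

    draws = {
        s.name: s.to_natural(unc[:, :, j]) for j, s in enumerate(specs)
    }
    rhat = rhat_max(draws, bound=mcmc.rhat_bound, context=f"{model} fit ({data.subject})")
    point = {k: float(v.mean()) for k, v in draws.items()}

    flat = {k: v.reshape(-1) for k, v in draws.items()}
    pw = batch_logp(flat, choices, rewards).reshape(mcmc.chains, mcmc.draws, -1)
    waic, waic_se, p_waic = waic_deviance(pw)

    return ModelFit(
        model=model,
        subject=data.subject,
        draws=draws,
        point_estimate=point,
        rhat=rhat,
        waic=waic,
        waic_se=waic_se,
        p_waic=p_waic,
        n_trials=len(choices),
        pointwise_loglik=pw.astype(np.float32) if keep_pointwise else None,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    table: pd.DataFrame          # subject x model WAIC (deviance scale)
    winners: dict[str, str]      # subject -> winning model
    counts: dict[str, int]       # model -> number of subjects won
    chi2: float
    chi2_p: float


def compare_models(fits_by_subject: Sequence[dict[str, ModelFit]]) -> ModelComparison:
    """Per-subject WAIC comparison with a chi-square test of winner counts.

    Each element maps model name -> ModelFit for one subject; all models
    must have been fit to the same trials.
    """
    records = []
    winners: dict[str, str] = {}
    models = sorted(fits_by_subject[0])
    for fits in fits_by_subject:
        if sorted(fits) != models:
            raise ValueError("all subjects must carry the same model set")
        n_trials = {f.n_trials for f in fits.values()}
        if len(n_trials) != 1:
            raise ValueError("mismatched trial counts across models")
        subject = next(iter(fits.values())).subject
        for name, f in fits.items():
            records.append({"subject": subject, "model": name, "waic": f.waic, "waic_se": f.waic_se})
        winners[subject] = min(fits, key=lambda m: fits[m].waic)
    counts = {m: sum(1 for w in winners.values() if w == m) for m in models}
    observed = np.array([counts[m] for m in models], dtype=float)
    chi2, p = stats.chisquare(observed)
    return ModelComparison(
        table=pd.DataFrame(records),
        winners=winners,
        counts=counts,
        chi2=float(chi2),
        chi2_p=float(p),
    )


# ---------------------------------------------------------------------------
# RPE extraction
# ---------------------------------------------------------------------------

@dataclass
class RPESeries:
    rpe: np.ndarray        # r_t - Q_t^c at the posterior-mean learning rate
    q_chosen: np.ndarray


def extract_rpes(fit: ModelFit, data: ChoiceDataset) -> RPESeries:
    """Forward pass of the delta rule at the posterior-mean alpha."""
    if fit.model != "rw":
        raise ValueError(f"RPE extraction requires an RW fit, got {fit.model!r}")
    res = rw_loglik(RWParams(fit.point_estimate["alpha"], fit.point_estimate["beta"]), data)
    q_chosen = res.q[np.arange(data.n_trials), data.choices]
    return RPESeries(rpe=res.rpe, q_chosen=q_chosen)


# ---------------------------------------------------------------------------
# parameter recovery / identifiability / reward landscape
# ---------------------------------------------------------------------------

def default_true_sampler(model: str) -> Callable[[np.random.Generator], dict[str, float]]:
    """Cohort-like generative parameter distributions for simulation studies."""
    if model == "rw":
        return lambda rng: {
            "alpha": float(np.clip(rng.normal(0.73, 0.19), 0.05, 0.98)),
            "beta": float(np.clip(rng.normal(4.9, 2.9), 0.5, 12.0)),
        }
    if model == "wsls":
        return lambda rng: {"epsilon": float(rng.uniform(0.65, 0.95))}
    if model == "bayes":
        return lambda rng: {
            "p_reward": float(rng.uniform(0.65, 0.9)),
            "p_switch": float(rng.uniform(0.05, 0.15)),
        }
    raise ValueError(f"unknown model {model!r}")


def _simulate_nondegenerate(
    spec: AgentSpec, config: TaskConfig, rng: np.random.Generator, subject: str
) -> ChoiceDataset:
    for _ in range(20):
        sched = generate_task_schedule(config, rng)
        ds = simulate_agent(spec, sched, rng, subject=subject)
        if len(np.unique(ds.choices)) >= 2:
            return ds
    raise DegenerateDataError("agent kept producing constant choices")


@dataclass
class RecoveryReport:
    model: str
    true: dict[str, np.ndarray]
    estimated: dict[str, np.ndarray]
    correlation: dict[str, float]   # NaN when the true values are constant
    bias: dict[str, float]


def parameter_recovery(
    model: str,
    n_agents: int,
    true_sampler: Callable[[np.random.Generator], dict[str, float]] | None = None,
    seed: int | None = None,
    config: TaskConfig | None = None,
    mcmc: MCMCConfig | None = None,
) -> RecoveryReport:
    """Simulate -> fit -> correlate true vs recovered parameters."""
    if n_agents < 2:
        raise ValueError("n_agents must be >= 2")
    config = config or TaskConfig()
    mcmc = mcmc or MCMCConfig(draws=1000, warmup=1000)
    sampler = true_sampler or default_true_sampler(model)
    rng = np.random.default_rng(seed)
    trues: list[dict[str, float]] = []
    ests: list[dict[str, float]] = []
    for i in range(n_agents):
        params = sampler(rng)
        ds = _simulate_nondegenerate(AgentSpec(model, params), config, rng, f"agent{i:03d}")
        fit = fit_model(
            model, ds,
            MCMCConfig(mcmc.chains, mcmc.draws, mcmc.warmup,
                       seed=int(rng.integers(2**31 - 1)), rhat_bound=mcmc.rhat_bound),
            keep_pointwise=False,
        )
        trues.append(params)
        ests.append(fit.point_estimate)
    names = list(trues[0])
    true_arr = {k: np.array([t[k] for t in trues]) for k in names}
    est_arr = {k: np.array([e[k] for e in ests]) for k in names}
    corr = {}
    bias = {}
    for k in names:
        if np.std(true_arr[k]) == 0:
            corr[k] = float("nan")
        else:
            corr[k] = float(stats.pearsonr(true_arr[k], est_arr[k])[0])
        bias[k] = float(np.mean(est_arr[k] - true_arr[k]))
    return RecoveryReport(model, true_arr, est_arr, corr, bias)


@dataclass
class IdentifiabilityMatrix:
    counts: pd.DataFrame  # generative model (rows) x best-fitting model (cols)

    def diagonal_modal(self) -> bool:
        c = self.counts
        return all(c.loc[m].idxmax() == m for m in c.index)


def identifiability(
    n_per_model: int,
    seed: int | None = None,
    config: TaskConfig | None = None,
    mcmc: MCMCConfig | None = None,
    models: Sequence[str] = ("rw", "wsls", "bayes"),
) -> IdentifiabilityMatrix:
    """Simulate cohorts from each model, fit all models, count WAIC winners."""
    config = config or TaskConfig()
    mcmc = mcmc or MCMCConfig(draws=500, warmup=500)
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(0, index=list(models), columns=list(models))
    for gen in models:
        sampler = default_true_sampler(gen)
        for i in range(n_per_model):
            ds = _simulate_nondegenerate(AgentSpec(gen, sampler(rng)), config, rng, f"{gen}{i:03d}")
            fits = {
                m: fit_model(
                    m, ds,
                    MCMCConfig(mcmc.chains, mcmc.draws, mcmc.warmup,
                               seed=int(rng.integers(2**31 - 1)), rhat_bound=mcmc.rhat_bound),
                    keep_pointwise=False,
                )
                for m in models
            }
            winner = min(fits, key=lambda m: fits[m].waic)
            counts.loc[gen, winner] += 1
    return IdentifiabilityMatrix(counts)


def _simulate_rw_batch(
    alpha: float, beta: float, p_win: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized RW agents over stacked schedules; returns total 0/1 reward."""
    n_sims, T, _ = p_win.shape
    q = np.full((n_sims, 2), 0.5)
    total = np.zeros(n_sims)
    for t in range(T):
        p0 = expit(beta * (q[:, 0] - q[:, 1]))
        c = (rng.random(n_sims) >= p0).astype(int)
        r = (rng.random(n_sims) < p_win[np.arange(n_sims), t, c]).astype(float)
        total += r
        idx = np.arange(n_sims)
        q[idx, c] += alpha * (r - q[idx, c])
    return total


def reward_landscape(
    alpha_grid: Sequence[float],
    beta_grid: Sequence[float],
    n_sims: int = 500,
    config: TaskConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Mean total reward (0/1 units) of RW agents over an (alpha, beta) grid.

    The same ``n_sims`` schedules are reused across cells (common random
    numbers for the schedule layer; outcome draws are fresh per cell).
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    if alpha_grid.size == 0 or beta_grid.size == 0:
        raise ValueError("grids must be non-empty")
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    p_win = np.stack(
        [generate_task_schedule(config, rng).p_win for _ in range(n_sims)], axis=0
    )
    out = np.empty((len(alpha_grid), len(beta_grid)))
    for i, a in enumerate(alpha_grid):
        for j, b in enumerate(beta_grid):
            out[i, j] = _simulate_rw_batch(a, b, p_win, rng).mean()
    return out
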