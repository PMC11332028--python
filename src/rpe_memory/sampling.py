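"""MCMC machinery shared by the decision-model, DDM and GLM fits.

Two samplers, both running 4 independent chains by default so the
Gelman–Rubin statistic is meaningful:

* :func:`run_mh` — adaptive random-walk Metropolis with a per-chain
  empirical proposal covariance (Haario-style adaptation during warm-up,
  frozen afterwards). Used for the low-dimensional per-subject decision
  models. Operates in an unconstrained space via the transforms below.
* :func:`run_hier_mh` — Metropolis-within-Gibbs for hierarchical models:
  a joint adaptive update of the shared/group block alternates with a
  vectorized per-subject update of the random-effect deviations.

Convergence is never silently accepted: fits flag any R-hat above the
configured threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import arviz as az
import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "MCMCConfig",
    "ParamSpec",
    "run_mh",
    "run_hier_mh",
    "rhat_max",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    """Sampler finished but a Gelman–Rubin statistic exceeded its bound."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings. Defaults mirror the full analysis configuration:
    4 chains, 4000 retained draws per chain after 4000 warm-up steps."""

    chains: int = 4
    draws: int = 4000
    warmup: int = 4000
    seed: int | None = None
    rhat_bound: float = 1.05


@dataclass(frozen=True)
class ParamSpec:
    """One scalar parameter: support transform + log-prior (natural scale).

    ``transform`` is one of ``interval`` (scaled logistic onto (lo, hi)),
    ``log`` (positive half-line) or ``identity``.
    """

    name: str
    transform: str = "identity"
    lo: float = 0.0
    hi: float = 1.0
    logprior: Callable[[np.ndarray], np.ndarray] | None = None
    init_lo: float = -1.0
    init_hi: float = 1.0

    def to_natural(self, x: np.ndarray) -> np.ndarray:
        if self.transform == "interval":
            return self.lo + (self.hi - self.lo) * expit(x)
        if self.transform == "log":
            return np.exp(x)
        return x

    def log_jacobian(self, x: np.ndarray) -> np.ndarray:
        if self.transform == "interval":
            return np.log(self.hi - self.lo) + log_expit(x) + log_expit(-x)
        if self.transform == "log":
            return x
        return np.zeros_like(x)

    def to_unconstrained(self, value: float) -> float:
        if self.transform == "interval":
            p = (value - self.lo) / (self.hi - self.lo)
            p = min(max(p, 1e-9), 1 - 1e-9)
            return float(np.log(p / (1 - p)))
        if self.transform == "log":
            return float(np.log(max(value, 1e-12)))
        return float(value)

    def init(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Overdispersed natural-scale starting points, mapped back later."""
        return rng.uniform(self.init_lo, self.init_hi, size=size)


def _chol_update(hist: np.ndarray, i: int, d: int) -> np.ndarray:
    seg = hist[(i + 1) // 2 : i + 1]
    cov = np.atleast_2d(np.cov(seg.T)) + 1e-6 * np.eye(d)
    return np.linalg.cholesky(cov)


def run_mh(
    logpost: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    *,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.3,
) -> tuple[np.ndarray, float]:
    """Adaptive random-walk Metropolis.

    ``logpost`` maps a (chains, dim) array of unconstrained parameter
    vectors to (chains,) log posterior densities (including Jacobians).
    Returns retained draws of shape (chains, draws, dim) and the mean
    post-warmup acceptance rate.
    """
    x = np.array(x0, dtype=float)
    n_chains, d = x.shape
    lp = logpost(x)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite log posterior at initialization")
    scale = np.full(n_chains, 2.38 / np.sqrt(d))
    chol = np.tile(np.eye(d), (n_chains, 1, 1))
    hist = np.empty((n_chains, warmup, d)) if warmup else None
    out = np.empty((n_chains, draws, d))
    acc_sum = 0.0
    for i in range(warmup + draws):
        step = np.einsum("cij,cj->ci", chol, rng.standard_normal((n_chains, d)))
        xp = x + scale[:, None] * step
        lpp = logpost(xp)
        accept = np.log(rng.random(n_chains)) < (lpp - lp)
        x[accept] = xp[accept]
        lp[accept] = lpp[accept]
        if i < warmup:
            hist[:, i] = x
            gamma = (i + 1.0) ** -0.6
            scale *= np.exp(gamma * (accept.astype(float) - target_accept))
            if (i + 1) % 250 == 0 and i >= 199:
                for c in range(n_chains):
                    chol[c] = _chol_update(hist[c], i, d)
        else:
            out[:, i - warmup] = x
            acc_sum += accept.mean()
    return out, acc_sum / max(draws, 1)


def hier_remix(
    xs: np.ndarray,
    xu: np.ndarray,
    rng: np.random.Generator,
    trans_links: list[tuple[int, float, int, int]],
    scale_links: list[tuple[int, int]],
    n_scale_steps: int = 10,
) -> None:
    """Likelihood-invariant interweaving moves for non-centered models.

    The linear predictor only sees ``b + sd * raw`` per subject, so two
    families of exact Gibbs moves leave the data likelihood unchanged
    while decorrelating the blocks:

    * translation — shift a fixed effect ``b`` by ``delta`` and the raw
      deviations by ``-delta * w_i / sd``, where ``w_i`` is the fixed
      effect's per-subject covariate value (1 for the intercept); the
      likelihood only sees ``b * w_i + sd * raw_i`` per subject, and
      ``delta`` has a closed-form Gaussian conditional under the Normal
      priors. ``trans_links`` holds ``(b_col, prior_var, subj_col,
      sd_col, weights)`` with ``weights`` a scalar or (n_subj,) array.
    * scale — re-sample a log-SD in the centered parameterization (the
      deviations ``sd * raw`` held fixed) by short MH on its 1-D
      conditional under the HalfNormal(1) prior. ``scale_links`` holds
      ``(log_sd_col, subj_col)``.

    Mutates ``xs``/``xu`` in place.
    """
    n_chains, n_subj, _ = xu.shape
    for b_col, prior_var, subj_col, sd_col, weights in trans_links:
        w = np.broadcast_to(np.asarray(weights, dtype=float), (n_subj,))
        sd = np.exp(xs[:, sd_col])
        lam = 1.0 / prior_var + (w**2).sum() / sd**2
        mu = ((xu[:, :, subj_col] * w[None, :]).sum(axis=1) / sd - xs[:, b_col] / prior_var) / lam
        delta = mu + rng.standard_normal(n_chains) / np.sqrt(lam)
        xs[:, b_col] += delta
        xu[:, :, subj_col] -= (delta / sd)[:, None] * w[None, :]
    for sd_col, subj_col in scale_links:
        s = xs[:, sd_col].copy()
        dev = np.exp(s)[:, None] * xu[:, :, subj_col]
        ssq = (dev**2).sum(axis=1)

        def logp(s_):
            return -0.5 * np.exp(2 * s_) + (1 - n_subj) * s_ - 0.5 * ssq * np.exp(-2 * s_)

        lp = logp(s)
        for _ in range(n_scale_steps):
            prop = s + 0.3 * rng.standard_normal(n_chains)
            lpp = logp(prop)
            acc = np.log(rng.random(n_chains)) < (lpp - lp)
            s[acc] = prop[acc]
            lp[acc] = lpp[acc]
        xs[:, sd_col] = s
        xu[:, :, subj_col] = dev * np.exp(-s)[:, None]


def run_hier_mh(
    *,
    loglik: Callable[[np.ndarray, np.ndarray], np.ndarray],
    shared_logprior: Callable[[np.ndarray], np.ndarray],
    subj_logprior: Callable[[np.ndarray, np.ndarray], np.ndarray],
    x_shared0: np.ndarray,
    x_subj0: np.ndarray,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.3,
    remix: Callable[[np.ndarray, np.ndarray, np.random.Generator], None] | None = None,
    shared_steps: int = 3,
    subj_steps: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Metropolis-within-Gibbs for two-level models.

    ``x_shared0``: (chains, d_shared) unconstrained group/pooled block.
    ``x_subj0``: (chains, n_subj, k) per-subject deviations.
    ``loglik(shared, subj)`` -> (chains, n_subj) per-subject data log
    likelihood; ``subj_logprior(shared, subj)`` -> (chains, n_subj).
    Returns (shared draws, subject draws).
    """
    xs = np.array(x_shared0, dtype=float)
    xu = np.array(x_subj0, dtype=float)
    n_chains, ds = xs.shape
    _, n_subj, k = xu.shape

    ll = loglik(xs, xu)
    sp = shared_logprior(xs)
    up = subj_logprior(xs, xu)
    if not (np.all(np.isfinite(ll)) and np.all(np.isfinite(sp)) and np.all(np.isfinite(up))):
        raise ValueError("non-finite log posterior at initialization")

    scale_s = np.full(n_chains, 2.38 / np.sqrt(ds))
    chol_s = np.tile(np.eye(ds), (n_chains, 1, 1))
    hist = np.empty((n_chains, warmup, ds)) if warmup else None
    scale_u = np.full((n_chains, n_subj), 0.5)

    out_s = np.empty((n_chains, draws, ds))
    out_u = np.empty((n_chains, draws, n_subj, k))

    for i in range(warmup + draws):
        # --- shared/group block (repeated: it is the mixing bottleneck) ---
        for _ in range(shared_steps):
            step = np.einsum("cij,cj->ci", chol_s, rng.standard_normal((n_chains, ds)))
            xsp = xs + scale_s[:, None] * step
            llp = loglik(xsp, xu)
            spp = shared_logprior(xsp)
            upp = subj_logprior(xsp, xu)
            delta = (spp + llp.sum(1) + upp.sum(1)) - (sp + ll.sum(1) + up.sum(1))
            acc_s = np.log(rng.random(n_chains)) < delta
            xs[acc_s] = xsp[acc_s]
            sp[acc_s] = spp[acc_s]
            ll[acc_s] = llp[acc_s]
            up[acc_s] = upp[acc_s]

        # --- per-subject deviations (vectorized accept/reject) ---
        for _ in range(subj_steps):
            xup = xu + scale_u[:, :, None] * rng.standard_normal((n_chains, n_subj, k))
            ll2 = loglik(xs, xup)
            up2 = subj_logprior(xs, xup)
            acc_u = np.log(rng.random((n_chains, n_subj))) < (ll2 + up2 - ll - up)
            xu[acc_u] = xup[acc_u]
            ll[acc_u] = ll2[acc_u]
            up[acc_u] = up2[acc_u]
            if remix is not None:
                remix(xs, xu, rng)  # likelihood-invariant; refresh the priors
                sp = shared_logprior(xs)
                up = subj_logprior(xs, xu)

        if i < warmup:
            hist[:, i] = xs
            gamma = (i + 1.0) ** -0.6
            scale_s *= np.exp(gamma * (acc_s.astype(float) - target_accept))
            scale_u *= np.exp(gamma * (acc_u.astype(float) - target_accept))
            if (i + 1) % 250 == 0 and i >= 199:
                for c in range(n_chains):
                    chol_s[c] = _chol_update(hist[c], i, ds)
        else:
            out_s[:, i - warmup] = xs
            out_u[:, i - warmup] = xu
    return out_s, out_u


def rhat_max(draws: dict[str, np.ndarray], bound: float | None = None, context: str = "") -> dict[str, float]:
    """Per-parameter split-R-hat from (chains, draws[, ...]) arrays.

    Warns with :class:`ConvergenceWarning` when any value exceeds ``bound``.
    """
    ds = az.convert_to_dataset({k: np.asarray(v) for k, v in draws.items()})
    rh = az.rhat(ds)
    result = {}
    for name in draws:
        vals = np.asarray(rh[name].values, dtype=float)
        result[name] = float(np.nanmax(vals))
    if bound is not None:
        worst = max(result.values())
        if worst >= bound:
            warnings.warn(
                f"{context or 'fit'}: max R-hat {worst:.4f} >= {bound}", ConvergenceWarning
            )
    return result
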