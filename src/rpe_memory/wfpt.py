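"""Wiener first-passage-time density for the drift-diffusion model.

The density of a unit-variance Wiener process with drift ``v``, boundary
separation ``a``, relative start point ``z`` (0 < z < 1, measured from the
lower boundary) and non-decision time ``t``, absorbed at the *lower*
boundary, is

    f_lower(rt) = exp(-v a z - v^2 tau / 2) / a^2 * f0(tau / a^2, z),

with ``tau = rt - t`` and ``f0`` the zero-drift density on the unit
interval, computed by the standard dual series expansion:

    small time:  f0(u, w) = (2 pi u^3)^(-1/2) sum_k (w + 2k) exp(-(w+2k)^2 / 2u)
    large time:  f0(u, w) = pi sum_{k>=1} k exp(-k^2 pi^2 u / 2) sin(k pi w)

The branch and the number of terms are chosen per evaluation point from
the truncation-error bound, so both series agree in the crossover region.
The upper-boundary density follows from the reflection
``f_upper(rt; v, z) = f_lower(rt; -v, 1 - z)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wfpt_logpdf", "wfpt_pdf", "simulate_wfpt"]

_MAX_TERMS = 120


def _f0(u: np.ndarray, w: np.ndarray, err: float) -> np.ndarray:
    """Zero-drift unit-interval first-passage density at normalized time u."""
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    out = np.empty_like(u)

    # required term counts (truncation-error bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * u) * err
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * u * np.log(np.maximum(arg_s, 1e-300)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(u) + 1.0)
        arg_l = np.pi * u * err
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0.0) / (np.pi**2 * u)),
            1.0 / (np.pi * np.sqrt(u)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(u)))

    small = ks < kl

    if np.any(small):
        us, ws = u[small], w[small]
        K = int(min(np.ceil((ks[small].max() - 1.0) / 2.0) + 1, _MAX_TERMS))
        k_range = np.arange(-K, K + 1)
        nodes = ws[:, None] + 2.0 * k_range[None, :]
        s = (nodes * np.exp(-(nodes**2) / (2.0 * us[:, None]))).sum(axis=1)
        out[small] = s / np.sqrt(2.0 * np.pi * us**3)

    large = ~small
    if np.any(large):
        ul, wl = u[large], w[large]
        K = int(min(np.ceil(kl[large].max()), _MAX_TERMS))
        k_range = np.arange(1, K + 1)
        s = (
            k_range[None, :]
            * np.exp(-(k_range[None, :] ** 2) * np.pi**2 * ul[:, None] / 2.0)
            * np.sin(k_range[None, :] * np.pi * wl[:, None])
        ).sum(axis=1)
        out[large] = np.pi * s

    return np.maximum(out, 0.0)


def _validate(a, z, t) -> None:
    if np.any(np.asarray(a) <= 0):
        raise ValueError("boundary separation a must be > 0")
    zz = np.asarray(z)
    if np.any((zz <= 0) | (zz >= 1)):
        raise ValueError("relative start point z must lie in (0, 1)")
    if np.any(np.asarray(t) < 0):
        raise ValueError("non-decision time t must be >= 0")


def wfpt_logpdf(rt, response, v, a, z, t, err: float = 1e-10) -> np.ndarray:
    """Log first-passage density at the named boundary.

    ``response``: 1 for the upper boundary (coded as an "old" recognition
    response), 0 for the lower. Arguments broadcast; returns -inf for
    ``rt <= t``.
    """
    _validate(a, z, t)
    rt, response, v, a, z, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (rt, response, v, a, z, t))
    )
    upper = response > 0.5
    v_eff = np.where(upper, -v, v)
    w_eff = np.where(upper, 1.0 - z, z)

    tau = rt - t
    ok = tau > 0
    out = np.full(rt.shape, -np.inf)
    if np.any(ok):
        tau_ok = tau[ok]
        a_ok = a[ok]
        u = tau_ok / a_ok**2
        f0 = _f0(u, w_eff[ok], err)
        logf = (
            np.log(np.maximum(f0, 1e-300))
            - 2.0 * np.log(a_ok)
            - v_eff[ok] * a_ok * w_eff[ok]
            - v_eff[ok] ** 2 * tau_ok / 2.0
        )
        out[ok] = logf
    return out


def wfpt_pdf(rt, response, v, a, z, t, err: float = 1e-10) -> np.ndarray:
    """First-passage density (1/seconds) at the named boundary."""
    logp = wfpt_logpdf(rt, response, v, a, z, t, err=err)
    return np.exp(logp)


def simulate_wfpt(
    n: int,
    v,
    a: float,
    z: float,
    t: float,
    rng: np.random.Generator,
    dt: float = 1e-3,
    max_time: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler–Maruyama forward simulation of the diffusion.

    ``v`` may be a scalar or a per-path array. Returns (rt, response) with
    response 1 for upper-boundary absorptions. Paths not absorbed by
    ``max_time`` (vanishingly rare at sensible parameters) are assigned
    the boundary closest to their final state at ``max_time``.
    """
    _validate(a, z, t)
    v = np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
    x = np.full(n, z * a)
    rt = np.full(n, t + max_time)
    resp = np.empty(n, dtype=int)
    active = np.arange(n)
    sqdt = np.sqrt(dt)
    step = 0
    n_steps = int(np.ceil(max_time / dt))
    while active.size and step < n_steps:
        step += 1
        x[active] += v[active] * dt + sqdt * rng.standard_normal(active.size)
        hit_up = x[active] >= a
        hit_lo = x[active] <= 0.0
        done = hit_up | hit_lo
        if np.any(done):
            idx = active[done]
            rt[idx] = t + step * dt
            resp[idx] = hit_up[done].astype(int)
            active = active[~done]
    if active.size:
        resp[active] = (x[active] >= a / 2.0).astype(int)
    return rt, resp
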