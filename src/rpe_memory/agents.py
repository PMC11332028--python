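"""Generative decision agents for the reversal bandit.

Three agent families mirror the candidate decision models:

* ``rw`` — Rescorla–Wagner delta-rule learner with softmax choice
  (learning rate ``alpha`` in [0, 1], inverse temperature ``beta`` >= 0);
* ``wsls`` — win-stay/lose-shift heuristic that emits the rule-consistent
  action with probability ``epsilon``;
* ``bayes`` — two-hidden-state forward filter over which arm is currently
  correct (``p_reward`` in (0.5, 1), ``p_switch`` in (0, 0.5)), choosing by
  probability-matching the predictive state posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .data import ChoiceDataset
from .task import TaskSchedule

__all__ = ["AgentSpec", "simulate_agent", "sample_memorability", "MEMORABILITY_POOL"]

MODELS = ("rw", "wsls", "bayes")

#: Stimulus pool emulating a "highly memorable" face set: normed d-prime
#: ratings from a truncated normal. Chosen once as a realistic pool; the
#: same distribution serves old items and lures (distribution-matched).
MEMORABILITY_POOL = {"mean": 2.2, "sd": 0.25, "lo": 1.5, "hi": 3.0}


def sample_memorability(rng: np.random.Generator, n: int, pool: dict | None = None) -> np.ndarray:
    pool = pool or MEMORABILITY_POOL
    a = (pool["lo"] - pool["mean"]) / pool["sd"]
    b = (pool["hi"] - pool["mean"]) / pool["sd"]
    return stats.truncnorm.rvs(a, b, loc=pool["mean"], scale=pool["sd"], size=n, random_state=rng)


_BOUNDS = {
    "rw": {"alpha": (0.0, 1.0), "beta": (0.0, np.inf)},
    "wsls": {"epsilon": (0.0, 1.0)},
    "bayes": {"p_reward": (0.5, 1.0), "p_switch": (0.0, 0.5)},
}


@dataclass(frozen=True)
class AgentSpec:
    """A named decision model plus its generative parameters."""

    model: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        bounds = _BOUNDS[self.model]
        if set(self.params) != set(bounds):
            raise ValueError(
                f"model {self.model!r} needs parameters {sorted(bounds)}, got {sorted(self.params)}"
            )
        for name, (lo, hi) in bounds.items():
            v = self.params[name]
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


def _softmax_choice_prob(q: np.ndarray, beta: float) -> float:
    """Probability of choosing arm 0 under a two-arm softmax."""
    return float(1.0 / (1.0 + np.exp(-beta * (q[0] - q[1]))))


def simulate_agent(
    spec: AgentSpec,
    schedule: TaskSchedule,
    seed: int | np.random.Generator | None = None,
    subject: str = "sim",
) -> ChoiceDataset:
    """Simulate one run of the bandit under the named decision model.

    Rewards are drawn from the scheduled arm probabilities; a trial-unique
    stimulus memorability rating is attached to every trial. For ``rw``
    agents the generative Q/RPE trajectories are retained on the dataset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = schedule.n_trials
    choices = np.empty(n, dtype=int)
    rewards = np.empty(n, dtype=int)
    true_q = None
    true_rpe = None

    if spec.model == "rw":
        alpha, beta = spec.params["alpha"], spec.params["beta"]
        q = np.array([0.5, 0.5])  # uninformative midpoint of the 0/1 scale
        true_q = np.empty((n, 2))
        true_rpe = np.empty(n)
        for t in range(n):
            true_q[t] = q
            p0 = _softmax_choice_prob(q, beta)
            c = 0 if rng.random() < p0 else 1
            r = int(rng.random() < schedule.p_win[t, c])
            rpe = r - q[c]
            q[c] += alpha * rpe
            choices[t], rewards[t], true_rpe[t] = c, r, rpe
    elif spec.model == "wsls":
        eps = spec.params["epsilon"]
        for t in range(n):
            if t == 0:
                rule = int(rng.integers(2))
            else:
                rule = choices[t - 1] if rewards[t - 1] == 1 else 1 - choices[t - 1]
            c = rule if rng.random() < eps else 1 - rule
            choices[t] = c
            rewards[t] = int(rng.random() < schedule.p_win[t, c])
    else:  # bayes
        p_r, p_s = spec.params["p_reward"], spec.params["p_switch"]
        belief = 0.5  # P(arm 0 is the correct arm)
        for t in range(n):
            belief = belief * (1 - p_s) + (1 - belief) * p_s
            c = 0 if rng.random() < belief else 1
            r = int(rng.random() < schedule.p_win[t, c])
            # reward likelihood under each hidden state
            lik_c = p_r if r == 1 else 1 - p_r  # chosen arm is correct
            lik_i = 1 - p_r if r == 1 else p_r
            l0, l1 = (lik_c, lik_i) if c == 0 else (lik_i, lik_c)
            belief = belief * l0 / (belief * l0 + (1 - belief) * l1)
            choices[t], rewards[t] = c, r

    return ChoiceDataset(
        subject=subject,
        choices=choices,
        rewards=rewards,
        pm=sample_memorability(rng, n),
        schedule=schedule,
        agent={"model": spec.model, **spec.params},
        true_rpe=true_rpe,
        true_q=true_q,
    )
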