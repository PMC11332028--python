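"""Subject-level moderation and equivalence analyses.

Tests whether individual differences in memory performance are explained
by the interaction between a subject's reliance on a trial-level signal
(the random RPE or PM slope exported from the memory regression) and a
transdiagnostic factor score. Null coefficients are accompanied by TOST
equivalence tests against the prespecified bounds [-0.1, 0.1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .memory_glm import standardize

__all__ = [
    "RegressionResult",
    "EquivalenceResult",
    "interaction_regression",
    "tost_equivalence",
]

_CONDITION_LIMIT = 1e8


@dataclass
class RegressionResult:
    term: str
    B: float
    SE: float
    p: float
    ci: tuple[float, float]
    df_resid: int


@dataclass
class EquivalenceResult:
    t_lower: float
    t_upper: float
    df: int
    p_eq: float
    bounds: tuple[float, float]

    @property
    def equivalent(self) -> bool:
        return self.p_eq < 0.05


def interaction_regression(
    table: pd.DataFrame,
    outcome: str,
    slope: str,
    moderator: str,
    standardize_predictors: bool = True,
) -> list[RegressionResult]:
    """OLS of ``outcome ~ slope * moderator`` with the 2-SD rule applied
    to the predictors. Returns the full coefficient table; flags severe
    collinearity."""
    if len(table) < 10:
        raise ValueError("need at least 10 subjects")
    s = table[slope].to_numpy(dtype=float)
    m = table[moderator].to_numpy(dtype=float)
    if standardize_predictors:
        s = standardize(s)
        m = standardize(m)
    X = pd.DataFrame(
        {
            slope: s,
            moderator: m,
            f"{slope}:{moderator}": s * m,
        }
    )
    X = sm.add_constant(X)
    if np.linalg.cond(X.to_numpy()) > _CONDITION_LIMIT:
        raise ValueError("design matrix is ill-conditioned (collinearity)")
    fit = sm.OLS(table[outcome].to_numpy(dtype=float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = []
    for term in X.columns:
        out.append(
            RegressionResult(
                term=str(term),
                B=float(fit.params[term]),
                SE=float(fit.bse[term]),
                p=float(fit.pvalues[term]),
                ci=(float(ci.loc[term, 0]), float(ci.loc[term, 1])),
                df_resid=int(fit.df_resid),
            )
        )
    return out


def tost_equivalence(
    B: float, SE: float, df: int, bounds: tuple[float, float] = (-0.1, 0.1)
) -> EquivalenceResult:
    """Two one-sided t tests of a coefficient against equivalence bounds.

    ``p_eq`` is the larger of the two one-sided p values; equivalence is
    concluded at p_eq < 0.05.
    """
    if SE <= 0:
        raise ValueError("SE must be > 0")
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must be ordered")
    t_lower = (B - lo) / SE    # H0: B <= lo, want large positive t
    t_upper = (B - hi) / SE    # H0: B >= hi, want large negative t
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    return EquivalenceResult(
        t_lower=float(t_lower),
        t_upper=float(t_upper),
        df=int(df),
        p_eq=max(p_lower, p_upper),
        bounds=(float(lo), float(hi)),
    )
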