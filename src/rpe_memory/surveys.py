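"""Synthetic psychometric surveys with a known oblique latent structure.

Items emulate three symptom scales — trait anxiety (STAI-T, 20 items),
depression (SDS, 20 items) and obsessive-compulsive symptoms (OCI-R,
18 items) — generated from a 3-factor oblique latent model: correlated
standard-normal factors, continuous item scores ``Lambda f + unique
noise`` with unit marginal variance, discretized to a 4-point Likert
scale by equal-probability thresholds. A configurable subset of items is
stored reverse-coded (as real scales are) and flagged in the metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyGenParams",
    "SurveyMatrix",
    "default_survey_params",
    "generate_surveys",
    "recode_reverse",
    "ParameterizationError",
]


class ParameterizationError(ValueError):
    """The latent-model parameters are inconsistent (e.g. non-PD Phi)."""


@dataclass
class SurveyGenParams:
    """Latent-model parameters: pattern loadings, factor correlations,
    uniquenesses (communality + uniqueness = 1 per item)."""

    loadings: np.ndarray
    factor_corr: np.ndarray
    uniqueness: np.ndarray
    item_names: list[str]
    item_scale: list[str]
    reverse_coded: np.ndarray
    likert_levels: int = 4
    n_respondents: int = 320
    seed: int | None = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        self.uniqueness = np.asarray(self.uniqueness, dtype=float)
        self.reverse_coded = np.asarray(self.reverse_coded, dtype=bool)
        p, k = self.loadings.shape
        if self.factor_corr.shape != (k, k):
            raise ParameterizationError("factor_corr shape does not match loadings")
        if not np.allclose(self.factor_corr, self.factor_corr.T):
            raise ParameterizationError("factor_corr must be symmetric")
        if not np.allclose(np.diag(self.factor_corr), 1.0):
            raise ParameterizationError("factor_corr must have unit diagonal")
        try:
            np.linalg.cholesky(self.factor_corr)
        except np.linalg.LinAlgError as exc:
            raise ParameterizationError("factor_corr must be positive definite") from exc
        comm = np.diag(self.loadings @ self.factor_corr @ self.loadings.T)
        if not np.allclose(comm + self.uniqueness, 1.0, atol=1e-6):
            raise ParameterizationError(
                "communality + uniqueness must equal 1 per item on the standardized scale"
            )
        if self.likert_levels < 2:
            raise ParameterizationError("likert_levels must be >= 2")


def default_survey_params(
    n_respondents: int = 320, seed: int | None = None
) -> SurveyGenParams:
    """Three scale-aligned factors with loadings 0.7 and the oblique
    factor correlations the transdiagnostic solution is meant to emulate."""
    counts = {"stai": 20, "sds": 20, "ocir": 18}
    names: list[str] = []
    scales: list[str] = []
    for scale, c in counts.items():
        for i in range(c):
            names.append(f"{scale}_{i+1:02d}")
            scales.append(scale)
    p = len(names)
    lam = np.zeros((p, 3))
    lam[:20, 0] = 0.7
    lam[20:40, 1] = 0.7
    lam[40:, 2] = 0.7
    phi = np.array([[1.0, -0.62, -0.22], [-0.62, 1.0, -0.38], [-0.22, -0.38, 1.0]])
    uniq = 1.0 - np.diag(lam @ phi @ lam.T)
    reverse = np.zeros(p, dtype=bool)
    reverse[[0, 4, 7, 9, 12, 20, 23, 27, 31]] = True  # positively-worded items
    return SurveyGenParams(
        loadings=lam,
        factor_corr=phi,
        uniqueness=uniq,
        item_names=names,
        item_scale=scales,
        reverse_coded=reverse,
        n_respondents=n_respondents,
        seed=seed,
    )


@dataclass
class SurveyMatrix:
    """Likert responses plus item metadata (and, for simulated data, the
    latent factors and pre-discretization continuous scores)."""

    responses: pd.DataFrame
    item_meta: pd.DataFrame
    continuous: np.ndarray | None = None
    latent: np.ndarray | None = None

    @property
    def n_respondents(self) -> int:
        return len(self.responses)


def generate_surveys(
    params: SurveyGenParams, rng: np.random.Generator | None = None
) -> SurveyMatrix:
    """Draw the survey matrix; deterministic given ``params.seed``."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p, k = params.loadings.shape
    n = params.n_respondents
    chol = np.linalg.cholesky(params.factor_corr)
    factors = rng.standard_normal((n, k)) @ chol.T
    continuous = factors @ params.loadings.T + rng.standard_normal((n, p)) * np.sqrt(
        params.uniqueness
    )
    # equal-probability thresholds on the standard-normal marginal
    qs = stats.norm.ppf(np.arange(1, params.likert_levels) / params.likert_levels)
    likert = 1 + np.searchsorted(qs, continuous).reshape(n, p)
    likert = np.asarray(likert, dtype=int)
    stored = np.where(
        params.reverse_coded[None, :], params.likert_levels + 1 - likert, likert
    )
    responses = pd.DataFrame(stored, columns=params.item_names)
    item_meta = pd.DataFrame(
        {
            "item": params.item_names,
            "scale": params.item_scale,
            "reverse_coded": params.reverse_coded,
        }
    )
    return SurveyMatrix(
        responses=responses, item_meta=item_meta, continuous=continuous, latent=factors
    )


def recode_reverse(m: SurveyMatrix, likert_levels: int = 4) -> pd.DataFrame:
    """Undo reverse-coding so all items point in the keyed direction."""
    out = m.responses.copy()
    rev = m.item_meta.set_index("item")["reverse_coded"]
    for item in out.columns:
        if bool(rev.get(item, False)):
            out[item] = likert_levels + 1 - out[item]
    return out
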