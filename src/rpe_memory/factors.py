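"""Exploratory factor analysis of the symptom surveys.

Sampling adequacy (Kaiser–Meyer–Olkin), Bartlett's sphericity test,
factor-number selection by the Cattell–Nelson–Gorsuch (CNG) slope test,
maximum-likelihood extraction with an oblique promax rotation, and
ten Berge correlation-preserving factor scores.

Correlations are Pearson on the (recoded) Likert items. Singular
correlation matrices receive a small ridge with a logged warning.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "FactorSolution",
    "kmo",
    "bartlett",
    "cng_nfactors",
    "fit_factor_model",
    "score_tenberge",
    "align_solution",
    "tucker_congruence",
]

log = logging.getLogger(__name__)

_RIDGE = 1e-8
_MIN_UNIQUENESS = 0.005


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float)
    return np.asarray(m, dtype=float)


def _corr(data: np.ndarray) -> np.ndarray:
    return np.corrcoef(data, rowvar=False)


def _safe_inverse(r: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(r)
    except np.linalg.LinAlgError:
        log.warning("singular correlation matrix; adding a %.0e ridge", _RIDGE)
        return np.linalg.inv(r + _RIDGE * np.eye(len(r)))


def kmo(data) -> tuple[float, np.ndarray]:
    """Kaiser–Meyer–Olkin sampling adequacy (overall, per item).

    Compares squared correlations with squared anti-image partial
    correlations: values near 1 mean diffuse shared variance suitable
    for factoring.
    """
    x = _as_matrix(data)
    r = _corr(x) if x.shape[0] != x.shape[1] or not np.allclose(x, x.T) else x
    s = _safe_inverse(r)
    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    q = -s / d
    np.fill_diagonal(q, 0.0)
    r_off = r - np.eye(len(r)) * np.diag(r)
    np.fill_diagonal(r_off, 0.0)
    r2 = r_off**2
    q2 = q**2
    overall = r2.sum() / (r2.sum() + q2.sum())
    per_item = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    return float(overall), per_item


def bartlett(data) -> tuple[float, int, float]:
    """Bartlett's sphericity test: chi2, df, p for H0 that the
    correlation matrix is the identity."""
    x = _as_matrix(data)
    n, p = x.shape
    if n <= p:
        raise ValueError("Bartlett's test requires more observations than items")
    r = _corr(x)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def _slope(y: np.ndarray) -> float:
    x = np.arange(len(y), dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def cng_nfactors(eigenvalues) -> int:
    """Cattell–Nelson–Gorsuch factor count.

    Scans successive pairs of 3-eigenvalue linear fits along the scree
    and returns the position of the maximal slope change. Needs at least
    6 eigenvalues. A flat profile (no distinguished elbow) still returns
    the argmax but warns.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if len(ev) < 6:
        raise ValueError("CNG needs at least 6 eigenvalues")
    if np.any(np.diff(ev) > 1e-10):
        raise ValueError("eigenvalues must be in descending order")
    diffs = []
    for i in range(len(ev) - 5):
        diffs.append(_slope(ev[i + 3 : i + 6]) - _slope(ev[i : i + 3]))
    diffs = np.asarray(diffs)
    if np.ptp(diffs) < 1e-10:
        warnings.warn("flat eigenvalue profile: no distinguished elbow", UserWarning)
    return int(np.argmax(diffs)) + 2


@dataclass
class FactorSolution:
    loadings: pd.DataFrame        # pattern matrix after promax (item x k)
    factor_corr: np.ndarray       # k x k
    uniqueness: pd.Series
    k: int
    eigenvalues: np.ndarray       # of the correlation matrix, descending
    heywood: bool                 # any uniqueness hit the lower bound
    corr: np.ndarray              # analyzed correlation matrix
    loadings_unrotated: np.ndarray | None = None


def _promax(v: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Oblique promax on a varimax solution; returns (pattern, Phi)."""
    q = v * np.abs(v) ** (power - 1)
    u = np.linalg.lstsq(v, q, rcond=None)[0]
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u @ np.diag(np.sqrt(d))
    pattern = v @ u
    phi = np.linalg.inv(u.T @ u)
    return pattern, phi


def fit_factor_model(data, k: int) -> FactorSolution:
    """ML factor extraction + varimax pre-rotation + promax (power 4).

    ``data`` is a respondents-by-items table (or a correlation matrix,
    in which case pass items as both axes). Heywood cases are flagged
    and uniquenesses floored at 0.005.
    """
    x = _as_matrix(data)
    names = list(data.columns) if isinstance(data, pd.DataFrame) else [
        f"item{i}" for i in range(x.shape[1])
    ]
    r = _corr(x)
    p = r.shape[0]
    if k >= p:
        raise ValueError("k must be smaller than the number of items")
    eigenvalues = np.sort(np.linalg.eigvalsh(r))[::-1]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = Factor(corr=r, n_factor=k, method="ml").fit()
    a = np.asarray(fa.loadings)[:, :k]
    uniq = np.asarray(fa.uniqueness, dtype=float)
    heywood = bool((uniq < _MIN_UNIQUENESS).any())
    if heywood:
        log.warning("Heywood case: %d uniquenesses floored", int((uniq < _MIN_UNIQUENESS).sum()))
        uniq = np.maximum(uniq, _MIN_UNIQUENESS)

    if k == 1:
        pattern, phi = a, np.eye(1)
        if pattern.sum() < 0:
            pattern = -pattern
    else:
        v, _ = rotate_factors(a, "varimax")
        pattern, phi = _promax(v)
        # order factors by explained variance, majority-positive sign
        order = np.argsort(-(pattern**2).sum(axis=0))
        pattern = pattern[:, order]
        phi = phi[np.ix_(order, order)]
        signs = np.sign(pattern.sum(axis=0))
        signs[signs == 0] = 1.0
        pattern = pattern * signs[None, :]
        phi = phi * np.outer(signs, signs)

    return FactorSolution(
        loadings=pd.DataFrame(pattern, index=names, columns=[f"f{i+1}" for i in range(k)]),
        factor_corr=phi,
        uniqueness=pd.Series(uniq, index=names, name="uniqueness"),
        k=k,
        eigenvalues=eigenvalues,
        heywood=heywood,
        corr=r,
        loadings_unrotated=a,
    )


def _mat_power(m: np.ndarray, power: float) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    if w.min() <= 0 and power < 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    w = np.maximum(w, 1e-12)
    return (v * w**power) @ v.T


def score_tenberge(sol: FactorSolution, data) -> pd.DataFrame:
    """Correlation-preserving (ten Berge) factor scores.

    The score weights are constructed so the sample correlations among
    score columns reproduce the solution's factor correlations exactly.
    """
    x = _as_matrix(data)
    if x.shape[1] != len(sol.loadings):
        raise ValueError("data and solution are dimensionally inconsistent")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = sol.corr
    lam = sol.loadings.to_numpy()
    phi = sol.factor_corr
    l_star = lam @ _mat_power(phi, 0.5)
    r_inv_half = _mat_power(r, -0.5)
    inner = l_star.T @ _mat_power(r, -1.0) @ l_star
    c = r_inv_half @ l_star @ _mat_power(inner, -0.5)
    w = r_inv_half @ c @ _mat_power(phi, 0.5)
    scores = z @ w
    index = data.index if isinstance(data, pd.DataFrame) else None
    return pd.DataFrame(scores, columns=sol.loadings.columns, index=index)


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-pairwise Tucker congruence coefficients."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    num = a.T @ b
    den = np.sqrt(np.outer((a**2).sum(axis=0), (b**2).sum(axis=0)))
    return num / den


def align_solution(
    estimated: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Match estimated factor columns to a target by brute-force
    permutation and sign search (k <= 4), maximizing mean Tucker
    congruence. Returns (permutation, signs, mean congruence)."""
    k = target.shape[1]
    if k > 4:
        raise ValueError("brute-force alignment supports k <= 4")
    cong = tucker_congruence(estimated, target)
    best = (None, None, -np.inf)
    for perm in itertools.permutations(range(k)):
        vals = np.array([cong[perm[j], j] for j in range(k)])
        score = float(np.abs(vals).mean())
        if score > best[2]:
            best = (np.array(perm), np.sign(vals), score)
    perm, signs, score = best
    signs[signs == 0] = 1.0
    return perm, signs, score
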