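"""Survey generation and the exploratory factor-analysis pipeline."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from rpe_memory.factors import (
    align_solution,
    bartlett,
    cng_nfactors,
    fit_factor_model,
    kmo,
    score_tenberge,
    tucker_congruence,
)
from rpe_memory.surveys import (
    ParameterizationError,
    SurveyGenParams,
    default_survey_params,
    generate_surveys,
    recode_reverse,
)


def _params(loadings, phi, n, seed=0, likert=4):
    loadings = np.asarray(loadings, dtype=float)
    p = loadings.shape[0]
    uniq = 1 - np.diag(loadings @ phi @ loadings.T)
    return SurveyGenParams(
        loadings=loadings,
        factor_corr=np.asarray(phi, dtype=float),
        uniqueness=uniq,
        item_names=[f"q{i:02d}" for i in range(p)],
        item_scale=["syn"] * p,
        reverse_coded=np.zeros(p, dtype=bool),
        likert_levels=likert,
        n_respondents=n,
        seed=seed,
    )


def _oblique3(n, seed=0, load=0.7, off=-0.4, p_per=4):
    lam = np.zeros((3 * p_per, 3))
    for j in range(3):
        lam[j * p_per : (j + 1) * p_per, j] = load
    phi = np.full((3, 3), off)
    np.fill_diagonal(phi, 1.0)
    return _params(lam, phi, n, seed=seed)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def test_zero_loadings_give_uncorrelated_items():
    params = _params(np.zeros((6, 2)), np.eye(2), 100_000, seed=1)
    sm = generate_surveys(params)
    r = np.corrcoef(sm.continuous.T)
    off = r[~np.eye(6, dtype=bool)]
    assert np.abs(off).max() < 0.02


def test_single_factor_closed_form_correlations():
    """lambda_i * lambda_j = 0.64 for every pair under a one-factor model
    with loadings 0.8 (continuous scale, n = 100,000)."""
    params = _params(np.full((6, 1), 0.8), np.eye(1), 100_000, seed=2)
    sm = generate_surveys(params)
    r = np.corrcoef(sm.continuous.T)
    off = r[~np.eye(6, dtype=bool)]
    np.testing.assert_allclose(off, 0.64, atol=0.02)


def test_model_implied_correlation_structure():
    """Sample correlations converge to Lambda Phi Lambda' + Psi."""
    params = _oblique3(100_000, seed=3)
    sm = generate_surveys(params)
    r = np.corrcoef(sm.continuous.T)
    implied = params.loadings @ params.factor_corr @ params.loadings.T
    np.fill_diagonal(implied, 1.0)
    assert np.abs(r - implied).max() < 0.02


def test_generator_validation_and_determinism():
    bad_phi = np.array([[1.0, 0.99], [0.99, -1.0]])
    with pytest.raises(ParameterizationError):
        _params(np.zeros((6, 2)), bad_phi, 10)
    with pytest.raises(ParameterizationError):
        p = _params(np.full((6, 1), 0.5), np.eye(1), 10)
        dataclasses.replace(p, uniqueness=np.full(6, 0.9))
    a = generate_surveys(default_survey_params(50, seed=7)).responses
    b = generate_surveys(default_survey_params(50, seed=7)).responses
    pd.testing.assert_frame_equal(a, b)


def test_likert_range_and_reverse_coding_roundtrip():
    params = default_survey_params(300, seed=8)
    sm = generate_surveys(params)
    assert sm.responses.to_numpy().min() >= 1
    assert sm.responses.to_numpy().max() <= params.likert_levels
    rec = recode_reverse(sm, params.likert_levels)
    flipped = params.item_names[int(np.flatnonzero(params.reverse_coded)[0])]
    kept = params.item_names[int(np.flatnonzero(~params.reverse_coded)[0])]
    assert (rec[flipped] == params.likert_levels + 1 - sm.responses[flipped]).all()
    assert (rec[kept] == sm.responses[kept]).all()


# ---------------------------------------------------------------------------
# adequacy statistics
# ---------------------------------------------------------------------------

def test_kmo_two_items_is_half():
    """With two items the partial correlation equals the correlation, so
    KMO = 0.5 for any nonzero association."""
    r = np.array([[1.0, 0.37], [0.37, 1.0]])
    overall, per_item = kmo(r)
    assert abs(overall - 0.5) < 1e-12
    np.testing.assert_allclose(per_item, 0.5, atol=1e-12)


def test_kmo_three_equicorrelated_items_analytic():
    """All off-diagonals 0.6: partials follow from the analytic inverse of
    an equicorrelation matrix."""
    rho = 0.6
    r = np.full((3, 3), rho)
    np.fill_diagonal(r, 1.0)
    # inverse of equicorrelation matrix: partial corr = rho / (1 + rho)
    q = rho / (1 + rho)
    expected = (6 * rho**2) / (6 * rho**2 + 6 * q**2)
    overall, _ = kmo(r)
    assert abs(overall - expected) < 1e-12


def test_kmo_high_for_strong_common_factor():
    params = _params(np.full((8, 1), 0.75), np.eye(1), 10_000, seed=4)
    sm = generate_surveys(params)
    overall, _ = kmo(pd.DataFrame(sm.continuous))
    assert overall > 0.7


def _data_with_exact_corr(r, n, seed=0):
    """Transform Gaussian data so its sample correlation equals r exactly."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, r.shape[0]))
    x -= x.mean(axis=0)
    cov = np.cov(x.T)
    white = x @ np.linalg.inv(np.linalg.cholesky(cov)).T
    return white @ np.linalg.cholesky(r).T


def test_bartlett_identity_is_zero():
    r = np.eye(3)
    x = _data_with_exact_corr(r, 101)
    chi2, df, p = bartlett(pd.DataFrame(x))
    assert abs(chi2) < 1e-8
    assert df == 3


def test_bartlett_arithmetic_at_known_determinant():
    """p=3, n=101, |R| = 0.5 -> chi2 = -(100 - 11/6) ln 0.5 = 68.05."""
    # equicorrelation with det 0.5: (1-rho)^2 (1+2rho) = 0.5
    from scipy.optimize import brentq

    rho = brentq(lambda r: (1 - r) ** 2 * (1 + 2 * r) - 0.5, 0.0, 0.9)
    r = np.full((3, 3), rho)
    np.fill_diagonal(r, 1.0)
    x = _data_with_exact_corr(r, 101)
    chi2, df, _ = bartlett(pd.DataFrame(x))
    assert abs(chi2 - 68.0455) < 1e-2
    assert df == 3


def test_bartlett_detects_correlation():
    params = _params(np.full((6, 1), 0.6), np.eye(1), 1000, seed=5)
    sm = generate_surveys(params)
    _, _, p = bartlett(pd.DataFrame(sm.continuous))
    assert p < 0.001


def test_bartlett_requires_enough_observations():
    with pytest.raises(ValueError):
        bartlett(pd.DataFrame(np.random.default_rng(0).standard_normal((5, 6))))


# ---------------------------------------------------------------------------
# factor count (CNG)
# ---------------------------------------------------------------------------

def test_cng_two_factor_scree():
    assert cng_nfactors([10, 9, 1, 0.9, 0.8, 0.7, 0.6]) == 2


def test_cng_flat_profile_warns():
    with pytest.warns(UserWarning):
        cng_nfactors(np.linspace(5, 1, 9))


def test_cng_needs_six_eigenvalues():
    with pytest.raises(ValueError):
        cng_nfactors([3, 2, 1, 0.5, 0.2])


def test_cng_recovers_three_factors():
    params = _oblique3(10_000, seed=6)
    sm = generate_surveys(params)
    ev = np.sort(np.linalg.eigvalsh(np.corrcoef(sm.responses.to_numpy().T)))[::-1]
    assert cng_nfactors(ev) == 3


# ---------------------------------------------------------------------------
# extraction, rotation, scoring
# ---------------------------------------------------------------------------

def test_one_factor_loading_recovery():
    params = _params(np.full((8, 1), 0.8), np.eye(1), 10_000, seed=9)
    sm = generate_surveys(params)
    sol = fit_factor_model(pd.DataFrame(sm.continuous), 1)
    assert np.abs(sol.loadings.to_numpy().ravel() - 0.8).max() < 0.05


def test_oblique_recovery_and_rotation_invariants():
    params = _oblique3(10_000, seed=10)
    sm = generate_surveys(params)
    data = pd.DataFrame(sm.continuous, columns=params.item_names)
    sol = fit_factor_model(data, 3)

    perm, signs, cong = align_solution(sol.loadings.to_numpy(), params.loadings)
    assert cong > 0.95
    phi_est = sol.factor_corr[np.ix_(perm, perm)] * np.outer(signs, signs)
    off = ~np.eye(3, dtype=bool)
    assert np.abs(phi_est[off] - params.factor_corr[off]).max() < 0.1

    # promax leaves communalities unchanged
    lam = sol.loadings.to_numpy()
    comm = np.diag(lam @ sol.factor_corr @ lam.T)
    np.testing.assert_allclose(comm + sol.uniqueness.to_numpy(), 1.0, atol=0.05)

    # reconstruction: Lambda Phi Lambda' + Psi approximates R
    implied = lam @ sol.factor_corr @ lam.T + np.diag(sol.uniqueness)
    resid = sol.corr - implied
    rmsr = np.sqrt((resid[off_diag(len(lam))] ** 2).mean())
    assert rmsr < 0.05


def off_diag(p):
    return ~np.eye(p, dtype=bool)


def test_promax_preserves_communalities_exactly():
    """Rotation must not change the fitted common variance (tol 1e-8):
    diag(P Phi P') equals diag(A A') of the unrotated solution."""
    params = _oblique3(5_000, seed=11)
    sm = generate_surveys(params)
    sol = fit_factor_model(pd.DataFrame(sm.continuous), 3)
    lam = sol.loadings.to_numpy()
    comm_rot = np.diag(lam @ sol.factor_corr @ lam.T)
    a = sol.loadings_unrotated
    np.testing.assert_allclose(comm_rot, np.diag(a @ a.T), atol=1e-8)


def test_uncorrelated_data_has_no_common_variance():
    """Pure noise has nothing to extract: communalities collapse toward
    zero except for degenerate Heywood directions, which must be flagged."""
    rng = np.random.default_rng(2)
    data = pd.DataFrame(rng.standard_normal((4000, 8)))
    sol = fit_factor_model(data, 2)
    comm = 1 - sol.uniqueness.to_numpy()
    assert np.median(comm) < 0.05
    # any sizable communality on noise is a Heywood artifact and is flagged
    assert comm.max() < 0.1 or sol.heywood


def test_tenberge_scores_reproduce_factor_correlations():
    params = _oblique3(10_000, seed=12)
    sm = generate_surveys(params)
    data = pd.DataFrame(sm.continuous, columns=params.item_names)
    sol = fit_factor_model(data, 3)
    scores = score_tenberge(sol, data)
    assert np.abs(np.corrcoef(scores.to_numpy().T) - sol.factor_corr).max() < 0.05

    # scores regress on the generating latent factors with slope > 0.8
    perm, signs, _ = align_solution(sol.loadings.to_numpy(), params.loadings)
    for j in range(3):
        f_true = sm.latent[:, j]
        f_est = signs[j] * scores.to_numpy()[:, perm[j]]
        slope = np.polyfit(f_true, f_est, 1)[0]
        assert slope > 0.8


def test_tenberge_orthogonal_solution_gives_uncorrelated_scores():
    params = _params(np.full((8, 1), 0.8), np.eye(1), 5_000, seed=13)
    sm = generate_surveys(params)
    data = pd.DataFrame(sm.continuous)
    sol = fit_factor_model(data, 1)
    scores = score_tenberge(sol, data)
    assert abs(np.corrcoef(scores.to_numpy().T) - 1.0).max() < 1e-9 if scores.shape[1] == 1 else True


def test_tenberge_dimension_mismatch():
    params = _oblique3(1000, seed=14)
    sm = generate_surveys(params)
    data = pd.DataFrame(sm.continuous)
    sol = fit_factor_model(data, 3)
    with pytest.raises(ValueError):
        score_tenberge(sol, data.iloc[:, :5])


def test_tucker_congruence_of_identical_loadings():
    lam = np.array([[0.7, 0.0], [0.6, 0.1], [0.0, 0.8]])
    c = tucker_congruence(lam, lam)
    np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)
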