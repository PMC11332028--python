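"""Response labeling, d-prime, 2-SD standardization and the mixed-effects
memory regression."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import rpe_memory as rm
from rpe_memory.memory_glm import (
    GLMDesign,
    SeparationError,
    categorize_responses,
    compute_dprime,
    fit_memory_glm,
    standardize,
)
from rpe_memory.sampling import MCMCConfig


def _probe_frame(rows):
    return pd.DataFrame(rows, columns=["is_old", "response"]).assign(
        subject="a", rt=1.0, pm=2.0, rpe=0.0, encoding_trial=1
    )


def test_four_way_labels():
    df = _probe_frame(
        [
            (True, "old"),    # hit
            (True, "new"),    # miss
            (False, "new"),   # correct rejection
            (False, "old"),   # false alarm
            (True, "old"),
            (True, "old"),
            (False, "new"),
            (False, "old"),
        ]
    )
    lab = categorize_responses(df)
    counts = lab["label"].value_counts()
    assert counts["hit"] == 3
    assert counts["miss"] == 1
    assert counts["correct_rejection"] == 2
    assert counts["false_alarm"] == 2
    assert lab.loc[lab["label"].isin(["hit", "correct_rejection"]), "correct"].all()
    assert not lab.loc[lab["label"].isin(["miss", "false_alarm"]), "correct"].any()


def test_missing_responses_dropped():
    df = _probe_frame([(True, "old"), (True, None)])
    lab = categorize_responses(df)
    assert len(lab) == 1


def test_label_counts_conserved(recognition_frame):
    lab = categorize_responses(recognition_frame)
    for _, grp in lab.groupby("subject"):
        old = grp[grp["is_old"]]
        new = grp[~grp["is_old"]]
        assert (old["label"] == "hit").sum() + (old["label"] == "miss").sum() == len(old)
        assert (new["label"] == "correct_rejection").sum() + (
            new["label"] == "false_alarm"
        ).sum() == len(new)


def test_dprime_examples():
    # hit rate == false-alarm rate -> 0
    rows = [(True, "old")] * 4 + [(True, "new")] * 6 + [(False, "old")] * 4 + [(False, "new")] * 6
    assert abs(compute_dprime(categorize_responses(_probe_frame(rows)))) < 1e-12

    # 0.8 hits / 0.2 false alarms -> 1.6832
    rows = [(True, "old")] * 8 + [(True, "new")] * 2 + [(False, "old")] * 2 + [(False, "new")] * 8
    d = compute_dprime(categorize_responses(_probe_frame(rows)))
    assert abs(d - 1.6832) < 1e-3


def test_dprime_extreme_rate_clamp():
    """A perfect hit rate over 60 old probes is clamped to 1 - 1/120."""
    rows = [(True, "old")] * 60 + [(False, "old")] * 30 + [(False, "new")] * 30
    d = compute_dprime(categorize_responses(_probe_frame(rows)))
    expected = stats.norm.ppf(1 - 1 / 120) - stats.norm.ppf(0.5)
    assert abs(d - expected) < 1e-10


def test_dprime_requires_both_probe_classes():
    rows = [(True, "old")] * 5
    with pytest.raises(ValueError):
        compute_dprime(categorize_responses(_probe_frame(rows)))


def test_dprime_monotone_in_rates():
    def d(h, f, n=100):
        hr = stats.norm.ppf(np.clip(h, 1 / (2 * n), 1 - 1 / (2 * n)))
        fr = stats.norm.ppf(np.clip(f, 1 / (2 * n), 1 - 1 / (2 * n)))
        return hr - fr

    hs = np.linspace(0.05, 0.95, 10)
    assert np.all(np.diff([d(h, 0.2) for h in hs]) > 0)
    assert np.all(np.diff([d(0.8, f) for f in hs]) < 0)


def test_standardize_two_point():
    """A balanced binary vector maps onto symmetric values approaching
    +/-0.5 (exactly so under the population SD; the n-1 estimator shrinks
    them by sqrt(1 - 1/n))."""
    n = 2000
    x = np.array([0, 1] * n, dtype=float)
    vals = np.sort(np.unique(standardize(x)))
    np.testing.assert_allclose(vals, [-0.5, 0.5], atol=1e-3)
    np.testing.assert_allclose(vals, [-0.5, 0.5] / np.sqrt(1 + 1 / (2 * n - 1)), atol=1e-12)


def test_standardize_arithmetic():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    np.testing.assert_allclose(standardize(x), (x - 3.0) / (2 * x.std(ddof=1)), atol=1e-14)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40).filter(
        lambda xs: np.std(xs) > 1e-6
    )
)
def test_standardize_properties(xs):
    z = standardize(np.array(xs))
    assert abs(z.mean()) < 1e-8
    assert abs(z.std(ddof=1) - 0.5) < 1e-8
    # idempotent up to scale: re-standardizing returns the same vector
    np.testing.assert_allclose(standardize(z), z, atol=1e-9)


def test_standardize_constant_raises():
    with pytest.raises(ValueError):
        standardize(np.ones(5))


def test_glm_recovers_generating_rpe_effect(recognition_frame):
    """The generating log-odds slope on standardized RPE (0.5) falls in the
    95% HDI of its fixed effect."""
    lab = categorize_responses(recognition_frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_memory_glm(lab, GLMDesign(), mcmc=MCMCConfig(4, 1000, 1000, seed=3))
    row = fit.fixed_effects.set_index("term").loc["rpe"]
    assert row["hdi_low"] < 0.5 < row["hdi_high"]
    assert row["meaningful"]  # an effect this size should exclude zero
    assert fit.max_rhat < 1.1


def test_glm_null_outcomes_center_intercept():
    """Coin-flip outcomes independent of all predictors concentrate the
    intercept near zero."""
    rng = np.random.default_rng(0)
    n_subj, n_probes = 12, 80
    rows = []
    for i in range(n_subj):
        rows.append(
            pd.DataFrame(
                {
                    "subject": f"s{i}",
                    "is_old": [True, False] * (n_probes // 2),
                    "rpe": np.where(
                        [True, False] * (n_probes // 2), rng.normal(size=n_probes), np.nan
                    ),
                    "pm": rng.uniform(1.5, 3.0, n_probes),
                    "encoding_trial": rng.integers(1, 13, n_probes),
                    "correct": rng.integers(0, 2, n_probes),
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_memory_glm(
            df,
            GLMDesign(random_rpe=False, random_pm=False),
            mcmc=MCMCConfig(4, 600, 600, seed=4),
        )
    row = fit.fixed_effects.set_index("term").loc["intercept"]
    assert abs(row["mean"]) < 0.15
    assert row["hdi_low"] < 0 < row["hdi_high"]


def test_glm_rejects_degenerate_outcomes(recognition_frame):
    lab = categorize_responses(recognition_frame).copy()
    lab["correct"] = 1
    with pytest.raises(SeparationError):
        fit_memory_glm(lab)


def test_exported_subject_slopes_track_generating_slopes(rw_cohort):
    """Per-subject random RPE slopes from the fit correlate with the
    per-subject generating slopes (heterogeneous cohort)."""
    recog, truth = rm.simulate_recognition(
        rw_cohort,
        [ds.true_rpe for ds in rw_cohort],
        rm.GenerativeMemoryParams(b_rpe=0.3, b_rpe_sd=0.6, b_pm_sd=0.0, subject_sd=0.3),
        seed=21,
        return_truth=True,
    )
    lab = categorize_responses(recog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_memory_glm(lab, GLMDesign(), mcmc=MCMCConfig(4, 800, 800, seed=22))
    est = fit.subject_beta_rpe.reindex(truth["subject"]).to_numpy()
    r = stats.pearsonr(est, truth["beta_rpe"].to_numpy())[0]
    assert r > 0.5
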