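"""RT exclusions and the hierarchical drift-regression model."""

import warnings

import numpy as np
import pandas as pd
import pytest

import rpe_memory as rm
from rpe_memory.ddm import (
    DDMParams,
    DriftRegressionSpec,
    compare_ddm_models,
    filter_rts,
    fit_hier_ddm,
)
from rpe_memory.sampling import MCMCConfig


def test_ddm_params_validation():
    with pytest.raises(ValueError):
        DDMParams(a=-1, z=0.5, t=0.1)
    with pytest.raises(ValueError):
        DDMParams(a=1, z=1.5, t=0.1)
    with pytest.raises(ValueError):
        DDMParams(a=1, z=0.5, t=-0.1)


def _frame(subjects, rts):
    return pd.DataFrame(
        {
            "subject": subjects,
            "rt": rts,
            "response": "old",
            "is_old": True,
            "rpe": 0.1,
            "pm": 2.0,
        }
    )


def test_filter_keeps_clean_data():
    rng = np.random.default_rng(0)
    df = _frame(["a"] * 30, rng.uniform(0.4, 2.0, 30))
    kept, rep = filter_rts(df)
    assert rep.n_excluded_fast == rep.n_excluded_slow == 0
    assert len(kept) >= 28  # at most a stray 3-SD outlier


def test_filter_absolute_bounds():
    df = _frame(["a"] * 5, [0.1, 0.5, 0.6, 11.0, 0.7])
    kept, rep = filter_rts(df)
    assert rep.n_excluded_fast == 1
    assert rep.n_excluded_slow == 1
    assert len(kept) == 3


def test_filter_three_sd_rule():
    """29 trials at 0.5 s plus one at 5 s: the slow trial is beyond 3
    subject-level SDs and is dropped."""
    rts = [0.5] * 29 + [5.0]
    df = _frame(["a"] * 30, rts)
    kept, rep = filter_rts(df)
    assert rep.n_excluded_sd == 1
    assert 5.0 not in kept["rt"].to_numpy()


def test_filter_flags_sparse_subjects():
    df = pd.concat(
        [_frame(["a"] * 30, np.linspace(0.4, 1.2, 30)), _frame(["b"], [0.1])],
        ignore_index=True,
    )
    kept, rep = filter_rts(df)
    assert "b" in rep.flagged_subjects
    assert set(kept["subject"]) == {"a"}


def test_filter_rejects_nonpositive_rts():
    with pytest.raises(ValueError):
        filter_rts(_frame(["a"] * 2, [-0.5, 0.4]))


@pytest.fixture(scope="module")
def coupled_recognition():
    """Cohort whose recognition responses and RTs come jointly from the
    diffusion, with the group drift slope on RPE at its default 0.046."""
    cohort = []
    for i in range(20):
        sched = rm.generate_task_schedule(rm.TaskConfig(seed=500 + i))
        cohort.append(
            rm.simulate_agent(
                rm.AgentSpec("rw", {"alpha": 0.7, "beta": 5.0}),
                sched,
                seed=600 + i,
                subject=f"d{i:02d}",
            )
        )
    recog = rm.simulate_recognition(
        cohort,
        [c.true_rpe for c in cohort],
        rm.GenerativeMemoryParams(),
        seed=9,
        couple_rt_to_response=True,
    )
    kept, _ = filter_rts(recog)
    return kept


def test_hier_ddm_recovers_generating_parameters(coupled_recognition):
    """Pooled a, z, t and the drift slope on standardized RPE are
    recovered: point estimates near truth, slope inside its 95% HDI."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_hier_ddm(
            coupled_recognition,
            DriftRegressionSpec("rpe"),
            MCMCConfig(4, 500, 500, seed=10),
        )
    means = fit.summary.set_index("parameter")["mean"]
    assert abs(means["a"] - 1.8) / 1.8 < 0.1
    assert abs(means["t"] - 0.35) / 0.35 < 0.1
    assert abs(means["z"] - 0.5) < 0.05
    lo, hi = fit.hdi("v_slope")
    assert lo < 0.046 < hi
    assert fit.max_rhat < 1.1


def test_ddm_model_comparison_prefers_generating_covariate():
    """With a strong linear RPE drift slope and no PM slope, WAIC ranks the
    RPE regression above the PM regression and above a quadratic-RPE
    distortion; identical fits compare with zero difference."""
    cohort = []
    for i in range(20):
        sched = rm.generate_task_schedule(rm.TaskConfig(seed=900 + i))
        cohort.append(
            rm.simulate_agent(
                rm.AgentSpec("rw", {"alpha": 0.7, "beta": 5.0}),
                sched,
                seed=950 + i,
                subject=f"c{i:02d}",
            )
        )
    gen = rm.GenerativeMemoryParams(
        ddm=rm.recognition.DDMGenParams(v_rpe=0.4, v_pm=0.0)
    )
    recog = rm.simulate_recognition(
        cohort, [c.true_rpe for c in cohort], gen, seed=33, couple_rt_to_response=True
    )
    data, _ = filter_rts(recog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = {
            name: fit_hier_ddm(data, spec, MCMCConfig(4, 300, 300, seed=20 + j))
            for j, (name, spec) in enumerate(
                {
                    "rpe_linear": DriftRegressionSpec("rpe"),
                    "pm_linear": DriftRegressionSpec("pm"),
                    "rpe_quadratic": DriftRegressionSpec("rpe", link="quadratic"),
                }.items()
            )
        }
    ranking = compare_ddm_models(fits).set_index("model")
    assert ranking.index[0] == "rpe_linear"
    assert ranking.loc["pm_linear", "d_waic"] > 0
    assert ranking.loc["rpe_quadratic", "d_waic"] > 0

    same = compare_ddm_models({"a": fits["rpe_linear"], "b": fits["rpe_linear"]})
    assert np.allclose(same["d_waic"], 0.0)


def test_ddm_comparison_rejects_mismatched_trials(coupled_recognition):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_all = fit_hier_ddm(
            coupled_recognition, DriftRegressionSpec("rpe"), MCMCConfig(2, 100, 100, seed=1)
        )
        fit_sub = fit_hier_ddm(
            coupled_recognition.iloc[: len(coupled_recognition) // 2],
            DriftRegressionSpec("rpe"),
            MCMCConfig(2, 100, 100, seed=2),
        )
    with pytest.raises(ValueError):
        compare_ddm_models({"all": fit_all, "sub": fit_sub})


def test_log_link_handles_signed_rpes(coupled_recognition):
    """The shifted-log transform is defined for negative RPEs."""
    spec = DriftRegressionSpec("rpe", link="log")
    x = np.array([-0.9, -0.2, 0.0, 0.4, 0.9])
    g = spec.apply_link(x)
    assert np.all(np.isfinite(g))
    assert g[0] == 0.0  # log(1) at the minimum
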