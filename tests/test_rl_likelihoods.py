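"""Decision-model likelihoods against hand traces and brute-force oracles."""

import numpy as np
import pytest

from conftest import make_dataset
from rpe_memory.rl import (
    BayesParams,
    RWParams,
    WSLSParams,
    bayes_filter_loglik,
    extract_rpes,
    rw_loglik,
    wsls_loglik,
)

# ---------------------------------------------------------------------------
# independent per-trial enumerations (test-local oracles)
# ---------------------------------------------------------------------------

def oracle_rw(alpha, beta, choices, rewards):
    q = [0.5, 0.5]
    logps = []
    for c, r in zip(choices, rewards):
        num = np.exp(beta * q[c])
        den = np.exp(beta * q[0]) + np.exp(beta * q[1])
        logps.append(np.log(num / den))
        q[c] = q[c] + alpha * (r - q[c])
    return np.array(logps)


def oracle_wsls(eps, choices, rewards):
    logps = [np.log(0.5)]
    for t in range(1, len(choices)):
        rule = choices[t - 1] if rewards[t - 1] == 1 else 1 - choices[t - 1]
        logps.append(np.log(eps if choices[t] == rule else 1 - eps))
    return np.array(logps)


def oracle_bayes(p_r, p_s, choices, rewards):
    b = 0.5  # P(arm 0 correct)
    logps = []
    for c, r in zip(choices, rewards):
        b = b * (1 - p_s) + (1 - b) * p_s
        logps.append(np.log(b if c == 0 else 1 - b))
        like = []
        for state in (0, 1):
            correct_choice = c == state
            if r == 1:
                like.append(p_r if correct_choice else 1 - p_r)
            else:
                like.append(1 - p_r if correct_choice else p_r)
        b = b * like[0] / (b * like[0] + (1 - b) * like[1])
    return np.array(logps)


FIVE_TRIALS = ([0, 1, 1, 0, 1], [1, 0, 1, 1, 0])


@pytest.mark.parametrize(
    "params_model",
    [
        ("rw", RWParams(0.3, 2.5)),
        ("rw", RWParams(0.9, 0.7)),
        ("wsls", WSLSParams(0.85)),
        ("bayes", BayesParams(0.8, 0.1)),
        ("bayes", BayesParams(0.6, 0.35)),
    ],
)
def test_likelihoods_match_bruteforce_enumeration(params_model):
    model, params = params_model
    choices, rewards = FIVE_TRIALS
    ds = make_dataset(choices, rewards)
    if model == "rw":
        got = rw_loglik(params, ds).per_trial_logp
        want = oracle_rw(params.alpha, params.beta, choices, rewards)
    elif model == "wsls":
        got = wsls_loglik(params, ds)[1]
        want = oracle_wsls(params.epsilon, choices, rewards)
    else:
        got = bayes_filter_loglik(params, ds).per_trial_logp
        want = oracle_bayes(params.p_reward, params.p_switch, choices, rewards)
    np.testing.assert_allclose(got, want, atol=1e-12, rtol=0)


def test_rw_hand_trace():
    """alpha=0.5, beta=2, choices (A,A,B), rewards (1,0,1): per-trial choice
    probabilities (0.5, 0.6225, 0.5622), total log-likelihood -1.7431,
    RPE series (0.5, -0.75, 0.5)."""
    res = rw_loglik(RWParams(0.5, 2.0), make_dataset([0, 0, 1], [1, 0, 1]))
    np.testing.assert_allclose(
        np.exp(res.per_trial_logp), [0.5, 0.62245933, 0.56217650], atol=1e-6
    )
    assert abs(res.total - (-1.7431)) < 1e-3
    np.testing.assert_allclose(res.rpe, [0.5, -0.75, 0.5], atol=1e-12)


def test_rw_zero_beta_is_chance():
    ds = make_dataset([0, 1, 0, 1, 1, 0], [1, 0, 0, 1, 1, 0])
    res = rw_loglik(RWParams(0.42, 0.0), ds)
    assert abs(res.total - 6 * np.log(0.5)) < 1e-12


def test_rw_choice_probabilities_sum_to_one():
    """Softmax probabilities over both arms sum to 1 at every trial."""
    rng = np.random.default_rng(0)
    choices = rng.integers(2, size=10)
    rewards = rng.integers(2, size=10)
    for beta in (0.0, 1.3, 7.0):
        p_a = np.exp(rw_loglik(RWParams(0.4, beta), make_dataset(choices, rewards)).per_trial_logp)
        # complementary choices on identical histories
        res_b = rw_loglik(RWParams(0.4, beta), make_dataset(1 - choices, rewards))
        # only trial 1 shares the same Q state across both datasets
        assert abs(p_a[0] + np.exp(res_b.per_trial_logp[0]) - 1.0) < 1e-12


def test_rw_value_fixed_point_decay():
    """With constant reward r the value converges to r geometrically:
    |Q_t - r| = (1 - alpha)^t |Q_0 - r|."""
    alpha = 0.3
    ds = make_dataset([0] * 12, [1] * 12)
    res = rw_loglik(RWParams(alpha, 1.0), ds)
    gaps = 1.0 - res.q[:, 0]
    np.testing.assert_allclose(gaps, 0.5 * (1 - alpha) ** np.arange(12), atol=1e-12)


def test_wsls_uninformative_at_half():
    ds = make_dataset([0, 1, 0, 1], [1, 1, 0, 0])
    total, _ = wsls_loglik(WSLSParams(0.5), ds)
    assert abs(total - 4 * np.log(0.5)) < 1e-12


def test_wsls_rule_readoff():
    # win then stay: second-trial likelihood = epsilon
    _, logp = wsls_loglik(WSLSParams(0.9), make_dataset([0, 0], [1, 0]))
    assert abs(np.exp(logp[1]) - 0.9) < 1e-12
    # (A, lose, A, win, B): ln 0.5 + ln 0.1 + ln 0.1
    total, _ = wsls_loglik(WSLSParams(0.9), make_dataset([0, 0, 1], [0, 1, 0]))
    assert abs(total - (np.log(0.5) + 2 * np.log(0.1))) < 1e-12


def test_bayes_flat_likelihood_stays_at_chance():
    res = bayes_filter_loglik(
        BayesParams(0.5 + 1e-12, 0.1), make_dataset([0, 1, 0, 1], [1, 0, 1, 0])
    )
    np.testing.assert_allclose(np.exp(res.per_trial_logp), 0.5, atol=1e-9)


def test_bayes_one_step_hand_trace():
    """p_switch=0.1, p_reward=0.8, observe (choose A, win): posterior
    (0.8, 0.2), next predictive prior 0.74 = next P(choose A)."""
    res = bayes_filter_loglik(BayesParams(0.8, 0.1), make_dataset([0, 0], [1, 1]))
    assert abs(res.posterior[0] - 0.8) < 1e-12
    assert abs(res.predictive[1] - 0.74) < 1e-12
    assert abs(np.exp(res.per_trial_logp[1]) - 0.74) < 1e-12


def test_bayes_pure_accumulation_when_no_switching():
    """With p_switch -> 0 the filter reduces to exact Bayesian updating:
    posterior matches the direct product-of-likelihoods oracle and
    converges monotonically to 1 under consistent evidence."""
    p_r, eps = 0.8, 1e-9
    choices = [0] * 10
    rewards = [1] * 10
    res = bayes_filter_loglik(BayesParams(p_r, eps), make_dataset(choices, rewards))
    direct = []
    for t in range(1, 11):
        l0 = p_r**t
        l1 = (1 - p_r) ** t
        direct.append(0.5 * l0 / (0.5 * l0 + 0.5 * l1))
    np.testing.assert_allclose(res.posterior, direct, atol=1e-6)
    assert np.all(np.diff(res.posterior) > 0)
    # posterior over the two states always sums to 1 by construction
    assert np.all((res.posterior >= 0) & (res.posterior <= 1))


def test_bayes_softmax_action_rule():
    """The alternative softmax-on-expected-reward rule: zero gain is
    chance, and an invalid rule name is rejected."""
    ds = make_dataset([0, 1, 0], [1, 0, 1])
    res = bayes_filter_loglik(BayesParams(0.8, 0.1), ds, action_rule="softmax", softmax_gain=0.0)
    np.testing.assert_allclose(np.exp(res.per_trial_logp), 0.5, atol=1e-12)
    # positive gain favors the arm with higher expected reward
    res2 = bayes_filter_loglik(
        BayesParams(0.8, 0.1), make_dataset([0, 0], [1, 1]), action_rule="softmax",
        softmax_gain=5.0,
    )
    assert np.exp(res2.per_trial_logp[1]) > 0.5
    with pytest.raises(ValueError):
        bayes_filter_loglik(BayesParams(0.8, 0.1), ds, action_rule="greedy")


def test_reward_coding_guard():
    ds = make_dataset([0, 1], [1, 0])
    ds.rewards = np.array([100, 0])
    with pytest.raises(ValueError):
        rw_loglik(RWParams(0.5, 1.0), ds)


def test_rpe_bounds_on_random_data():
    rng = np.random.default_rng(3)
    ds = make_dataset(rng.integers(2, size=60), rng.integers(2, size=60))
    res = rw_loglik(RWParams(0.8, 3.0), ds)
    assert np.all(res.rpe >= -1.0) and np.all(res.rpe <= 1.0)


def test_rpe_closed_form_under_constant_reward():
    """All-reward sequence: RPE_t = (1 - alpha)^t * 0.5, shrinking
    monotonically from the 0.5 initialization."""
    alpha = 0.4
    ds = make_dataset([1] * 8, [1] * 8)
    res = rw_loglik(RWParams(alpha, 2.0), ds)
    np.testing.assert_allclose(res.rpe, 0.5 * (1 - alpha) ** np.arange(8), atol=1e-12)
    assert res.rpe[0] == 0.5
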