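"""Conjugate updating and between-arm comparison probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screentrial.bayes import (
    ArmState,
    BetaParams,
    compare_arms,
    prob_best,
    prob_best_two_arm_exact,
    prob_within_margin,
    prob_within_margin_two_arm_exact,
    update_posterior,
)
from screentrial.errors import ConfigurationError, InvalidInputError

from conftest import oracle_prob_best, oracle_prob_within_margin


@pytest.mark.parametrize(
    "prior, n, s, expected",
    [
        (BetaParams(100, 100), 0, 0, (100, 100)),
        (BetaParams(100, 100), 100, 60, (160, 140)),
        (BetaParams(1, 1), 10, 10, (11, 1)),
    ],
)
def test_update_posterior_conjugacy(prior, n, s, expected):
    post = update_posterior(prior, n, s)
    assert (post.alpha, post.beta) == expected


@pytest.mark.parametrize(
    "n, s, message",
    [(-1, 0, "n_outcomes"), (5, -1, "n_attended"), (5, 6, "n_attended")],
)
def test_update_posterior_rejects_bad_counts(n, s, message):
    with pytest.raises(InvalidInputError, match=message):
        update_posterior(BetaParams(100, 100), n, s)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    n1=st.integers(0, 500),
    n2=st.integers(0, 500),
    data=st.data(),
)
def test_update_posterior_batch_associativity(n1, n2, data):
    """Updating in two batches equals one update with the pooled counts."""
    s1 = data.draw(st.integers(0, n1))
    s2 = data.draw(st.integers(0, n2))
    prior = BetaParams(100, 100)
    stepwise = update_posterior(update_posterior(prior, n1, s1), n2, s2)
    pooled = update_posterior(prior, n1 + n2, s1 + s2)
    assert stepwise == pooled


def test_posterior_mean_shrinks_toward_prior():
    """With a regularising prior the posterior mean lies strictly between the
    prior mean and the empirical proportion."""
    prior = BetaParams(100, 100)
    post = update_posterior(prior, 50, 40)  # empirical 0.8, prior mean 0.5
    assert prior.mean < post.mean < 0.8
    post_low = update_posterior(prior, 50, 10)  # empirical 0.2
    assert 0.2 < post_low.mean < prior.mean


def _arm(arm_id, alpha, beta):
    """Arm with a directly specified posterior (counts immaterial here)."""
    return ArmState(
        arm_id=arm_id,
        n_allocated=10**6,
        n_outcomes_observed=10**6,
        n_attended=0,
        posterior=BetaParams(alpha, beta),
    )


def test_prob_best_symmetry_two_and_three_arms():
    arms2 = [_arm("A", 160, 140), _arm("B", 160, 140)]
    n_draws = 40_000
    comp = prob_best(arms2, n_draws=n_draws, seed=7)
    tol = 3 / np.sqrt(n_draws)
    assert abs(comp.p_best["A"] - 0.5) < tol
    arms3 = [_arm(a, 100, 100) for a in "ABC"]
    comp3 = prob_best(arms3, n_draws=n_draws, seed=8)
    for a in "ABC":
        assert abs(comp3.p_best[a] - 1 / 3) < tol


def test_p_best_sums_to_one_exactly():
    arms = [_arm("A", 3, 2), _arm("B", 2, 3), _arm("C", 4, 4)]
    comp = prob_best(arms, n_draws=10_000, seed=3)
    assert sum(comp.p_best.values()) == pytest.approx(1.0, abs=1e-12)


# frozen by independent adaptive quadrature (scipy.integrate.quad, err < 1e-8)
FROZEN_P_BEST_160_140 = 0.9490908
FROZEN_P_MARGIN_2_1 = 0.0133333
FROZEN_P_MARGIN_100_100 = 0.1586226


def test_prob_best_matches_frozen_quadrature_value():
    a, b = _arm("A", 160, 140), _arm("B", 140, 160)
    n_draws = 100_000
    comp = prob_best([a, b], n_draws=n_draws, seed=11)
    assert abs(comp.p_best["A"] - FROZEN_P_BEST_160_140) < 4 / np.sqrt(n_draws)
    exact = prob_best_two_arm_exact(a.posterior, b.posterior)
    assert exact == pytest.approx(FROZEN_P_BEST_160_140, abs=1e-5)


@pytest.mark.parametrize(
    "params, frozen",
    [
        (((2, 1), (1, 2)), FROZEN_P_MARGIN_2_1),
        (((100, 100), (100, 100)), FROZEN_P_MARGIN_100_100),
    ],
)
def test_prob_within_margin_matches_frozen_quadrature(params, frozen):
    (a1, b1), (a2, b2) = params
    arms = [_arm("A", a1, b1), _arm("B", a2, b2)]
    n_draws = 100_000
    mc = prob_within_margin(arms, margin=0.01, n_draws=n_draws, seed=12)
    assert abs(mc - frozen) < 4 / np.sqrt(n_draws)
    exact = prob_within_margin_two_arm_exact(
        arms[0].posterior, arms[1].posterior, 0.01
    )
    assert exact == pytest.approx(frozen, abs=1e-4)


def test_prob_within_margin_degenerate_concentration():
    """Posteriors concentrated at the same point are equivalent within any margin."""
    arms = [_arm("A", 5e5, 5e5), _arm("B", 5e5, 5e5)]
    assert prob_within_margin(arms, margin=0.01, n_draws=20_000, seed=1) > 0.999
    assert (
        prob_within_margin_two_arm_exact(arms[0].posterior, arms[1].posterior, 0.01)
        > 0.999
    )


def test_two_arm_estimates_match_independent_2d_oracle():
    """MC and quadrature agree with brute-force 2-D summation over 20 random
    posterior pairs."""
    rng = np.random.default_rng(2026)
    n_draws = 20_000
    tol = 4 / np.sqrt(n_draws)
    for _ in range(20):
        a = BetaParams(*rng.uniform(1, 300, 2))
        b = BetaParams(*rng.uniform(1, 300, 2))
        expected = oracle_prob_best(a, b)
        arms = [_arm("A", a.alpha, a.beta), _arm("B", b.alpha, b.beta)]
        mc = prob_best(arms, n_draws=n_draws, seed=int(rng.integers(2**31)))
        assert abs(mc.p_best["A"] - expected) < tol
        assert abs(prob_best_two_arm_exact(a, b) - expected) < 2e-3


def test_margin_estimates_match_independent_2d_oracle():
    rng = np.random.default_rng(99)
    for _ in range(5):
        a = BetaParams(*rng.uniform(1, 200, 2))
        b = BetaParams(*rng.uniform(1, 200, 2))
        expected = oracle_prob_within_margin(a, b, 0.05)
        assert prob_within_margin_two_arm_exact(a, b, 0.05) == pytest.approx(
            expected, abs=3e-3
        )


def test_prob_within_margin_monotone_in_margin():
    """On the same joint draws, widening the margin can only increase the
    equivalence probability."""
    arms = [_arm("A", 120, 80), _arm("B", 100, 100)]
    values = [
        prob_within_margin(arms, margin=m, n_draws=20_000, seed=42)
        for m in (0.005, 0.01, 0.05, 0.1, 0.3)
    ]
    assert all(v1 <= v2 for v1, v2 in zip(values, values[1:]))


def test_compare_arms_exact_and_mc_paths_agree():
    arms = [_arm("control", 160, 140), _arm("intervention", 150, 150)]
    exact = compare_arms(arms, margin=0.01, method="exact")
    n_draws = 100_000
    mc = compare_arms(arms, margin=0.01, n_draws=n_draws, seed=5, method="mc")
    tol = 4 / np.sqrt(n_draws)
    assert abs(exact.p_best["control"] - mc.p_best["control"]) < tol
    assert abs(exact.p_equivalent - mc.p_equivalent) < tol
    assert exact.method == "exact" and mc.method == "mc"


def test_comparison_reproducible_given_seed():
    arms = [_arm("A", 50, 60), _arm("B", 55, 55)]
    c1 = compare_arms(arms, margin=0.01, n_draws=5000, seed=17, method="mc")
    c2 = compare_arms(arms, margin=0.01, n_draws=5000, seed=17, method="mc")
    assert c1.p_best == c2.p_best and c1.p_equivalent == c2.p_equivalent


@pytest.mark.parametrize(
    "call",
    [
        lambda: prob_best([_arm("A", 1, 1)], n_draws=10, seed=0),
        lambda: prob_within_margin(
            [_arm("A", 1, 1), _arm("B", 1, 1)], margin=0.0, n_draws=10, seed=0
        ),
        lambda: prob_best([_arm("A", 1, 1), _arm("B", 1, 1)], n_draws=0, seed=0),
        lambda: compare_arms(
            [_arm("A", 1, 1), _arm("B", 1, 1), _arm("C", 1, 1)],
            margin=0.01,
            method="exact",
        ),
    ],
)
def test_invalid_comparison_inputs_raise(call):
    with pytest.raises((InvalidInputError, ConfigurationError)):
        call()


def test_beta_params_validation():
    with pytest.raises(InvalidInputError):
        BetaParams(0, 1)
    with pytest.raises(InvalidInputError):
        BetaParams(1, -2)
    assert 0 < BetaParams(100, 100).mean < 1


def test_arm_state_count_ordering_enforced():
    with pytest.raises(InvalidInputError):
        ArmState("A", n_allocated=5, n_outcomes_observed=6, n_attended=1)
    with pytest.raises(InvalidInputError):
        ArmState("A", n_allocated=5, n_outcomes_observed=5, n_attended=6)
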