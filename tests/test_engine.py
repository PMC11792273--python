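"""Trial-engine loop: termination, reproducibility, replay."""

import numpy as np
import pandas as pd
import pytest

from screentrial import (
    Arm,
    PopulationSpec,
    StoppingThresholds,
    Subgroup,
    TrialConfig,
    replay_recorded,
    run_trial,
)
from screentrial.bayes import BetaParams, prob_best_two_arm_exact
from screentrial.errors import ConfigurationError, SchemaError


def test_extreme_effect_always_finds_the_winner(two_arm_config, uniform_population):
    """A 0.50 vs 0.90 contrast is decisive at the very first interims."""
    for seed in range(50):
        result = run_trial(
            two_arm_config(seed=seed),
            uniform_population(effect=0.40, seed=seed),
            record_participants=False,
        )
        assert result.decision.reason == "rule1_superiority"
        assert result.decision.winner == "intervention"


def test_absurdly_wide_margin_stops_by_equivalence_immediately(
    two_arm_config, uniform_population
):
    config = two_arm_config(thresholds=StoppingThresholds(margin=0.5))
    result = run_trial(config, uniform_population())
    assert result.decision.reason == "rule2_equivalence"
    assert result.n_interims == 1 and result.decision.winner is None


def test_ceiling_truncates_at_exactly_the_maximum(two_arm_config, uniform_population):
    config = two_arm_config(
        thresholds=StoppingThresholds(ceiling_n=100, margin=1e-6, x_best=0.999)
    )
    result = run_trial(config, uniform_population())
    assert result.decision.reason == "rule3_ceiling"
    assert result.total_enrolled == 100 and result.decision.winner is None


def test_trial_fully_reproducible_from_master_seed(two_arm_config, uniform_population):
    r1 = run_trial(two_arm_config(seed=77), uniform_population(effect=0.05, seed=77))
    r2 = run_trial(two_arm_config(seed=77), uniform_population(effect=0.05, seed=77))
    assert r1.to_dict() == r2.to_dict()
    pd.testing.assert_frame_equal(r1.participants, r2.participants)
    pd.testing.assert_frame_equal(r1.interim_log, r2.interim_log)


def test_counts_conserved_at_every_interim(two_arm_config, uniform_population):
    result = run_trial(two_arm_config(seed=5), uniform_population(effect=0.1, seed=5))
    log = result.interim_log
    assert (log["n_control"] + log["n_intervention"] == log["total_enrolled"]).all()
    assert result.total_enrolled == sum(
        s.n_allocated for s in result.per_arm.values()
    )
    assert result.total_enrolled == len(result.participants)
    # immediate-outcome mode: every allocated participant has an outcome
    for s in result.per_arm.values():
        assert s.n_outcomes_observed == s.n_allocated


def test_replay_of_simulated_records_reproduces_the_trial(
    two_arm_config, uniform_population
):
    config = two_arm_config(seed=13)
    result = run_trial(config, uniform_population(effect=0.08, seed=13))
    replayed = replay_recorded(result.participants, config)
    assert replayed.decision == result.decision
    assert replayed.n_interims == result.n_interims
    for arm_id, state in result.per_arm.items():
        assert replayed.per_arm[arm_id].n_attended == state.n_attended
        assert replayed.per_arm[arm_id].posterior == state.posterior


def test_replay_one_sided_records_stop_early_for_the_good_arm(two_arm_config):
    """All 200 outcomes favouring one arm trigger a superiority stop within
    two interims, consistent with the exact posterior comparison."""
    records = pd.DataFrame(
        {
            "arm": ["control", "intervention"] * 100,
            "attended": [False, True] * 100,
            "window": [i // 100 for i in range(200)],
        }
    )
    config = two_arm_config()
    result = replay_recorded(records, config)
    assert result.decision.reason == "rule1_superiority"
    assert result.decision.winner == "intervention"
    assert result.n_interims <= 2
    # cross-check the stopping probability against the exact comparison
    s = result.per_arm["intervention"]
    c = result.per_arm["control"]
    p = prob_best_two_arm_exact(s.posterior, c.posterior)
    assert p > config.thresholds.x_best
    assert result.decision.p_best_at_stop["intervention"] == pytest.approx(p, abs=1e-9)


def test_replay_schema_validation(two_arm_config):
    config = two_arm_config()
    with pytest.raises(SchemaError, match="attended"):
        replay_recorded(pd.DataFrame({"arm": ["control"]}), config)
    bad_arm = pd.DataFrame({"arm": ["mystery"] * 4, "attended": [True] * 4})
    with pytest.raises(SchemaError, match="mystery"):
        replay_recorded(bad_arm, config)
    non_monotone = pd.DataFrame(
        {"arm": ["control"] * 3, "attended": [True] * 3, "window": [0, 2, 1]}
    )
    with pytest.raises(SchemaError, match="monotone"):
        replay_recorded(non_monotone, config)


def test_replay_may_run_out_of_data_without_stopping(two_arm_config):
    records = pd.DataFrame(
        {"arm": ["control", "intervention"] * 25, "attended": [True, True] * 25}
    )
    result = replay_recorded(records, two_arm_config())
    assert not result.decision.stopped
    assert result.total_enrolled == 50


def test_guard_stops_pathological_unbounded_runs(two_arm_config, uniform_population):
    config = two_arm_config(
        thresholds=StoppingThresholds(ceiling_n=None, margin=1e-9, x_best=0.9999)
    )
    result = run_trial(
        config, uniform_population(), record_participants=False, guard_outcomes=300
    )
    assert result.guard_triggered and result.decision.reason == "guard"
    assert result.decision.winner is None


def test_exact_and_mc_comparison_paths_reach_the_same_decision(
    two_arm_config, uniform_population
):
    pop = uniform_population(effect=0.40, seed=4)
    r_exact = run_trial(two_arm_config(seed=4, comparison_method="exact"), pop)
    r_mc = run_trial(two_arm_config(seed=4, comparison_method="mc"), pop)
    assert r_exact.decision.reason == r_mc.decision.reason
    assert r_exact.decision.winner == r_mc.decision.winner
    assert r_exact.total_enrolled == r_mc.total_enrolled


def test_config_validation():
    with pytest.raises(ConfigurationError, match="control"):
        TrialConfig(arms=[Arm("a"), Arm("b")])
    with pytest.raises(ConfigurationError, match="control"):
        TrialConfig(arms=[Arm("a", True), Arm("b", True)])
    with pytest.raises(ConfigurationError, match="ceiling"):
        TrialConfig(
            arms=[Arm("a", True), Arm("b")],
            thresholds=StoppingThresholds(ceiling_n=50),
            interim_every_outcomes=100,
        )
    with pytest.raises(ConfigurationError):
        TrialConfig(arms=[Arm("a", True)])


def test_population_must_cover_all_arms(two_arm_config):
    pop = PopulationSpec(
        subgroups=(Subgroup("all", 1.0, 0.5),), arm_effects={"control": 0.0}, seed=0
    )
    with pytest.raises(ConfigurationError, match="intervention"):
        run_trial(two_arm_config(), pop)


def test_winner_estimate_is_posterior_mean_of_winner(
    two_arm_config, uniform_population
):
    result = run_trial(two_arm_config(seed=2), uniform_population(effect=0.4, seed=2))
    w = result.decision.winner
    assert result.winner_estimate == result.per_arm[w].posterior.mean
    assert result.true_rates == {"control": 0.5, "intervention": 0.9}
    assert result.winner_bias == pytest.approx(result.winner_estimate - 0.9)
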