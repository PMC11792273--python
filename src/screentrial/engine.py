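"""Orchestration of one adaptive individual trial.

The engine couples the referral stream, permuted-block allocation, conjugate
posterior updating, and the stopping rules into the interim-analysis loop the
protocol prescribes: enrol referrals, observe their attendance, and after
every ``interim_every_outcomes`` newly observed outcomes (default 100,
matching the expected 100 referrals per 72-hour window) recompute the
posterior comparison and apply the stopping rules.  The loop always
terminates — by superiority, practical equivalence, the enrolment ceiling,
or (when no ceiling is configured) a generous guard on total outcomes that
flags pathological runs instead of looping forever.

Everything is a deterministic function of ``master_seed`` plus the population
seed: allocation, referral subgroups, latent outcome draws, and the
Monte-Carlo comparison seeds each live on independent counter-based streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import AllocationSpec, BlockRandomizer
from .bayes import (
    DEFAULT_N_DRAWS,
    DEFAULT_PRIOR,
    ArmState,
    BetaParams,
    compare_arms,
)
from .errors import ConfigurationError, SchemaError
from .population import (
    PARTICIPANT_COLUMNS,
    PopulationSpec,
    uniforms_at,
)
from .stopping import StopDecision, StoppingThresholds, evaluate_stopping

__all__ = ["Arm", "TrialConfig", "TrialResult", "run_trial", "replay_recorded"]

# Philox stream tags inside the engine (population streams use 1 and 2)
_STREAM_SUBGROUP = 1
_STREAM_OUTCOME = 2
_STREAM_COMPARISON = 3

GUARD_OUTCOMES = 1_000_000
REASON_GUARD = "guard"


@dataclass(frozen=True)
class Arm:
    arm_id: str
    is_control: bool = False


@dataclass
class TrialConfig:
    """All design knobs for one individual trial."""

    arms: Sequence[Arm]
    prior: BetaParams = field(default_factory=lambda: DEFAULT_PRIOR)
    thresholds: StoppingThresholds = field(default_factory=StoppingThresholds)
    allocation: AllocationSpec | None = None
    interim_every_outcomes: int = 100
    comparison_draws: int = DEFAULT_N_DRAWS
    comparison_method: str = "auto"
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.arms = tuple(
            a if isinstance(a, Arm) else Arm(**a) if isinstance(a, dict) else Arm(*a)
            for a in self.arms
        )
        defects = []
        if len(self.arms) < 2:
            defects.append(f"need at least 2 arms, got {len(self.arms)}")
        n_control = sum(a.is_control for a in self.arms)
        if n_control != 1:
            defects.append(f"exactly one control arm required, got {n_control}")
        if self.interim_every_outcomes < 1:
            defects.append(
                f"interim_every_outcomes must be >= 1, got {self.interim_every_outcomes}"
            )
        ceiling = self.thresholds.ceiling_n
        if ceiling is not None and ceiling < self.interim_every_outcomes:
            defects.append(
                f"ceiling_n ({ceiling}) is smaller than one interim batch "
                f"({self.interim_every_outcomes})"
            )
        if defects:
            raise ConfigurationError(defects)
        if self.allocation is None:
            self.allocation = AllocationSpec(
                arm_ids=tuple(a.arm_id for a in self.arms), seed=self.master_seed
            )

    @property
    def arm_ids(self) -> tuple[str, ...]:
        return tuple(a.arm_id for a in self.arms)

    @property
    def control_arm(self) -> str:
        return next(a.arm_id for a in self.arms if a.is_control)


@dataclass
class TrialResult:
    """Everything a completed (or replayed) trial reports.

    ``true_rates`` holds the generative attendance probability of each arm
    (simulation mode only); together with ``winner_estimate`` — the posterior
    mean of the declared winner — it quantifies the optimistic bias of
    early-stopped winner estimates.
    """

    decision: StopDecision
    per_arm: Mapping[str, ArmState]
    n_interims: int
    total_enrolled: int
    true_rates: Mapping[str, float] | None = None
    winner_estimate: float | None = None
    guard_triggered: bool = False
    interim_log: pd.DataFrame | None = None
    participants: pd.DataFrame | None = None

    @property
    def winner_bias(self) -> float | None:
        """winner_estimate minus the winner's true rate, when both are known."""
        w = self.decision.winner
        if w is None or self.true_rates is None or self.winner_estimate is None:
            return None
        return self.winner_estimate - self.true_rates[w]

    def to_dict(self) -> dict:
        return {
            "decision": {
                "stopped": self.decision.stopped,
                "reason": self.decision.reason,
                "winner": self.decision.winner,
                "p_best_at_stop": dict(self.decision.p_best_at_stop),
                "p_equivalent_at_stop": self.decision.p_equivalent_at_stop,
            },
            "per_arm": {
                arm_id: {
                    "n_allocated": s.n_allocated,
                    "n_outcomes_observed": s.n_outcomes_observed,
                    "n_attended": s.n_attended,
                    "posterior_alpha": s.posterior.alpha,
                    "posterior_beta": s.posterior.beta,
                    "posterior_mean": s.posterior.mean,
                }
                for arm_id, s in self.per_arm.items()
            },
            "n_interims": self.n_interims,
            "total_enrolled": self.total_enrolled,
            "true_rates": dict(self.true_rates) if self.true_rates else None,
            "winner_estimate": self.winner_estimate,
            "winner_bias": self.winner_bias,
            "guard_triggered": self.guard_triggered,
        }


def _comparison_seed(master_seed: int, interim_index: int) -> int:
    state = np.random.SeedSequence(
        entropy=(int(master_seed), _STREAM_COMPARISON, int(interim_index))
    ).generate_state(1)[0]
    return int(state) % (2**31)


def _arm_states(
    config: TrialConfig, n_out: np.ndarray, n_att: np.ndarray
) -> dict[str, ArmState]:
    states = {}
    for i, arm in enumerate(config.arms):
        states[arm.arm_id] = ArmState(
            arm_id=arm.arm_id,
            is_control=arm.is_control,
            n_allocated=int(n_out[i]),
            n_outcomes_observed=int(n_out[i]),
            n_attended=int(n_att[i]),
            posterior=BetaParams(
                config.prior.alpha + int(n_att[i]),
                config.prior.beta + int(n_out[i]) - int(n_att[i]),
            ),
        )
    return states


def run_trial(
    config: TrialConfig,
    population: PopulationSpec,
    record_participants: bool = True,
    guard_outcomes: int = GUARD_OUTCOMES,
) -> TrialResult:
    """Simulate one adaptive trial to its stopping decision.

    Enrols one batch of ``interim_every_outcomes`` referrals per window (the
    final batch truncated if a ceiling intervenes), observes their outcomes
    immediately, updates each arm's conjugate posterior, and evaluates the
    stopping rules.  Fully reproducible given ``config.master_seed`` and
    ``population.seed``.
    """
    arm_ids = config.arm_ids
    missing = [a for a in arm_ids if a not in population.arm_effects]
    if missing:
        raise ConfigurationError(f"population defines no effect for arms {missing}")

    n_arms = len(arm_ids)
    labels = population.labels
    # attendance probability lookup: [arm, subgroup]
    p_table = np.array(
        [
            [population.attendance_probability(sg, arm) for sg in labels]
            for arm in arm_ids
        ]
    )
    prevalence = np.array([s.prevalence for s in population.subgroups])
    cum_prev = np.cumsum(prevalence)
    method = config.comparison_method
    if method == "auto":
        method = "exact" if n_arms == 2 else "mc"
    control_arms = frozenset(a.arm_id for a in config.arms if a.is_control)

    allocator = BlockRandomizer(config.allocation)
    ceiling = config.thresholds.ceiling_n
    batch_nominal = config.interim_every_outcomes

    n_out = np.zeros(n_arms, dtype=np.int64)
    n_att = np.zeros(n_arms, dtype=np.int64)
    total = 0
    interim = 0
    guard = False
    log_rows: list[dict] = []
    rec_subgroup: list[np.ndarray] = []
    rec_arm: list[np.ndarray] = []
    rec_attended: list[np.ndarray] = []
    rec_window: list[np.ndarray] = []

    while True:
        batch = batch_nominal
        if ceiling is not None:
            batch = min(batch, ceiling - total)
        # enrol, allocate, observe
        u_sub = uniforms_at(population.seed, _STREAM_SUBGROUP, total, batch)
        sub_idx = np.searchsorted(cum_prev, u_sub, side="right")
        arm_assign = allocator.take_indices(batch)
        u_out = uniforms_at(population.seed, _STREAM_OUTCOME, total, batch)
        attended = u_out < p_table[arm_assign, sub_idx]
        np.add.at(n_out, arm_assign, 1)
        np.add.at(n_att, arm_assign, attended)
        if record_participants:
            rec_subgroup.append(sub_idx)
            rec_arm.append(arm_assign)
            rec_attended.append(attended)
            rec_window.append(np.full(batch, interim, dtype=np.int64))
        total += batch
        interim += 1

        states = _arm_states(config, n_out, n_att)
        comparison = compare_arms(
            list(states.values()),
            margin=config.thresholds.margin,
            n_draws=config.comparison_draws,
            seed=(
                0 if method == "exact"
                else _comparison_seed(config.master_seed, interim)
            ),
            method=method,
        )
        decision = evaluate_stopping(
            comparison, config.thresholds, total, control_arms=control_arms
        )
        log_rows.append(
            {
                "interim": interim,
                "total_enrolled": total,
                **{f"n_{a}": int(n_out[i]) for i, a in enumerate(arm_ids)},
                **{f"attended_{a}": int(n_att[i]) for i, a in enumerate(arm_ids)},
                **{f"p_best_{a}": comparison.p_best[a] for a in arm_ids},
                "p_equivalent": comparison.p_equivalent,
                "stopped": decision.stopped,
                "reason": decision.reason,
                "winner": decision.winner,
            }
        )
        if decision.stopped:
            break
        if ceiling is None and total >= guard_outcomes:
            guard = True
            decision = StopDecision(
                stopped=True,
                reason=REASON_GUARD,
                winner=None,
                p_best_at_stop=dict(comparison.p_best),
                p_equivalent_at_stop=comparison.p_equivalent,
            )
            break

    winner = decision.winner
    winner_estimate = states[winner].posterior.mean if winner is not None else None
    participants = None
    if record_participants:
        sub_all = np.concatenate(rec_subgroup)
        arm_all = np.concatenate(rec_arm)
        att_all = np.concatenate(rec_attended)
        win_all = np.concatenate(rec_window)
        participants = pd.DataFrame(
            {
                "participant_id": [f"P{i:07d}" for i in range(total)],
                "subgroup": np.array(labels, dtype=object)[sub_all],
                "window": win_all,
                "arm": np.array(arm_ids, dtype=object)[arm_all],
                "attended": att_all,
            },
            columns=PARTICIPANT_COLUMNS,
        )
    return TrialResult(
        decision=decision,
        per_arm=states,
        n_interims=interim,
        total_enrolled=total,
        true_rates=population.true_rates(),
        winner_estimate=winner_estimate,
        guard_triggered=guard,
        interim_log=pd.DataFrame(log_rows),
        participants=participants,
    )


def replay_recorded(records: pd.DataFrame, config: TrialConfig) -> TrialResult:
    """Run the interim-analysis loop over a recorded participant table.

    No allocation or outcome generation happens: rows are consumed in order,
    an interim analysis fires after every ``interim_every_outcomes`` recorded
    outcomes (and once more on a final partial batch), and the stopping rules
    are applied exactly as in simulation.  If the records run out before any
    rule fires the returned decision has ``stopped = False``.
    """
    defects = []
    for col in ("arm", "attended"):
        if col not in records.columns:
            defects.append(f"missing required column {col!r}")
    if defects:
        raise SchemaError(defects)
    known = set(config.arm_ids)
    seen = set(records["arm"].unique())
    unknown = sorted(seen - known)
    if unknown:
        defects.append(f"unknown arm ids in records: {unknown}")
    if "window" in records.columns:
        w = np.asarray(records["window"])
        if len(w) > 1 and np.any(np.diff(w) < 0):
            defects.append("window indices must be monotone non-decreasing")
    if defects:
        raise SchemaError(defects)

    arm_ids = config.arm_ids
    arm_index = {a: i for i, a in enumerate(arm_ids)}
    control_arms = frozenset(a.arm_id for a in config.arms if a.is_control)
    arm_assign = np.fromiter(
        (arm_index[a] for a in records["arm"]), dtype=np.int64, count=len(records)
    )
    attended = np.asarray(records["attended"]).astype(bool)

    n_out = np.zeros(len(arm_ids), dtype=np.int64)
    n_att = np.zeros(len(arm_ids), dtype=np.int64)
    total = 0
    interim = 0
    log_rows: list[dict] = []
    batch_size = config.interim_every_outcomes
    ceiling = config.thresholds.ceiling_n
    decision = StopDecision(stopped=False)
    states = _arm_states(config, n_out, n_att)

    pos = 0
    n_records = len(records)
    while pos < n_records:
        end = min(pos + batch_size, n_records)
        if ceiling is not None:
            end = min(end, pos + (ceiling - total))
        sel = slice(pos, end)
        np.add.at(n_out, arm_assign[sel], 1)
        np.add.at(n_att, arm_assign[sel], attended[sel])
        total += end - pos
        pos = end
        interim += 1
        states = _arm_states(config, n_out, n_att)
        comparison = compare_arms(
            list(states.values()),
            margin=config.thresholds.margin,
            n_draws=config.comparison_draws,
            seed=_comparison_seed(config.master_seed, interim),
            method=config.comparison_method,
        )
        decision = evaluate_stopping(
            comparison, config.thresholds, total, control_arms=control_arms
        )
        log_rows.append(
            {
                "interim": interim,
                "total_enrolled": total,
                **{f"n_{a}": int(n_out[i]) for i, a in enumerate(arm_ids)},
                **{f"attended_{a}": int(n_att[i]) for i, a in enumerate(arm_ids)},
                **{f"p_best_{a}": comparison.p_best[a] for a in arm_ids},
                "p_equivalent": comparison.p_equivalent,
                "stopped": decision.stopped,
                "reason": decision.reason,
                "winner": decision.winner,
            }
        )
        if decision.stopped:
            break

    winner = decision.winner
    winner_estimate = states[winner].posterior.mean if winner is not None else None
    return TrialResult(
        decision=decision,
        per_arm=states,
        n_interims=interim,
        total_enrolled=total,
        true_rates=None,
        winner_estimate=winner_estimate,
        interim_log=pd.DataFrame(log_rows),
        participants=None,
    )
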