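"""Stopping rules for individual trials and the platform-closure rule.

An individual trial ends at the first interim analysis where one of three
rules fires, checked in fixed priority order:

1. *Superiority* — the posterior probability that some arm is best exceeds
   the threshold ``x_best`` (default 95%); that arm is declared the winner.
2. *Practical equivalence* — the posterior probability that every remaining
   arm lies within the equivalence margin (default 1 percentage point) of the
   best exceeds ``y_equiv`` (default 95%); no winner.
3. *Ceiling* — total enrolment has reached a maximum (default 10 000); the
   trial ends indeterminate, no winner.

The whole platform closes once attendance reaches or exceeds 80% in every
sociodemographic group at a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .bayes import PosteriorComparison
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "StoppingThresholds",
    "StopDecision",
    "evaluate_stopping",
    "evaluate_platform_closure",
    "PLATFORM_CLOSURE_ATTENDANCE",
]

PLATFORM_CLOSURE_ATTENDANCE = 0.80

RULE_SUPERIORITY = "rule1_superiority"
RULE_EQUIVALENCE = "rule2_equivalence"
RULE_CEILING = "rule3_ceiling"
RULE_NONE = "none"


@dataclass(frozen=True)
class StoppingThresholds:
    """Design thresholds x (superiority), y (equivalence), margin, and ceiling.

    ``superiority_scope`` controls which arms can end the trial by rule 1:
    ``"any"`` (the symmetric reading — any arm, control included, may be
    declared best) or ``"non_control"`` (only an intervention-superiority
    finding stops the trial; evidence favouring standard care leaves it
    running until equivalence or the ceiling).  The one-sided form is the
    design whose operating characteristics the simulation study reports.
    """

    x_best: float = 0.95
    y_equiv: float = 0.95
    margin: float = 0.01
    ceiling_n: int | None = 10_000
    superiority_scope: str = "any"

    def __post_init__(self) -> None:
        defects = []
        if not (0.5 <= self.x_best < 1):
            defects.append(f"x_best must lie in [0.5, 1), got {self.x_best}")
        if not (0.5 <= self.y_equiv < 1):
            defects.append(f"y_equiv must lie in [0.5, 1), got {self.y_equiv}")
        if not self.margin > 0:
            defects.append(f"margin must be > 0, got {self.margin}")
        if self.ceiling_n is not None and self.ceiling_n < 1:
            defects.append(f"ceiling_n must be positive or None, got {self.ceiling_n}")
        if self.superiority_scope not in ("any", "non_control"):
            defects.append(
                f"superiority_scope must be 'any' or 'non_control', "
                f"got {self.superiority_scope!r}"
            )
        if defects:
            raise ConfigurationError(defects)


@dataclass
class StopDecision:
    """Outcome of evaluating the stopping rules at one interim analysis."""

    stopped: bool
    reason: str = RULE_NONE
    winner: str | None = None
    p_best_at_stop: Mapping[str, float] = field(default_factory=dict)
    p_equivalent_at_stop: float | None = None


def evaluate_stopping(
    comparison: PosteriorComparison,
    thresholds: StoppingThresholds,
    total_enrolled: int,
    control_arms: frozenset[str] | set[str] = frozenset(),
) -> StopDecision:
    """Apply the three stopping rules in priority order (1 then 2 then 3).

    Rule 1 and 2 comparisons are strict (">x%", probability of difference
    "<margin" exceeding y); rule 3 fires when ``total_enrolled`` has reached
    the ceiling.  The first rule satisfied determines the decision; a
    superiority finding therefore takes precedence over equivalence, which
    takes precedence over an indeterminate ceiling stop.

    Under ``superiority_scope = "non_control"`` the arms in ``control_arms``
    cannot be declared winners: rule 1 fires only when a non-control arm's
    probability of being best exceeds ``x_best``.
    """
    if total_enrolled < 0:
        raise InvalidInputError(f"total_enrolled must be >= 0, got {total_enrolled}")
    p_best = dict(comparison.p_best)
    if thresholds.superiority_scope == "non_control":
        candidates = {a: p for a, p in p_best.items() if a not in control_arms}
        if not candidates:
            raise InvalidInputError(
                "superiority_scope='non_control' but every arm is a control arm"
            )
    else:
        candidates = p_best
    best_arm = max(candidates, key=lambda a: candidates[a])
    if p_best[best_arm] > thresholds.x_best:
        return StopDecision(
            stopped=True,
            reason=RULE_SUPERIORITY,
            winner=best_arm,
            p_best_at_stop=p_best,
            p_equivalent_at_stop=comparison.p_equivalent,
        )
    p_eq = comparison.p_equivalent
    if p_eq is not None and p_eq > thresholds.y_equiv:
        return StopDecision(
            stopped=True,
            reason=RULE_EQUIVALENCE,
            winner=None,
            p_best_at_stop=p_best,
            p_equivalent_at_stop=p_eq,
        )
    if thresholds.ceiling_n is not None and total_enrolled >= thresholds.ceiling_n:
        return StopDecision(
            stopped=True,
            reason=RULE_CEILING,
            winner=None,
            p_best_at_stop=p_best,
            p_equivalent_at_stop=p_eq,
        )
    return StopDecision(
        stopped=False,
        reason=RULE_NONE,
        winner=None,
        p_best_at_stop=p_best,
        p_equivalent_at_stop=p_eq,
    )


def evaluate_platform_closure(group_attendance: Mapping[str, float]) -> bool:
    """True iff every group's attendance has reached or exceeded 80%.

    The boundary is inclusive: a group at exactly 0.80 counts as reached.
    """
    if not group_attendance:
        raise InvalidInputError("group_attendance must not be empty")
    for group, p in group_attendance.items():
        if not (0.0 <= p <= 1.0):
            raise InvalidInputError(
                f"attendance for group {group!r} must lie in [0,1], got {p}"
            )
    return all(p >= PLATFORM_CLOSURE_ATTENDANCE for p in group_attendance.values())
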