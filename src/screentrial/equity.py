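"""Disaggregated attendance analysis and the left-behind group.

The platform's primary outcome is attendance in the *left-behind* group: the
sociodemographic group(s) with the lowest attendance that together make up at
least 10% of the referred population.  This module computes per-group
attendance tables, identifies the left-behind set, and reports the primary
(left-behind) and secondary (overall) attendance outcomes with their absolute
percentage-point difference — the quantity used to check that an intervention
helping the left-behind group has not depressed attendance overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ScreentrialError, SequencingError

__all__ = [
    "GroupAttendance",
    "EquityReport",
    "attendance_by_group",
    "identify_left_behind",
    "equity_report",
]

DEFAULT_MIN_FRACTION = 0.10


@dataclass(frozen=True)
class GroupAttendance:
    group: str
    population_fraction: float
    n_referred: int
    n_attended: int

    @property
    def attendance(self) -> float:
        if self.n_referred == 0:
            return float("nan")
        return self.n_attended / self.n_referred


@dataclass(frozen=True)
class EquityReport:
    left_behind_groups: frozenset[str]
    primary_attendance: float
    overall_attendance: float
    absolute_difference: float  # (overall - primary), in percentage points

    def to_dict(self) -> dict:
        return {
            "left_behind_groups": sorted(self.left_behind_groups),
            "primary_attendance": self.primary_attendance,
            "overall_attendance": self.overall_attendance,
            "absolute_difference": self.absolute_difference,
        }


def _require_resolved(participants: pd.DataFrame) -> None:
    if "attended" not in participants.columns:
        raise SequencingError("participant table has no 'attended' column")
    if len(participants) and pd.isna(participants["attended"]).any():
        raise SequencingError(
            "participants with pending outcomes: resolve outcomes before analysis"
        )


def attendance_by_group(
    participants: pd.DataFrame,
    domain: str = "subgroup",
    population_fractions: Mapping[str, float] | None = None,
) -> list[GroupAttendance]:
    """Per-group referral and attendance counts within one disaggregation domain.

    ``domain`` names the column holding the group label (e.g. sex, age band).
    Population fractions default to the observed referral shares; pass
    ``population_fractions`` to use external (e.g. census or baseline-survey)
    shares instead.  Groups with zero referrals are omitted.
    """
    _require_resolved(participants)
    if domain not in participants.columns:
        raise InvalidInputError(f"domain column {domain!r} not in participant table")
    if len(participants) == 0:
        return []
    grouped = participants.groupby(domain, sort=True)["attended"]
    n_ref = grouped.size()
    n_att = grouped.sum()
    total = int(n_ref.sum())
    rows = []
    for label in n_ref.index:
        if population_fractions is not None:
            if label not in population_fractions:
                raise InvalidInputError(
                    f"population_fractions missing group {label!r}"
                )
            frac = float(population_fractions[label])
        else:
            frac = int(n_ref[label]) / total
        rows.append(
            GroupAttendance(
                group=str(label),
                population_fraction=frac,
                n_referred=int(n_ref[label]),
                n_attended=int(n_att[label]),
            )
        )
    return rows


def identify_left_behind(
    table: Sequence[GroupAttendance],
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> set[str]:
    """Groups with the lowest attendance summing to at least ``min_fraction``.

    Groups are taken in ascending order of attendance until their population
    fractions accumulate to the floor (default 10%).  Attendance ties are
    broken in favour of the larger group (reaching the floor with fewer
    groups), then by label order.
    """
    if not table:
        raise InvalidInputError("group attendance table must be non-empty")
    for row in table:
        if row.population_fraction is None or np.isnan(row.population_fraction):
            raise InvalidInputError(
                f"group {row.group!r} has no population fraction"
            )
    if not (0.0 < min_fraction <= 1.0):
        raise InvalidInputError(f"min_fraction must lie in (0,1], got {min_fraction}")
    ordered = sorted(
        table, key=lambda g: (g.attendance, -g.population_fraction, g.group)
    )
    selected: set[str] = set()
    cum = 0.0
    for row in ordered:
        selected.add(row.group)
        cum += row.population_fraction
        if cum >= min_fraction:
            break
    else:
        raise InvalidInputError(
            f"population fractions sum to {cum:.4f} < min_fraction {min_fraction}"
        )
    return selected


def equity_report(
    participants: pd.DataFrame,
    left_behind: Iterable[str],
    domain: str = "subgroup",
) -> EquityReport:
    """Primary (left-behind) and overall attendance, and their gap.

    The gap is reported as (overall - primary) in absolute percentage points;
    a positive value means the left-behind group still attends less than the
    population at large.
    """
    _require_resolved(participants)
    left_behind = frozenset(left_behind)
    if not left_behind:
        raise InvalidInputError("left_behind set must be non-empty")
    mask = participants[domain].isin(left_behind)
    n_left = int(mask.sum())
    if n_left == 0:
        raise ScreentrialError(
            "no referred participants in the left-behind set: primary outcome undefined"
        )
    attended = participants["attended"].astype(bool)
    primary = float(attended[mask].mean())
    overall = float(attended.mean())
    return EquityReport(
        left_behind_groups=left_behind,
        primary_attendance=primary,
        overall_attendance=overall,
        absolute_difference=(overall - primary) * 100.0,
    )
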