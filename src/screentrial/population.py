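"""Synthetic screening-programme generator.

Models the referral stream of an embedded screening programme: a fixed number
of people (default 100) are referred for further care in every interim window
(default 72 hours), each belonging to a sociodemographic subgroup drawn from
stated prevalences.  Once a participant is allocated to a trial arm, their
attendance at the clinic is a Bernoulli outcome whose probability is the
subgroup's baseline attendance plus the arm's additive effect (in absolute
probability units), clipped to [0, 1].

Randomness is split into named counter-based streams keyed off the spec seed
(Philox), so subgroup draws and outcome draws are independent, and the
outcome uniform attached to the i-th referred participant depends only on
(seed, i).  Replaying the same stream under a different design therefore
reuses identical latent draws — common random numbers across designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, SequencingError

__all__ = [
    "Subgroup",
    "PopulationSpec",
    "Participant",
    "generate_referral_stream",
    "generate_outcome",
    "generate_outcomes",
    "PARTICIPANT_COLUMNS",
]

PARTICIPANT_COLUMNS = ["participant_id", "subgroup", "window", "arm", "attended"]

# Philox stream tags: subgroup labels vs attendance outcomes
_STREAM_SUBGROUP = 1
_STREAM_OUTCOME = 2


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Counter-based generator for an independent named stream of ``seed``."""
    return np.random.Generator(np.random.Philox(key=[int(seed), int(stream)]))


@dataclass(frozen=True)
class Subgroup:
    label: str
    prevalence: float
    baseline_attendance: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ConfigurationError(
                f"subgroup {self.label!r}: prevalence must lie in [0,1], "
                f"got {self.prevalence}"
            )
        if not (0.0 <= self.baseline_attendance <= 1.0):
            raise ConfigurationError(
                f"subgroup {self.label!r}: baseline_attendance must lie in [0,1], "
                f"got {self.baseline_attendance}"
            )


@dataclass(frozen=True)
class PopulationSpec:
    """Generative model of the referred population.

    ``arm_effects`` maps each arm to either a single additive effect (absolute
    probability points applied in every subgroup) or a mapping from subgroup
    label to effect, allowing e.g. proportionate-universalism scenarios where
    the left-behind group benefits most.
    """

    subgroups: tuple[Subgroup, ...]
    arm_effects: Mapping[str, float | Mapping[str, float]]
    referrals_per_window: int = 100
    window_hours: float = 72.0
    seed: int = 0

    def __post_init__(self) -> None:
        subgroups = tuple(
            s if isinstance(s, Subgroup) else Subgroup(*s) for s in self.subgroups
        )
        object.__setattr__(self, "subgroups", subgroups)
        if not subgroups:
            raise ConfigurationError("at least one subgroup is required")
        total = sum(s.prevalence for s in subgroups)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"subgroup prevalences must sum to 1, got {total!r}"
            )
        if self.referrals_per_window < 1:
            raise ConfigurationError(
                f"referrals_per_window must be positive, got {self.referrals_per_window}"
            )
        if not self.window_hours > 0:
            raise ConfigurationError(
                f"window_hours must be positive, got {self.window_hours}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.subgroups)

    def attendance_probability(self, subgroup: str, arm: str) -> float:
        """Baseline attendance plus the arm effect, clipped to [0, 1]."""
        base = {s.label: s.baseline_attendance for s in self.subgroups}
        if subgroup not in base:
            raise InvalidInputError(f"unknown subgroup {subgroup!r}")
        if arm not in self.arm_effects:
            raise InvalidInputError(f"unknown arm {arm!r} in arm_effects")
        effect = self.arm_effects[arm]
        if isinstance(effect, Mapping):
            effect = effect.get(subgroup, 0.0)
        return float(np.clip(base[subgroup] + effect, 0.0, 1.0))

    def true_rates(self) -> dict[str, float]:
        """Prevalence-weighted attendance probability per arm."""
        return {
            arm: sum(
                s.prevalence * self.attendance_probability(s.label, arm)
                for s in self.subgroups
            )
            for arm in self.arm_effects
        }


@dataclass
class Participant:
    """One referred person; ``arm`` and ``attended`` start unresolved."""

    participant_id: str
    subgroup: str
    referral_window_index: int
    arm: str | None = None
    attended: bool | None = None


def generate_referral_stream(spec: PopulationSpec, n_windows: int) -> pd.DataFrame:
    """Referral stream for ``n_windows`` interim windows.

    Returns a DataFrame with one row per referred participant and columns
    ``participant_id, subgroup, window, arm, attended``; ``arm`` is empty and
    ``attended`` is missing (pending) until allocation and outcome generation
    have run.  Reproducible given ``spec.seed``.
    """
    if n_windows < 1:
        raise InvalidInputError(f"n_windows must be >= 1, got {n_windows}")
    n = spec.referrals_per_window * n_windows
    u = uniforms_at(spec.seed, _STREAM_SUBGROUP, 0, n)
    cum_prev = np.cumsum([s.prevalence for s in spec.subgroups])
    idx = np.searchsorted(cum_prev, u, side="right")
    labels = np.array(spec.labels, dtype=object)[idx]
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:07d}" for i in range(n)],
            "subgroup": labels,
            "window": np.repeat(np.arange(n_windows), spec.referrals_per_window),
            "arm": pd.array([pd.NA] * n, dtype="string"),
            "attended": pd.array([pd.NA] * n, dtype="boolean"),
        }
    )


def _participant_uniforms(spec: PopulationSpec, start: int, count: int) -> np.ndarray:
    """Latent outcome uniforms for participants [start, start+count).

    Depends only on (seed, participant index): the outcome stream is advanced
    to ``start`` before drawing, so the same participant always receives the
    same uniform regardless of batch boundaries or arm assignment.
    """
    return uniforms_at(spec.seed, _STREAM_OUTCOME, start, count)


def uniforms_at(seed: int, stream: int, start: int, count: int) -> np.ndarray:
    """Uniforms at raw-word positions [start, start+count) of a Philox stream.

    Position-indexed (one 64-bit word per double, Philox counter advanced in
    4-word steps), so the value at a position is independent of how preceding
    positions were consumed.
    """
    bg = np.random.Philox(key=[int(seed), int(stream)])
    skip = start % 4
    if start >= 4:
        bg.advance(start // 4)
    raw = bg.random_raw(skip + count)[skip:]
    return (raw >> np.uint64(11)) * (2.0 ** -53)


def generate_outcomes(
    participants: pd.DataFrame,
    spec: PopulationSpec,
    start_index: int | None = None,
) -> np.ndarray:
    """Vectorised Bernoulli attendance outcomes for allocated participants.

    ``start_index`` is the global participant index of the first row (default:
    parsed from ``participant_id``); it anchors the common-random-numbers
    scheme.  Raises SequencingError if any row is unallocated.
    """
    if participants["arm"].isna().any():
        raise SequencingError("outcome generation requires every row to have an arm")
    if start_index is None:
        first = str(participants["participant_id"].iloc[0])
        start_index = int(first.lstrip("P"))
    u = _participant_uniforms(spec, start_index, len(participants))
    probs = np.array(
        [
            spec.attendance_probability(sg, arm)
            for sg, arm in zip(participants["subgroup"], participants["arm"])
        ]
    )
    return u < probs


def generate_outcome(participant: Participant, spec: PopulationSpec) -> bool:
    """Attendance outcome for a single participant (scalar convenience form)."""
    if participant.arm is None:
        raise SequencingError(
            f"participant {participant.participant_id!r} has no arm: "
            "allocation must precede outcome generation"
        )
    index = int(str(participant.participant_id).lstrip("P"))
    u = _participant_uniforms(spec, index, 1)[0]
    p = spec.attendance_probability(participant.subgroup, participant.arm)
    return bool(u < p)
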