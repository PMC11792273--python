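"""Permuted-block randomisation with optional stratification.

Assignments are computer-generated in blocks: each block's length is drawn
uniformly at random from a permitted set (by default the multiples of the
allocation-ratio total lying between 4 and 12), the block is filled with arms
in the ratio proportions, and its order is uniformly permuted.  Within every
completed block the realised allocation ratio is therefore exact, and the
imbalance at any point in the sequence is bounded by one incomplete block.

When strata are declared, each stratum runs its own independent block
sequence, seeded deterministically from the master seed and the stratum
label, so each stratum's marginal sequence is reproducible under any
interleaving of arrivals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = ["AllocationSpec", "BlockRandomizer", "StratifiedAllocator", "generate_sequence"]

_DEFAULT_BLOCK_RANGE = (4, 12)


def _default_block_sizes(ratio_total: int) -> list[int]:
    lo, hi = _DEFAULT_BLOCK_RANGE
    sizes = [k for k in range(lo, hi + 1) if k % ratio_total == 0]
    return sizes


@dataclass(frozen=True)
class AllocationSpec:
    """Arms, allocation ratio, permitted block sizes, strata, and seed."""

    arm_ids: tuple[str, ...]
    ratio: tuple[int, ...] = ()
    block_sizes: tuple[int, ...] = ()
    strata: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm_ids", tuple(self.arm_ids))
        if len(self.arm_ids) < 2:
            raise ConfigurationError(
                f"allocation needs at least 2 arms, got {len(self.arm_ids)}"
            )
        if len(set(self.arm_ids)) != len(self.arm_ids):
            raise ConfigurationError("arm_ids must be unique")
        ratio = tuple(self.ratio) if self.ratio else (1,) * len(self.arm_ids)
        if len(ratio) != len(self.arm_ids):
            raise ConfigurationError(
                f"ratio has {len(ratio)} entries for {len(self.arm_ids)} arms"
            )
        if any(r < 1 for r in ratio):
            raise ConfigurationError(f"ratio weights must be positive, got {ratio}")
        object.__setattr__(self, "ratio", ratio)
        total = sum(ratio)
        sizes = tuple(self.block_sizes) if self.block_sizes else tuple(
            _default_block_sizes(total)
        )
        if not sizes:
            raise ConfigurationError(
                f"no permitted block size in {_DEFAULT_BLOCK_RANGE} is a multiple "
                f"of the ratio total {total}"
            )
        bad = [s for s in sizes if s < 1 or s % total != 0]
        if bad:
            raise ConfigurationError(
                f"block sizes {bad} are not positive multiples of the ratio total {total}"
            )
        object.__setattr__(self, "block_sizes", sizes)
        if self.strata is not None:
            object.__setattr__(self, "strata", tuple(self.strata))

    @property
    def ratio_total(self) -> int:
        return sum(self.ratio)


class BlockRandomizer:
    """Stateful generator of one permuted-block allocation sequence.

    ``take(k)`` returns the next ``k`` assignments, generating new blocks as
    needed; the full sequence is a deterministic function of (spec, seed).
    """

    def __init__(self, spec: AllocationSpec, seed: int | None = None):
        self.spec = spec
        self.seed = spec.seed if seed is None else seed
        self._rng = np.random.default_rng(self.seed)
        self._sizes = np.asarray(spec.block_sizes)
        # per-size template of arm indices in ratio proportions
        self._templates = {
            int(s): np.repeat(
                np.arange(len(spec.arm_ids)),
                np.asarray(spec.ratio) * (int(s) // spec.ratio_total),
            )
            for s in spec.block_sizes
        }
        self._buffer = np.empty(0, dtype=np.int64)

    def _extend(self, at_least: int) -> None:
        # generate whole blocks until the buffer holds >= at_least assignments;
        # one permutation draw per block keeps the sequence identical whatever
        # the batching of take() calls
        rng = self._rng
        chunks = [self._buffer]
        have = len(self._buffer)
        while have < at_least:
            size = int(self._sizes[rng.integers(len(self._sizes))])
            block = rng.permutation(self._templates[size])
            chunks.append(block)
            have += size
        self._buffer = np.concatenate(chunks)

    def take_indices(self, k: int) -> np.ndarray:
        """Next ``k`` assignments as arm indices into ``spec.arm_ids``."""
        if k < 1:
            raise InvalidInputError(f"k must be >= 1, got {k}")
        if len(self._buffer) < k:
            self._extend(k)
        out, self._buffer = self._buffer[:k], self._buffer[k:]
        return out

    def take(self, k: int) -> list[str]:
        """Next ``k`` assignments as arm labels."""
        return [self.spec.arm_ids[i] for i in self.take_indices(k)]


def generate_sequence(spec: AllocationSpec, n: int) -> list[str]:
    """The first ``n`` assignments of the (unstratified) block sequence."""
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    return BlockRandomizer(spec).take(n)


def _stratum_seed(master_seed: int, stratum: str) -> int:
    # deterministic, label-stable derivation; crc32 keeps it below 2**32
    return (int(master_seed) * 2_654_435_761 + zlib.crc32(stratum.encode())) % (2**31)


class StratifiedAllocator:
    """Independent permuted-block sequences, one per declared stratum."""

    def __init__(self, spec: AllocationSpec):
        self.spec = spec
        self._single = spec.strata is None
        if self._single:
            # no stratification: one sequence, identical to generate_sequence
            self._randomizers = {"__all__": BlockRandomizer(spec)}
        else:
            self._randomizers = {
                s: BlockRandomizer(spec, seed=_stratum_seed(spec.seed, s))
                for s in spec.strata
            }

    def allocate(self, participant_stratum: str | None = None) -> str:
        """Next assignment from the participant's stratum sequence."""
        if self._single:
            key = "__all__"
        else:
            key = participant_stratum
            if key not in self._randomizers:
                raise InvalidInputError(
                    f"undeclared stratum {participant_stratum!r}; "
                    f"declared: {sorted(self._randomizers)}"
                )
        return self._randomizers[key].take(1)[0]


def allocate_stratified(
    allocator: StratifiedAllocator, participant_stratum: str
) -> str:
    """Functional wrapper over :meth:`StratifiedAllocator.allocate`."""
    return allocator.allocate(participant_stratum)
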