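"""Experiment design: duration ladders, trial schedules, training criterion.

The time-generalization task probes perceived duration with a small set of
test durations spaced geometrically around a reference (the "standard").
A ladder with ``log10_step = 0.1`` puts successive durations a constant
factor ``10**0.1 ≈ 1.259`` apart, i.e. roughly 25% increments, with the
reference sitting exactly at the middle rung.

A test block presents each non-reference duration a fixed number of times
and the reference itself more often (the canonical design: 6 repetitions of
each of the 6 non-reference durations plus 18 reference presentations,
54 trials per block).  Schedules are seeded permutations of that fixed
multiset, never resamples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDesignError, InvalidInputError

__all__ = [
    "DurationLadder",
    "TrialSchedule",
    "build_ladder",
    "build_test_block",
    "build_training_block",
    "training_criterion_met",
]

#: Canonical per-block repetition counts: 6 per non-reference duration,
#: 18 for the reference, giving 6*6 + 18 = 54 trials.
DEFAULT_REPS_NONREF = 6
DEFAULT_REPS_REF = 18

#: Proportion-correct criterion that ends the training phase.
TRAINING_THRESHOLD = 0.85


@dataclass(frozen=True)
class DurationLadder:
    """Geometric ladder of test durations centred on a reference.

    ``durations_s[k] = reference_s * 10**(log10_step * (k - (n_levels-1)/2))``
    so the middle element equals the reference and consecutive durations keep
    a constant ratio of ``10**log10_step``.
    """

    reference_s: float
    n_levels: int
    log10_step: float
    durations_s: tuple[float, ...]

    @property
    def reference_index(self) -> int:
        return (self.n_levels - 1) // 2

    def rounded(self, ndigits: int = 3) -> tuple[float, ...]:
        """Durations rounded for display / comparison with printed values."""
        return tuple(round(d, ndigits) for d in self.durations_s)

    def __contains__(self, duration_s: float) -> bool:
        return any(np.isclose(duration_s, d, rtol=1e-12) for d in self.durations_s)


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered sequence of (duration, is-reference) trials.

    A schedule is a seeded permutation of the generating design's trial
    multiset: per-duration counts are exact, only the order is random.
    """

    durations_s: tuple[float, ...]
    is_reference: tuple[bool, ...]
    block_label: str
    rng_seed: int

    def __len__(self) -> int:
        return len(self.durations_s)

    @property
    def trials(self) -> list[tuple[float, bool]]:
        return list(zip(self.durations_s, self.is_reference))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["trial_index", "duration_s", "is_reference", "block_label", "seed"])
            for i, (d, r) in enumerate(self.trials):
                w.writerow([i, repr(d), int(r), self.block_label, self.rng_seed])


def build_ladder(reference_s: float, n_levels: int, log10_step: float) -> DurationLadder:
    """Construct a geometric duration ladder around ``reference_s``.

    Parameters
    ----------
    reference_s : float
        Reference ("standard") duration in seconds; the middle rung.
    n_levels : int
        Odd number of distinct test durations, at least 3.
    log10_step : float
        Spacing between adjacent rungs on the log10-seconds axis.
        0.1 reproduces the canonical ~25% geometric increments.

    Examples
    --------
    >>> build_ladder(0.4, 7, 0.1).rounded()
    (0.2, 0.252, 0.318, 0.4, 0.504, 0.634, 0.798)
    """
    if not isinstance(n_levels, (int, np.integer)) or n_levels < 3 or n_levels % 2 == 0:
        raise InvalidDesignError(f"n_levels must be an odd integer >= 3, got {n_levels!r}")
    if reference_s <= 0:
        raise InvalidDesignError(f"reference_s must be positive, got {reference_s!r}")
    if log10_step < 0:
        raise InvalidDesignError(f"log10_step must be non-negative, got {log10_step!r}")
    half = (n_levels - 1) // 2
    durations = tuple(
        float(reference_s * 10.0 ** (log10_step * (k - half))) for k in range(n_levels)
    )
    return DurationLadder(
        reference_s=float(reference_s),
        n_levels=int(n_levels),
        log10_step=float(log10_step),
        durations_s=durations,
    )


def _permuted_schedule(durations, flags, block_label, seed):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(durations))
    return TrialSchedule(
        durations_s=tuple(durations[i] for i in order),
        is_reference=tuple(flags[i] for i in order),
        block_label=block_label,
        rng_seed=int(seed),
    )


def build_test_block(
    ladder: DurationLadder,
    reps_nonref: int = DEFAULT_REPS_NONREF,
    reps_ref: int = DEFAULT_REPS_REF,
    seed: int = 0,
    block_label: str = "test",
) -> TrialSchedule:
    """Build one seeded test block.

    Each non-reference rung contributes ``reps_nonref`` trials and the
    reference rung ``reps_ref`` trials (the reference's extra presentations
    replace, not augment, its ordinary repetition slot), for a total of
    ``reps_nonref * (n_levels - 1) + reps_ref`` trials in seeded random order.
    """
    if reps_nonref < 1 or reps_ref < 1:
        raise InvalidDesignError("repetition counts must be positive")
    durations: list[float] = []
    flags: list[bool] = []
    ref_idx = ladder.reference_index
    for i, d in enumerate(ladder.durations_s):
        reps = reps_ref if i == ref_idx else reps_nonref
        durations.extend([d] * reps)
        flags.extend([i == ref_idx] * reps)
    return _permuted_schedule(durations, flags, block_label, seed)


def build_training_block(
    ladder: DurationLadder, seed: int = 0, block_label: str = "training"
) -> TrialSchedule:
    """One training block: every ladder duration exactly once, random order."""
    durations = list(ladder.durations_s)
    flags = [i == ladder.reference_index for i in range(ladder.n_levels)]
    return _permuted_schedule(durations, flags, block_label, seed)


def training_criterion_met(block_responses, threshold: float = TRAINING_THRESHOLD) -> bool:
    """Whether a completed training block reaches the proportion-correct criterion.

    Evaluated per completed block: true iff the fraction of correct responses
    is at least ``threshold`` (6/7 ≈ 0.857 passes the canonical 0.85).
    """
    responses = list(block_responses)
    if len(responses) == 0:
        raise InvalidInputError("empty training block")
    if not 0 < threshold <= 1:
        raise InvalidInputError(f"threshold must lie in (0, 1], got {threshold!r}")
    return sum(bool(r) for r in responses) / len(responses) >= threshold
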