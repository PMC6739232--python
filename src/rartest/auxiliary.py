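"""Pre-trial fixed auxiliary designs.

The auxiliary design is a hypothetical fixed allocation sequence
``b_1..b_n`` for the experimental patients, chosen before the trial.  Its
first ``r`` entries equal the burn-in schedule; entries ``r+1..n-1`` are an
arbitrary fixed sequence; the final entry ``b_n`` must lie in the hypothesis
index set ``I`` being tested, so it is resolved per hypothesis.  The adaptive
test measures the realized trial against this design: the auxiliary arm
totals ``n'_i`` play the role of the natural weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trial_model import TrialDesign

__all__ = [
    "AuxiliaryDesign",
    "uniform_auxiliary",
    "explicit_auxiliary",
    "even_block_auxiliary",
]


@dataclass(frozen=True)
class AuxiliaryDesign:
    """Fixed allocation sequence with a per-hypothesis final slot.

    ``base`` holds ``b_1..b_{n-1}``; the final allocation is supplied by
    ``final_slot_rule`` (currently ``"min"``: the smallest arm index in I).
    """

    base: np.ndarray
    t: int
    final_slot_rule: str = "min"

    def __post_init__(self) -> None:
        base = np.asarray(self.base, dtype=np.int64)
        if base.ndim != 1:
            raise ValueError("auxiliary base sequence must be one-dimensional")
        if base.size and (base.min() < 1 or base.max() > self.t):
            raise ValueError("auxiliary allocations must lie in 1..t")
        if self.final_slot_rule != "min":
            raise ValueError("only the 'min' final-slot rule is supported")
        object.__setattr__(self, "base", base)

    @property
    def n(self) -> int:
        return self.base.size + 1

    def final_slot(self, I) -> int:
        """The final allocation ``b_n`` for hypothesis I (must lie in I)."""
        I = sorted(int(i) for i in I)
        if not I or I[0] < 1 or I[-1] > self.t:
            raise ValueError("hypothesis index set must be a non-empty subset of 1..t")
        return I[0]

    def full_sequence(self, I) -> np.ndarray:
        """``b_1..b_n`` with the final slot resolved for hypothesis I."""
        return np.append(self.base, self.final_slot(I))

    def in_I(self, I) -> np.ndarray:
        """Boolean indicator ``1{b_k in I}`` for k = 1..n."""
        return np.isin(self.full_sequence(I), sorted(I))

    def n_prime_arm(self, i: int, I=None) -> int:
        """Auxiliary total allocations ``n'_i`` to arm ``i``.

        The final slot counts toward the arm it resolves to, which depends
        on the hypothesis; by default arm ``i`` is tested as I = {i}.
        """
        I = {i} if I is None else I
        return int(np.sum(self.full_sequence(I) == i))

    def n_prime(self, I) -> int:
        """Auxiliary in-I total ``n'_I``."""
        return int(self.in_I(I).sum())

    def tail_counts(self, I) -> np.ndarray:
        """``m_{I,k}``: planned in-I allocations among slots k..n (k = 1..n)."""
        return np.cumsum(self.in_I(I)[::-1])[::-1]

    def block_counts(self, I, design: TrialDesign) -> np.ndarray:
        """Planned in-I allocations per experimental block ``q_1..q_J``."""
        ind = self.in_I(I)
        return np.array([ind[a:b].sum() for a, b in design.block_bounds()], dtype=np.int64)


def _check_burn_in(base: np.ndarray, design: TrialDesign) -> None:
    sched = design.burn_in_schedule
    if not np.array_equal(base[: design.r], sched):
        raise ValueError("auxiliary sequence must start with the burn-in schedule")


def uniform_auxiliary(design: TrialDesign, rng: np.random.Generator) -> AuxiliaryDesign:
    """Burn-in schedule followed by n - r - 1 iid uniform draws on {1..t}.

    This is the natural equipoise choice: before the trial there is no reason
    to expect any experimental arm to receive more patients than another.
    """
    m = design.n - design.r - 1
    draws = rng.integers(1, design.t + 1, size=m)
    base = np.concatenate([design.burn_in_schedule, draws])
    return AuxiliaryDesign(base=base, t=design.t)


def explicit_auxiliary(sequence, t: int, final_slot_rule: str = "min") -> AuxiliaryDesign:
    """Auxiliary design from a user-specified fixed sequence ``b_1..b_{n-1}``.

    ``sequence`` may be an iterable of arm indices or a string of arm digits
    (e.g. ``"1221221121"``).
    """
    if isinstance(sequence, str):
        sequence = [int(c) for c in sequence]
    return AuxiliaryDesign(base=np.asarray(sequence, dtype=np.int64), t=t,
                           final_slot_rule=final_slot_rule)


def even_block_auxiliary(design: TrialDesign) -> AuxiliaryDesign:
    """Deterministic block auxiliary: each block split as evenly as possible.

    Remainder slots go to the lower arm indices; the final block reserves its
    last slot for the per-hypothesis final allocation.
    """
    if not design.is_block:
        raise ValueError("design has no block structure")
    parts = [design.burn_in_schedule]
    for j, d in enumerate(design.block_sizes):
        size = d - 1 if j == design.n_blocks - 1 else d
        per, rem = divmod(size, design.t)
        counts = [per + (1 if i < rem else 0) for i in range(design.t)]
        parts.append(np.repeat(np.arange(1, design.t + 1), counts))
    return AuxiliaryDesign(base=np.concatenate(parts), t=design.t)
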