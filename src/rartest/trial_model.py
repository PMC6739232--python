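"""Trial configuration, realized trial data, and the synthetic outcome model.

A trial compares ``t`` experimental arms against a common control.  Outcomes
are normal with known unit variance: control outcomes are ``N(mu, 1)`` and
arm-``i`` outcomes are ``N(mu + delta_i, 1)``, where ``delta_i`` is the
incremental benefit of arm ``i``.  The experimental allocation is
response-adaptive after a fixed burn-in; the control allocation is fixed
(fully sequential designs) or blocked (block designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EffectConfig",
    "TrialDesign",
    "TrialData",
    "draw_outcome",
    "substream",
]

# Named substreams derived from one global seed, so that e.g. changing the
# randomization rule does not perturb the outcome draws.
_STREAMS = {"outcomes": 0, "control": 1, "rule": 2, "auxiliary": 3}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent named RNG substream for a global seed."""
    try:
        key = _STREAMS[name]
    except KeyError:  # pragma: no cover - programming error
        raise ValueError(f"unknown substream {name!r}; one of {sorted(_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class EffectConfig:
    """True treatment effects: control mean ``mu`` and increments ``deltas``.

    The outcome variance is fixed at 1 (known-variance model).
    """

    deltas: tuple[float, ...]
    mu: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "deltas", tuple(float(d) for d in self.deltas))
        if self.sigma2 != 1.0:
            raise ValueError("the outcome model fixes sigma2 = 1")
        if len(self.deltas) < 1:
            raise ValueError("need at least one experimental arm effect")

    @property
    def t(self) -> int:
        return len(self.deltas)

    def arm_mean(self, arm: int) -> float:
        """Mean outcome for ``arm`` (0 = control)."""
        if arm == 0:
            return self.mu
        if not 1 <= arm <= self.t:
            raise ValueError(f"arm {arm} out of range 1..{self.t}")
        return self.mu + self.deltas[arm - 1]


@dataclass(frozen=True)
class TrialDesign:
    """Static trial configuration.

    Parameters
    ----------
    t
        Number of experimental arms (> 1 in the intended use; 1 allowed for
        degenerate checks).
    n, n0
        Total experimental-arm and control patients.
    burn_in
        Per-arm burn-in counts ``(r_1, ..., r_t)``, each > 0.
    block_sizes, control_block_sizes
        Experimental per-block counts ``(d_1, ..., d_J)`` and control
        per-block counts ``(d_01, ..., d_0J)``; empty for fully sequential.
    control_burn_in
        Control burn-in ``r_0`` (block designs only).
    control_split
        ``(m_01, m_02)`` partition of the control observations into the
        weight groups used by the terminal step of the invariance recursion;
        defaults to ``(n0 - 1, 1)``.
    alpha
        One-sided significance level.
    """

    t: int
    n: int
    n0: int
    burn_in: tuple[int, ...]
    block_sizes: tuple[int, ...] = ()
    control_block_sizes: tuple[int, ...] = ()
    control_burn_in: int = 0
    control_split: tuple[int, int] | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "burn_in", tuple(int(r) for r in self.burn_in))
        object.__setattr__(self, "block_sizes", tuple(int(d) for d in self.block_sizes))
        object.__setattr__(
            self, "control_block_sizes", tuple(int(d) for d in self.control_block_sizes)
        )
        if self.control_split is None:
            object.__setattr__(self, "control_split", (self.n0 - 1, 1))
        else:
            object.__setattr__(
                self, "control_split", tuple(int(m) for m in self.control_split)
            )
        self._validate()

    def _validate(self) -> None:
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if len(self.burn_in) != self.t:
            raise ValueError("burn_in must have one entry per experimental arm")
        if any(r <= 0 for r in self.burn_in):
            raise ValueError("all burn-in counts must be positive")
        if self.r > self.n:
            raise ValueError("burn-in exceeds total experimental sample size")
        if self.n0 < 2:
            raise ValueError("need at least two control patients")
        m01, m02 = self.control_split
        if m01 < 1 or m02 < 1 or m01 + m02 != self.n0:
            raise ValueError("control_split must be positive and sum to n0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.is_block:
            if len(self.control_block_sizes) != len(self.block_sizes):
                raise ValueError("block_sizes and control_block_sizes differ in length")
            if sum(self.block_sizes) != self.n - self.r:
                raise ValueError("block sizes must sum to n - r")
            if self.control_burn_in <= 0:
                raise ValueError("block designs need a control burn-in r_0 > 0")
            if self.control_burn_in + sum(self.control_block_sizes) != self.n0:
                raise ValueError("r_0 + sum(d_0j) must equal n0")
            if self.control_block_sizes[-1] <= 1:
                # The final control block supplies the two terminal degrees of
                # freedom of the weight recursion.
                raise ValueError("the final control block needs d_0J > 1")

    @property
    def r(self) -> int:
        """Total burn-in size across experimental arms."""
        return sum(self.burn_in)

    @property
    def is_block(self) -> bool:
        return len(self.block_sizes) > 0

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    @property
    def burn_in_schedule(self) -> np.ndarray:
        """Fixed burn-in allocation sequence: r_1 patients to arm 1, etc."""
        return np.repeat(np.arange(1, self.t + 1), self.burn_in)

    def block_bounds(self) -> list[tuple[int, int]]:
        """(start, stop) slot indices (0-based) of each experimental block."""
        bounds, start = [], self.r
        for d in self.block_sizes:
            bounds.append((start, start + d))
            start += d
        return bounds


@dataclass
class TrialData:
    """A realized trial: per-patient experimental allocations and outcomes.

    ``allocations[k]`` is the arm (1..t) of the k-th experimental patient and
    ``outcomes[k]`` their response; ``control_outcomes`` holds the n0 control
    responses in patient order.
    """

    allocations: np.ndarray
    outcomes: np.ndarray
    control_outcomes: np.ndarray

    def __post_init__(self) -> None:
        self.allocations = np.asarray(self.allocations, dtype=np.int64)
        self.outcomes = np.asarray(self.outcomes, dtype=np.float64)
        self.control_outcomes = np.asarray(self.control_outcomes, dtype=np.float64)
        if self.allocations.shape != self.outcomes.shape:
            raise ValueError("allocations and outcomes must have equal length")
        if self.allocations.ndim != 1 or self.control_outcomes.ndim != 1:
            raise ValueError("trial data arrays must be one-dimensional")
        if self.allocations.size and self.allocations.min() < 1:
            raise ValueError("allocations must be arm indices >= 1")

    @property
    def n(self) -> int:
        return self.allocations.size

    @property
    def n0(self) -> int:
        return self.control_outcomes.size

    def arm_count(self, arm: int) -> int:
        return int(np.sum(self.allocations == arm))

    def n_I(self, I) -> int:
        """Number of allocations to arms in the index set ``I``."""
        return int(np.isin(self.allocations, list(I)).sum())

    # -- plain-text round trip -------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        """Three-column table: patient_id, arm ('0' = control), outcome."""
        arm = np.concatenate([self.allocations, np.zeros(self.n0, dtype=np.int64)])
        outcome = np.concatenate([self.outcomes, self.control_outcomes])
        return pd.DataFrame(
            {"patient_id": np.arange(1, arm.size + 1), "arm": arm, "outcome": outcome}
        )

    def to_csv(self, path) -> None:
        self.to_table().to_csv(path, index=False)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "TrialData":
        required = {"patient_id", "arm", "outcome"}
        if not required.issubset(table.columns):
            raise ValueError(f"trial table needs columns {sorted(required)}")
        table = table.sort_values("patient_id")
        arm = table["arm"].to_numpy(dtype=np.int64)
        outcome = table["outcome"].to_numpy(dtype=np.float64)
        is_control = arm == 0
        return cls(
            allocations=arm[~is_control],
            outcomes=outcome[~is_control],
            control_outcomes=outcome[is_control],
        )

    @classmethod
    def from_csv(cls, path) -> "TrialData":
        return cls.from_table(pd.read_csv(path))


def draw_outcome(arm: int, effects: EffectConfig, rng: np.random.Generator) -> float:
    """Draw one outcome for ``arm`` (0 = control) under the normal model."""
    return float(rng.normal(effects.arm_mean(arm), 1.0))
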