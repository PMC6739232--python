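"""Conditional-invariance weights and the adaptive test statistic.

The adaptive statistic for an intersection hypothesis ``H_I`` is

    T~_I = sum_{k: a_k in I} X_k / w_k  -  sum_j X_0j / w0_j,

a reweighted contrast of the in-I experimental outcomes against the control.
The weights start at the natural values of the auxiliary design
(``n'_I`` for experimental slots, ``n0`` for controls) and are updated
whenever the realized allocation deviates from the auxiliary plan, in a way
that preserves the conditional null distribution of the not-yet-observed part
of the statistic at every step.  As a result ``T~_I`` is exactly
``N(0, 1/n'_I + 1/n0)`` under ``H_I`` for *any* response-adaptive rule,
restoring the familiar z-test calibration that adaptivity destroys.

Each deviation step re-solves two unknown coefficients from two conservation
laws applied to the remaining (future) part of the statistic:

* BALANCE - the sum of inverse weights on the experimental side equals the
  sum on the control side (the statistic stays mean-zero for every control
  mean ``mu``);
* VARIANCE - the sum of squared inverse weights equals ``1/n'_I + 1/n0``.

The two unknowns are the common coefficient of the remaining planned in-I
experimental slots and the common coefficient of the adjustable control
observations.  When the final planned slot is missed and no experimental
unknowns remain, the control observations split into two groups of sizes
``(m01, m02)`` (default ``(n0-1, 1)``) that supply the two terminal degrees
of freedom; this is what allows a single control observation to take an
extreme - even negative - weight while the rest stay near ``n0``.

Each step is a quadratic; the root continuous with the no-deviation
(natural-weight) solution is selected.  A negative discriminant means no
real weights exist; the result is flagged invalid rather than silently
mis-calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .auxiliary import AuxiliaryDesign
from .trial_model import TrialData, TrialDesign

__all__ = [
    "WeightSet",
    "TestStatisticValue",
    "sequential_weights",
    "block_weights",
    "block_weights_adaptive_control",
    "adaptive_statistic",
    "naive_z_statistic",
]

_DISC_TOL = 1e-9


def _solve_two_group(P, Q, A, B, current):
    """Solve ``P*u - Q*v = A`` and ``P*u**2 + Q*v**2 = B`` for (u, v).

    ``P`` observations share the unknown coefficient ``u`` and ``Q``
    observations the coefficient ``-v`` (sign handled by the caller).  Of the
    two roots, the one closest to ``current`` is returned (continuity with
    the no-deviation solution).  Works elementwise on arrays.

    Returns ``(u, v, ok)`` where ``ok`` is False where no real solution
    exists.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    disc = P * Q * ((P + Q) * B - A * A)
    ok = disc >= -_DISC_TOL
    root = np.sqrt(np.clip(disc, 0.0, None))
    denom = P * (P + Q)
    u_hi = (A * P + root) / denom
    u_lo = (A * P - root) / denom
    u = np.where(np.abs(u_hi - current) <= np.abs(u_lo - current), u_hi, u_lo)
    v = (P * u - A) / Q
    return u, v, ok


@dataclass
class WeightSet:
    """Adaptive weights for one intersection hypothesis.

    ``exp_weights[k]`` is the weight in effect at experimental slot ``k``
    after that slot was processed; it enters the statistic only where
    ``used[k]`` (i.e. ``a_k in I``).  Unused entries mirror the running
    future weight for display, matching the usual worked-example layout;
    a slot with no surviving experimental weight (terminal miss) is NaN.
    """

    hypothesis: frozenset
    exp_weights: np.ndarray
    used: np.ndarray
    control_weights: np.ndarray
    n_prime: int
    n0_prime: int
    valid: bool = True
    message: str = ""

    def balance_gap(self) -> float:
        """BALANCE identity residual: sum of used inverse experimental
        weights minus sum of inverse control weights (0 when valid)."""
        return float(
            np.sum(1.0 / self.exp_weights[self.used])
            - np.sum(1.0 / self.control_weights)
        )

    def variance_gap(self) -> float:
        """VARIANCE identity residual against ``1/n'_I + 1/n0'``."""
        total = np.sum(self.exp_weights[self.used] ** -2.0) + np.sum(
            self.control_weights ** -2.0
        )
        return float(total - (1.0 / self.n_prime + 1.0 / self.n0_prime))


@dataclass
class TestStatisticValue:
    """A test statistic with its null variance and one-sided p-value."""

    value: float
    variance: float
    p_value: float = field(init=False)
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            self.p_value = float(
                1.0 - special.ndtr(self.value / np.sqrt(self.variance))
            )
        else:
            self.p_value = float("nan")

    def rejects(self, alpha: float) -> bool:
        """One-sided rejection at level ``alpha``; invalid never rejects."""
        return bool(self.valid and self.p_value <= alpha)


def _validate_inputs(I, actual, aux: AuxiliaryDesign, design: TrialDesign):
    I = frozenset(int(i) for i in I)
    if not I or min(I) < 1 or max(I) > design.t:
        raise ValueError("hypothesis index set must be a non-empty subset of 1..t")
    actual = np.asarray(actual, dtype=np.int64)
    if actual.size != design.n or aux.n != design.n:
        raise ValueError("allocation sequences must have length n")
    if not np.array_equal(actual[: design.r], design.burn_in_schedule):
        raise ValueError("actual allocations must start with the burn-in schedule")
    return I, actual


def sequential_weights(
    I, actual, aux: AuxiliaryDesign, design: TrialDesign
) -> WeightSet:
    """Adaptive weights for a fully sequential trial with fixed control.

    The weights depend only on the allocation sequences and the design -
    never on outcomes.  Slots are processed in order; at each deviation
    between the realized and planned in-I membership the remaining
    experimental coefficient and the common control coefficient are
    re-solved from the BALANCE and VARIANCE conservation laws.
    """
    I, actual = _validate_inputs(I, actual, aux, design)
    in_a = np.isin(actual, sorted(I))
    in_b = aux.in_I(I)
    n_prime = int(in_b.sum())
    n0 = design.n0
    m01, m02 = design.control_split

    m = n_prime  # planned in-I slots at or after the current one
    x = 1.0 / n_prime  # coefficient of future planned in-I slots
    y = 1.0 / n0  # common coefficient of the control observations
    exp_w = np.empty(design.n)
    ctrl_w = np.full(n0, float(n0))
    valid, message = True, ""
    terminal_split = False

    for k in range(design.n):
        ia, ib = in_a[k], in_b[k]
        if ia and ib:  # planned slot filled as planned
            exp_w[k] = 1.0 / x
            m -= 1
        elif not ia and not ib:
            exp_w[k] = 1.0 / x
        elif ib and not ia:  # planned in-I slot missed
            if m > 1:
                A = m * x - n0 * y
                B = m * x * x + n0 * y * y
                x, v, ok = _solve_two_group(m - 1, n0, A, B, x)
                y = v
                m -= 1
                exp_w[k] = 1.0 / x
                if not ok:
                    valid, message = False, f"no real weights at slot {k + 1}"
                    break
            else:  # final planned slot missed: resolve into the control split
                A0 = n0 * y - x
                B0 = x * x + n0 * y * y
                y1, v, ok = _solve_two_group(m01, m02, A0, B0, y)
                y2 = -v
                m -= 1
                exp_w[k] = np.nan
                ctrl_w[:m01] = 1.0 / y1
                ctrl_w[m01:] = 1.0 / y2
                terminal_split = True
                if not ok:
                    valid, message = False, "no real weights at the final slot"
                break
        else:  # extra in-I observation at an out-of-plan slot
            A = m * x - n0 * y
            B = m * x * x + n0 * y * y
            x, v, ok = _solve_two_group(m + 1, n0, A, B, x)
            y = v
            exp_w[k] = 1.0 / x
            if not ok:
                valid, message = False, f"no real weights at slot {k + 1}"
                break

    if not terminal_split:
        ctrl_w[:] = 1.0 / y
    return WeightSet(
        hypothesis=I,
        exp_weights=exp_w,
        used=in_a,
        control_weights=ctrl_w,
        n_prime=n_prime,
        n0_prime=n0,
        valid=valid,
        message=message,
    )


def block_weights(I, actual, aux: AuxiliaryDesign, design: TrialDesign) -> WeightSet:
    """Adaptive weights for a block randomized trial with fixed control.

    All observations within a block share a weight; weights are re-solved
    block-by-block.  Control observations in past blocks (and the burn-in)
    are frozen at their current weight because the rule may already have
    seen them; the current block's and all future controls adjust together.
    """
    I, actual = _validate_inputs(I, actual, aux, design)
    if not design.is_block:
        raise ValueError("design has no block structure")
    in_a = np.isin(actual, sorted(I))
    in_b = aux.in_I(I)
    n_prime = int(in_b.sum())
    n0 = design.n0
    q = aux.block_counts(I, design)
    bounds = design.block_bounds()

    x = 1.0 / n_prime
    y = 1.0 / n0
    M = n_prime - int(in_b[: design.r].sum())  # planned in-I in current+future blocks
    N0f = n0 - design.control_burn_in  # adjustable controls (current+future)
    exp_w = np.empty(design.n)
    exp_w[: design.r] = 1.0 / x
    ctrl_w = np.full(n0, float(n0))
    ctrl_pos = design.control_burn_in
    valid, message = True, ""

    for l, (a_lo, a_hi) in enumerate(bounds):
        c = int(in_a[a_lo:a_hi].sum())
        d0 = design.control_block_sizes[l]
        P = c + M - q[l]
        if c == q[l]:
            pass  # realized in-I count as planned: weights carry over
        elif P >= 1:
            A = M * x - N0f * y
            B = M * x * x + N0f * y * y
            x, v, ok = _solve_two_group(P, N0f, A, B, x)
            y = v
            if not ok:
                valid, message = False, f"no real weights in block {l + 1}"
                exp_w[a_lo:] = np.nan
                break
        else:  # final block with no in-I observations: control split
            A0 = N0f * y - M * x
            B0 = M * x * x + N0f * y * y
            y1, v, ok = _solve_two_group(d0 - 1, 1, A0, B0, y)
            exp_w[a_lo:a_hi] = np.nan
            ctrl_w[ctrl_pos : ctrl_pos + d0 - 1] = 1.0 / y1
            ctrl_w[ctrl_pos + d0 - 1] = -1.0 / v
            ctrl_pos += d0
            M, N0f = M - q[l], N0f - d0
            if not ok:
                valid, message = False, f"no real weights in block {l + 1}"
            break
        exp_w[a_lo:a_hi] = 1.0 / x
        ctrl_w[ctrl_pos : ctrl_pos + d0] = 1.0 / y
        ctrl_pos += d0
        M, N0f = M - q[l], N0f - d0

    return WeightSet(
        hypothesis=I,
        exp_weights=exp_w,
        used=in_a,
        control_weights=ctrl_w,
        n_prime=n_prime,
        n0_prime=n0,
        valid=valid,
        message=message,
    )


def block_weights_adaptive_control(
    I, actual, control_block_counts, aux: AuxiliaryDesign, design: TrialDesign
) -> WeightSet:
    """Block weights when the control allocation is itself adaptive.

    ``control_block_counts`` are the realized per-block control counts
    ``c_01..c_0J`` (the burn-in ``r_0`` stays fixed); the design's
    ``control_block_sizes`` play the role of the planned (auxiliary) control
    allocation, and ``n0' = r_0 + sum d_0j`` is the auxiliary control total
    entering the null variance.  The procedure can genuinely fail here
    (e.g. too few realized controls left to absorb a deviation); failures
    are flagged, never silently mis-calibrated.
    """
    I, actual = _validate_inputs(I, actual, aux, design)
    if not design.is_block:
        raise ValueError("design has no block structure")
    c0 = tuple(int(v) for v in control_block_counts)
    if len(c0) != design.n_blocks or any(v < 0 for v in c0):
        raise ValueError("need one non-negative control count per block")
    in_a = np.isin(actual, sorted(I))
    in_b = aux.in_I(I)
    n_prime = int(in_b.sum())
    n0_prime = design.n0
    n0_actual = design.control_burn_in + sum(c0)
    q = aux.block_counts(I, design)
    bounds = design.block_bounds()

    x = 1.0 / n_prime
    y = 1.0 / n0_prime
    M = n_prime - int(in_b[: design.r].sum())
    N0f = n0_prime - design.control_burn_in  # planned adjustable controls
    exp_w = np.empty(design.n)
    exp_w[: design.r] = 1.0 / x
    ctrl_w = np.full(n0_actual, float(n0_prime))
    ctrl_pos = design.control_burn_in
    valid, message = True, ""

    for l, (a_lo, a_hi) in enumerate(bounds):
        c = int(in_a[a_lo:a_hi].sum())
        d0 = design.control_block_sizes[l]
        P = c + M - q[l]
        Q = c0[l] + N0f - d0  # realized current + planned future controls
        if c == q[l] and c0[l] == d0:
            exp_w[a_lo:a_hi] = 1.0 / x
            ctrl_w[ctrl_pos : ctrl_pos + c0[l]] = 1.0 / y
        elif P >= 1 and Q >= 1:
            A = M * x - N0f * y
            B = M * x * x + N0f * y * y
            x, v, ok = _solve_two_group(P, Q, A, B, x)
            y = v
            exp_w[a_lo:a_hi] = 1.0 / x
            ctrl_w[ctrl_pos : ctrl_pos + c0[l]] = 1.0 / y
            if not ok:
                valid = False
                message = f"no real weights in block {l + 1}"
                break
        elif P == 0 and Q >= 2:
            A0 = N0f * y - M * x
            B0 = M * x * x + N0f * y * y
            y1, v, ok = _solve_two_group(Q - 1, 1, A0, B0, y)
            exp_w[a_lo:a_hi] = np.nan
            # realized controls of this block take the split; any shortfall
            # relative to Q means future planned controls no longer exist,
            # which only happens in the final block.
            ctrl_w[ctrl_pos : ctrl_pos + c0[l] - 1] = 1.0 / y1
            if c0[l] >= 1:
                ctrl_w[ctrl_pos + c0[l] - 1] = -1.0 / v
            if l != design.n_blocks - 1 or c0[l] < 2 or Q != c0[l] or not ok:
                valid = False
                message = f"weight system infeasible in block {l + 1}"
            ctrl_pos += c0[l]
            M, N0f = M - q[l], N0f - d0
            break
        else:
            valid = False
            message = f"weight system infeasible in block {l + 1}"
            exp_w[a_lo:] = np.nan
            break
        ctrl_pos += c0[l]
        M, N0f = M - q[l], N0f - d0

    return WeightSet(
        hypothesis=I,
        exp_weights=exp_w,
        used=in_a,
        control_weights=ctrl_w,
        n_prime=n_prime,
        n0_prime=n0_prime,
        valid=valid,
        message=message,
    )


def adaptive_statistic(weights: WeightSet, data: TrialData) -> TestStatisticValue:
    """Evaluate the reweighted contrast ``T~_I`` for realized outcomes."""
    if data.n != weights.exp_weights.size:
        raise ValueError("weights and data disagree on the number of patients")
    if data.n0 != weights.control_weights.size:
        raise ValueError("weights and data disagree on the number of controls")
    variance = 1.0 / weights.n_prime + 1.0 / weights.n0_prime
    if not weights.valid:
        return TestStatisticValue(value=float("nan"), variance=variance, valid=False)
    value = float(
        np.sum(data.outcomes[weights.used] / weights.exp_weights[weights.used])
        - np.sum(data.control_outcomes / weights.control_weights)
    )
    return TestStatisticValue(value=value, variance=variance)


def naive_z_statistic(I, data: TrialData) -> TestStatisticValue:
    """The unadjusted z-test contrast for ``H_I`` with natural weights.

    Nominal null variance ``1/n_I + 1/n0``; under response-adaptive
    allocation this nominal calibration can fail badly.
    """
    I = sorted(set(int(i) for i in I))
    mask = np.isin(data.allocations, I)
    n_I = int(mask.sum())
    if n_I == 0:
        raise ValueError("no observations on the tested arms")
    value = float(data.outcomes[mask].mean() - data.control_outcomes.mean())
    return TestStatisticValue(value=value, variance=1.0 / n_I + 1.0 / data.n0)
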