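"""Multiplicity procedures over naive and adaptive statistics.

Four named procedures are built from two ingredients (a family of one-sided
local tests and a multiplicity principle):

* ``adaptive_closed`` - closure principle over the adaptive statistics
  ``T~_I`` for all non-empty intersections I;
* ``closed_z``        - closure principle over the naive z-statistics;
* ``holm_adaptive``   - Holm step-down over the adjusted per-arm p-values
  ``p~_i = 1 - Phi((1/n'_i + 1/n0')^{-1/2} T~_i)``;
* ``holm_z``          - Holm step-down over the naive per-arm p-values;

plus ``bonferroni_z`` and the ``dual`` test (reject only where both the
adaptive closed test and the closed z-test reject).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np

from .auxiliary import AuxiliaryDesign
from .invariance_weights import (
    TestStatisticValue,
    WeightSet,
    adaptive_statistic,
    block_weights,
    naive_z_statistic,
    sequential_weights,
)
from .trial_model import TrialData, TrialDesign

__all__ = [
    "TestReport",
    "closed_test",
    "holm",
    "bonferroni",
    "dual_test",
    "all_hypotheses",
    "analyze_trial",
]


def all_hypotheses(t: int) -> list[frozenset]:
    """All 2^t - 1 non-empty intersection hypothesis index sets."""
    arms = range(1, t + 1)
    return [
        frozenset(c) for c in chain.from_iterable(
            combinations(arms, k) for k in range(1, t + 1)
        )
    ]


def closed_test(decisions: dict, t: int) -> set[int]:
    """Closure principle: reject H_i iff every H_I with i in I is rejected.

    ``decisions`` maps each non-empty index set (any iterable of arms) to
    the local level-alpha rejection decision.
    """
    table = {frozenset(I): bool(d) for I, d in decisions.items()}
    missing = [I for I in all_hypotheses(t) if I not in table]
    if missing:
        raise ValueError(f"missing intersection decisions: {sorted(map(sorted, missing))}")
    return {
        i
        for i in range(1, t + 1)
        if all(table[I] for I in all_hypotheses(t) if i in I)
    }


def _clean_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def holm(p_values, alpha: float) -> set[int]:
    """Holm step-down: sort ascending, reject while p_(j) <= alpha/(t-j+1).

    Returns 1-based hypothesis indices.  Ties are ordered by hypothesis
    index, which only matters on a measure-zero event.
    """
    p = _clean_p(p_values)
    t = p.size
    order = np.argsort(p, kind="stable")
    rejected: set[int] = set()
    for j, idx in enumerate(order):
        if p[idx] <= alpha / (t - j):
            rejected.add(int(idx) + 1)
        else:
            break
    return rejected


def bonferroni(p_values, alpha: float) -> set[int]:
    """Reject H_i iff p_i <= alpha / t."""
    p = _clean_p(p_values)
    return {int(i) + 1 for i in np.nonzero(p <= alpha / p.size)[0]}


def dual_test(adaptive_set: set[int], naive_set: set[int]) -> set[int]:
    """Reject only hypotheses rejected by both component procedures."""
    return set(adaptive_set) & set(naive_set)


@dataclass
class TestReport:
    """Statistics, p-values and rejection sets for one analyzed trial."""

    alpha: float
    naive: dict[frozenset, TestStatisticValue]
    adaptive: dict[frozenset, TestStatisticValue]
    weights: dict[frozenset, WeightSet]
    rejections: dict[str, set[int]] = field(default_factory=dict)

    @property
    def invalid_hypotheses(self) -> list[frozenset]:
        return [I for I, s in self.adaptive.items() if not s.valid]

    def p_table(self):
        """Per-hypothesis summary as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for I in sorted(self.naive, key=lambda s: (len(s), sorted(s))):
            rows.append(
                {
                    "hypothesis": "H{" + ",".join(map(str, sorted(I))) + "}",
                    "z_statistic": self.naive[I].value,
                    "z_p": self.naive[I].p_value,
                    "adaptive_statistic": self.adaptive[I].value,
                    "adaptive_p": self.adaptive[I].p_value,
                    "valid_weights": self.adaptive[I].valid,
                }
            )
        return pd.DataFrame(rows)


def analyze_trial(
    data: TrialData,
    design: TrialDesign,
    aux: AuxiliaryDesign,
    alpha: float | None = None,
) -> TestReport:
    """Run every shipped multiplicity procedure on one realized trial.

    Computes naive and adaptive statistics for all 2^t - 1 intersections
    (block or sequential weights according to the design) and assembles the
    rejection sets of the six procedures.  An invalid weight set records
    'no rejection' for its hypothesis, which is conservative.
    """
    alpha = design.alpha if alpha is None else alpha
    t = design.t
    weights_fn = block_weights if design.is_block else sequential_weights
    hypos = all_hypotheses(t)

    naive = {I: naive_z_statistic(I, data) for I in hypos}
    wsets = {I: weights_fn(I, data.allocations, aux, design) for I in hypos}
    adaptive = {I: adaptive_statistic(wsets[I], data) for I in hypos}

    adaptive_closed = closed_test({I: adaptive[I].rejects(alpha) for I in hypos}, t)
    closed_z = closed_test({I: naive[I].rejects(alpha) for I in hypos}, t)
    p_adj = [adaptive[frozenset({i})] for i in range(1, t + 1)]
    p_nai = [naive[frozenset({i})] for i in range(1, t + 1)]
    # invalid weights -> p-value treated as 1 (never rejected)
    holm_adaptive = holm([p.p_value if p.valid else 1.0 for p in p_adj], alpha)
    holm_z = holm([p.p_value for p in p_nai], alpha)
    bonf_z = bonferroni([p.p_value for p in p_nai], alpha)

    report = TestReport(alpha=alpha, naive=naive, adaptive=adaptive, weights=wsets)
    report.rejections = {
        "adaptive_closed": adaptive_closed,
        "holm_adaptive": holm_adaptive,
        "closed_z": closed_z,
        "holm_z": holm_z,
        "bonferroni_z": bonf_z,
        "dual": dual_test(adaptive_closed, closed_z),
    }
    return report
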