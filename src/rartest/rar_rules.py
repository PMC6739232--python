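"""Response-adaptive randomization rules.

A rule maps the accrued per-arm history (allocation counts and outcome sums
for the experimental arms) to a probability vector over the experimental
arms.  Fully sequential designs draw the next patient's arm from that
vector after every patient; block designs draw a whole block of patients
independently from the vector computed at the start of the block.

Rules never see control information in the fully sequential setting; in
block designs the engine only feeds them data available at the previous
block boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "RandomizationRule",
    "EqualRandomization",
    "FixedProbability",
    "TypeIErrorInflator",
    "BayesianAdaptiveRandomization",
    "posterior_parameters",
    "prob_best",
    "rule_from_config",
]


def posterior_parameters(
    counts: np.ndarray,
    sums: np.ndarray,
    prior_means: np.ndarray,
    prior_vars: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate normal posterior (known unit outcome variance).

    Posterior precision adds one unit per observation, so the posterior
    variance strictly decreases with every incorporated outcome.
    """
    prec = 1.0 / np.asarray(prior_vars, dtype=float) + counts
    var = 1.0 / prec
    mean = (np.asarray(prior_means, dtype=float) / np.asarray(prior_vars, dtype=float) + sums) * var
    return mean, var


def prob_best(means: np.ndarray, variances: np.ndarray, n_nodes: int = 41) -> np.ndarray:
    """P(arm i has the largest mean) for independent normal posteriors.

    Exact (normal difference CDF) for two arms; Gauss-Hermite quadrature
    otherwise.  Accepts leading batch dimensions: ``means`` and ``variances``
    have shape ``(..., t)``.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    t = means.shape[-1]
    if t == 1:
        return np.ones_like(means)
    if t == 2:
        z = (means[..., 0] - means[..., 1]) / np.sqrt(
            variances[..., 0] + variances[..., 1]
        )
        p1 = special.ndtr(z)
        return np.stack([p1, 1.0 - p1], axis=-1)
    # P(X_i best) = E_Z prod_{j!=i} Phi((mu_i + sd_i Z - mu_j)/sd_j), Z~N(0,1)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / np.sqrt(2.0 * np.pi)
    sd = np.sqrt(variances)
    # shapes: (..., t, 1) against nodes (n,)
    x = means[..., :, None] + sd[..., :, None] * nodes  # candidate draws
    out = np.empty_like(means)
    for i in range(t):
        others = [j for j in range(t) if j != i]
        z = (
            x[..., i, None, :] - means[..., others, None]
        ) / sd[..., others, None]  # (..., t-1, n)
        out[..., i] = np.sum(np.prod(special.ndtr(z), axis=-2) * weights, axis=-1)
    # quadrature can drift slightly from a simplex
    out = np.clip(out, 0.0, None)
    return out / out.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class RandomizationRule:
    """Base class; subclasses implement :meth:`probabilities`."""

    name: str = field(default="rule", init=False)

    def probabilities(self, counts: np.ndarray, sums: np.ndarray) -> np.ndarray:
        """Allocation probability vector over experimental arms.

        ``counts`` and ``sums`` may carry leading batch dimensions
        ``(..., t)``; the returned array has the same shape.
        """
        raise NotImplementedError

    def next_arm(
        self, counts: np.ndarray, sums: np.ndarray, rng: np.random.Generator
    ) -> int:
        """Draw the next patient's arm (1-based) for one trial."""
        p = self.probabilities(np.asarray(counts, float), np.asarray(sums, float))
        return int(rng.choice(p.size, p=p)) + 1

    @property
    def uses_control(self) -> bool:
        """Whether the rule consumes control data (block designs only)."""
        return False


@dataclass(frozen=True)
class EqualRandomization(RandomizationRule):
    t: int = 2
    name: str = field(default="equal", init=False)

    def probabilities(self, counts, sums):
        shape = np.asarray(counts, float).shape
        return np.full(shape, 1.0 / self.t)


@dataclass(frozen=True)
class FixedProbability(RandomizationRule):
    """Fixed (possibly unequal) allocation probabilities."""

    p: tuple[float, ...] = (0.5, 0.5)
    name: str = field(default="fixed", init=False)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("p must be a probability vector")
        object.__setattr__(self, "p", tuple(p / p.sum()))

    def probabilities(self, counts, sums):
        counts = np.asarray(counts, float)
        return np.broadcast_to(np.asarray(self.p), counts.shape).copy()


@dataclass(frozen=True)
class TypeIErrorInflator(RandomizationRule):
    """Threshold-switching rule that inflates the naive z-test's error rate.

    Allocates to arm 2 as soon as the running mean of arm-1 outcomes exceeds
    ``threshold`` (informal early stopping of arm 1 'for efficacy'), and to
    arm 1 otherwise.  For three or more arms the remaining arms share the
    allocation uniformly once arm 1 stops.
    """

    threshold: float = 0.5
    name: str = field(default="inflator", init=False)

    def probabilities(self, counts, sums):
        counts = np.asarray(counts, dtype=float)
        sums = np.asarray(sums, dtype=float)
        t = counts.shape[-1]
        if t < 2:
            raise ValueError("the inflator rule needs at least two arms")
        n1 = counts[..., 0]
        if np.any(n1 < 1):
            raise ValueError("inflator rule undefined before any arm-1 outcome")
        stopped = sums[..., 0] / n1 > self.threshold
        p = np.zeros_like(counts)
        p[..., 0] = ~stopped
        rest = stopped[..., None] / (t - 1.0)
        p[..., 1:] = np.broadcast_to(rest, p[..., 1:].shape)
        return p


@dataclass(frozen=True)
class BayesianAdaptiveRandomization(RandomizationRule):
    """Allocation proportional to P(arm is best)^gamma.

    Conjugate normal posteriors with known unit outcome variance, updated
    after every patient (sequential) or every block (block designs).
    ``gamma = 0`` reduces to equal randomization; ``floor`` optionally bounds
    each allocation probability away from zero before renormalization.
    """

    t: int = 2
    gamma: float = 0.5
    prior_means: tuple[float, ...] | None = None
    prior_vars: tuple[float, ...] | None = None
    floor: float = 0.0
    name: str = field(default="bar", init=False)

    def __post_init__(self):
        pm = (5.0,) * self.t if self.prior_means is None else tuple(self.prior_means)
        pv = (1.0,) * self.t if self.prior_vars is None else tuple(self.prior_vars)
        if len(pm) != self.t or len(pv) != self.t:
            raise ValueError("prior parameter lengths must match t")
        if any(v <= 0 for v in pv):
            raise ValueError("prior variances must be positive")
        if not 0.0 <= self.floor < 1.0 / self.t:
            raise ValueError("floor must be in [0, 1/t)")
        object.__setattr__(self, "prior_means", pm)
        object.__setattr__(self, "prior_vars", pv)

    def probabilities(self, counts, sums):
        counts = np.asarray(counts, dtype=float)
        sums = np.asarray(sums, dtype=float)
        mean, var = posterior_parameters(
            counts, sums, np.asarray(self.prior_means), np.asarray(self.prior_vars)
        )
        if self.gamma == 0.0:
            return np.full_like(counts, 1.0 / self.t)
        p = prob_best(mean, var) ** self.gamma
        total = p.sum(axis=-1, keepdims=True)
        # all-zero rows can only arise from underflow; fall back to equal
        p = np.where(total > 0, p / np.where(total > 0, total, 1.0), 1.0 / self.t)
        if self.floor > 0.0:
            # floor plus proportional share of the remaining mass: keeps the
            # simplex and guarantees every probability >= floor
            p = self.floor + (1.0 - self.t * self.floor) * p
        return p


_RULES = {
    "equal": lambda t, params: EqualRandomization(t=t),
    "fixed": lambda t, params: FixedProbability(p=tuple(params.get("p", (1.0 / t,) * t))),
    "inflator": lambda t, params: TypeIErrorInflator(
        threshold=float(params.get("threshold", 0.5))
    ),
    "bar": lambda t, params: BayesianAdaptiveRandomization(
        t=t,
        gamma=float(params.get("gamma", 0.5)),
        prior_means=params.get("prior_means"),
        prior_vars=params.get("prior_vars"),
        floor=float(params.get("floor", 0.0)),
    ),
}


def rule_from_config(name: str, t: int, params: dict | None = None) -> RandomizationRule:
    """Instantiate a named rule (``equal``/``fixed``/``inflator``/``bar``)."""
    params = dict(params or {})
    try:
        factory = _RULES[name]
    except KeyError:
        raise ValueError(f"unknown rule {name!r}; one of {sorted(_RULES)}")
    return factory(t, params)
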