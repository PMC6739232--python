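"""Monte-Carlo harness: trial simulation and operating characteristics.

`run_trial` simulates a single trial patient-by-patient (or block-by-block)
and is the readable reference path.  `estimate_oc` estimates familywise
error rate (FWER) and disjunctive power per multiplicity procedure over many
replicates; internally it uses a replicate-vectorized engine that advances
all replicates one patient (or block) at a time with numpy, which is what
makes 1e5-replicate studies feasible on one core.  The vectorized and
scalar paths are equality-tested against each other in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .auxiliary import AuxiliaryDesign, uniform_auxiliary
from .invariance_weights import _solve_two_group
from .rar_rules import RandomizationRule, rule_from_config
from .testing import all_hypotheses
from .trial_model import EffectConfig, TrialData, TrialDesign, substream

__all__ = [
    "PROCEDURES",
    "OperatingCharacteristics",
    "run_trial",
    "estimate_oc",
    "scenario_table",
    "load_config",
    "SCENARIO_PRESETS",
    "preset",
]

PROCEDURES = (
    "adaptive_closed",
    "holm_adaptive",
    "closed_z",
    "holm_z",
    "bonferroni_z",
    "dual",
)


# --------------------------------------------------------------------------
# single-trial simulation (reference path)
# --------------------------------------------------------------------------

def run_trial(
    design: TrialDesign,
    rule: RandomizationRule,
    effects: EffectConfig,
    seed: int,
) -> TrialData:
    """Simulate one trial: burn-in, then rule-driven allocation.

    Sequential designs consult the rule before every patient; block designs
    compute one probability vector per block from the data available at the
    block boundary and draw the whole block from it.
    """
    if effects.t != design.t:
        raise ValueError("effects and design disagree on the number of arms")
    rng_out = substream(seed, "outcomes")
    rng_ctrl = substream(seed, "control")
    rng_rule = substream(seed, "rule")
    deltas = np.asarray(effects.deltas)

    alloc = np.empty(design.n, dtype=np.int64)
    outcomes = np.empty(design.n)
    counts = np.zeros(design.t)
    sums = np.zeros(design.t)

    def draw(k: int, arm: int) -> None:
        alloc[k] = arm
        outcomes[k] = effects.mu + deltas[arm - 1] + rng_out.standard_normal()
        counts[arm - 1] += 1
        sums[arm - 1] += outcomes[k]

    for k, arm in enumerate(design.burn_in_schedule):
        draw(k, int(arm))

    if design.is_block:
        for lo, hi in design.block_bounds():
            p = rule.probabilities(counts, sums)
            arms = rng_rule.choice(design.t, size=hi - lo, p=p) + 1
            for k, arm in zip(range(lo, hi), arms):
                draw(k, int(arm))
    else:
        for k in range(design.r, design.n):
            draw(k, rule.next_arm(counts, sums, rng_rule))

    control = effects.mu + rng_ctrl.standard_normal(design.n0)
    return TrialData(allocations=alloc, outcomes=outcomes, control_outcomes=control)


# --------------------------------------------------------------------------
# replicate-vectorized engine
# --------------------------------------------------------------------------

def _draw_categorical(p: np.ndarray, u: np.ndarray) -> np.ndarray:
    """0-based arm draws from per-row probability vectors via one uniform."""
    cdf = np.cumsum(p, axis=-1)
    return np.minimum((u[..., None] > cdf).sum(axis=-1), p.shape[-1] - 1)


def _simulate_batch(design, rule, effects, reps, seed):
    """Simulate `reps` trials; returns (A, X, ctrl) arrays."""
    rng_out = substream(seed, "outcomes")
    rng_ctrl = substream(seed, "control")
    rng_rule = substream(seed, "rule")
    t, n = design.t, design.n
    deltas = np.asarray(effects.deltas)

    A = np.empty((reps, n), dtype=np.int8)
    X = np.empty((reps, n))
    counts = np.zeros((reps, t))
    sums = np.zeros((reps, t))
    rows = np.arange(reps)

    def draw_column(k: int, arm0: np.ndarray) -> None:
        A[:, k] = arm0 + 1
        X[:, k] = effects.mu + deltas[arm0] + rng_out.standard_normal(reps)
        counts[rows, arm0] += 1
        sums[rows, arm0] += X[:, k]

    for k, arm in enumerate(design.burn_in_schedule):
        draw_column(k, np.full(reps, arm - 1))

    if design.is_block:
        for lo, hi in design.block_bounds():
            p = rule.probabilities(counts, sums)
            for k in range(lo, hi):
                draw_column(k, _draw_categorical(p, rng_rule.random(reps)))
    else:
        for k in range(design.r, n):
            p = rule.probabilities(counts, sums)
            draw_column(k, _draw_categorical(p, rng_rule.random(reps)))

    ctrl = effects.mu + rng_ctrl.standard_normal((reps, design.n0))
    return A, X, ctrl


def _auxiliary_batch(design, reps, seed):
    """Per-replicate uniform auxiliary base sequences, shape (reps, n-1)."""
    rng = substream(seed, "auxiliary")
    m = design.n - design.r - 1
    draws = rng.integers(1, design.t + 1, size=(reps, m))
    burn = np.broadcast_to(design.burn_in_schedule, (reps, design.r))
    return np.concatenate([burn, draws], axis=1).astype(np.int8)


def _adaptive_stats_sequential(A, X, base, I, design, ctrl):
    """Vectorized sequential weight recursion; returns (T, var, valid)."""
    reps, n = A.shape
    n0 = design.n0
    m01, m02 = design.control_split
    members = sorted(I)
    in_a = np.isin(A, members)
    in_b = np.concatenate(
        [np.isin(base, members), np.ones((reps, 1), dtype=bool)], axis=1
    )
    n_prime = in_b.sum(axis=1).astype(float)

    m = n_prime.copy()
    x = 1.0 / n_prime
    y = np.full(reps, 1.0 / n0)
    stat = np.zeros(reps)
    valid = np.ones(reps, dtype=bool)
    has_split = np.zeros(reps, dtype=bool)
    y1 = np.zeros(reps)
    y2 = np.zeros(reps)

    for k in range(n):
        ia, ib = in_a[:, k], in_b[:, k]
        miss = ib & ~ia
        term = miss & (m < 1.5)
        dev = (ia ^ ib) & ~term
        if dev.any():
            P = np.where(ib, m - 1.0, m + 1.0)
            An = m * x - n0 * y
            Bn = m * x * x + n0 * y * y
            u, v, ok = _solve_two_group(np.where(dev, P, 1.0), n0, An, Bn, x)
            x = np.where(dev, u, x)
            y = np.where(dev, v, y)
            valid &= ok | ~dev
        if term.any():
            A0 = n0 * y - x
            B0 = x * x + n0 * y * y
            u, v, ok = _solve_two_group(float(m01), float(m02), A0, B0, y)
            y1 = np.where(term, u, y1)
            y2 = np.where(term, -v, y2)
            has_split |= term
            valid &= ok | ~term
        stat += np.where(ia, x * X[:, k], 0.0)
        m = m - ib

    s0_g1 = ctrl[:, :m01].sum(axis=1)
    s0_g2 = ctrl[:, m01:].sum(axis=1)
    ctrl_stat = np.where(has_split, y1 * s0_g1 + y2 * s0_g2, y * (s0_g1 + s0_g2))
    return stat - ctrl_stat, 1.0 / n_prime + 1.0 / n0, valid


def _adaptive_stats_block(A, X, base, I, design, ctrl):
    """Vectorized block weight recursion (fixed control)."""
    reps, n = A.shape
    n0 = design.n0
    r, r0 = design.r, design.control_burn_in
    members = sorted(I)
    in_a = np.isin(A, members)
    in_b = np.concatenate(
        [np.isin(base, members), np.ones((reps, 1), dtype=bool)], axis=1
    )
    n_prime = in_b.sum(axis=1).astype(float)

    x = 1.0 / n_prime
    y = np.full(reps, 1.0 / n0)
    M = n_prime - in_b[:, :r].sum(axis=1)
    N0f = float(n0 - r0)
    valid = np.ones(reps, dtype=bool)
    stat = (X[:, :r] * in_a[:, :r]).sum(axis=1) * x
    ctrl_stat = ctrl[:, :r0].sum(axis=1) / n0
    pos = r0

    for l, (lo, hi) in enumerate(design.block_bounds()):
        c = in_a[:, lo:hi].sum(axis=1).astype(float)
        q = in_b[:, lo:hi].sum(axis=1).astype(float)
        d0 = design.control_block_sizes[l]
        S = (X[:, lo:hi] * in_a[:, lo:hi]).sum(axis=1)
        P = c + M - q
        dev = c != q
        mid = dev & (P > 0.5)
        term = dev & (P < 0.5)  # only possible in the final block
        if mid.any():
            An = M * x - N0f * y
            Bn = M * x * x + N0f * y * y
            u, v, ok = _solve_two_group(np.where(mid, P, 1.0), N0f, An, Bn, x)
            x = np.where(mid, u, x)
            y = np.where(mid, v, y)
            valid &= ok | ~mid
        ctrl_block = ctrl[:, pos : pos + d0].sum(axis=1)
        if term.any():
            A0 = N0f * y - M * x
            B0 = M * x * x + N0f * y * y
            u, v, ok = _solve_two_group(float(d0 - 1), 1.0, A0, B0, y)
            valid &= ok | ~term
            split = u * ctrl[:, pos : pos + d0 - 1].sum(axis=1) + (-v) * ctrl[:, pos + d0 - 1]
            ctrl_stat += np.where(term, split, y * ctrl_block)
        else:
            ctrl_stat += y * ctrl_block
        stat += x * S  # S is zero wherever term holds (c == 0)
        pos += d0
        M = M - q
        N0f -= d0

    return stat - ctrl_stat, 1.0 / n_prime + 1.0 / n0, valid


def _naive_stats(A, X, I, design, ctrl):
    members = sorted(I)
    mask = np.isin(A, members)
    n_I = mask.sum(axis=1).astype(float)
    T = (X * mask).sum(axis=1) / n_I - ctrl.mean(axis=1)
    return T, 1.0 / n_I + 1.0 / design.n0


def _one_sided_p(T, var):
    from scipy import special

    return 1.0 - special.ndtr(T / np.sqrt(var))


def _closed_batch(p_by_I, valid_by_I, alpha, t):
    """Closure principle, vectorized: (reps, t) rejection matrix."""
    local = {I: (p_by_I[I] <= alpha) & valid_by_I[I] for I in p_by_I}
    reps = next(iter(local.values())).size
    rej = np.ones((reps, t), dtype=bool)
    for I, dec in local.items():
        for i in I:
            rej[:, i - 1] &= dec
    return rej


def _holm_batch(P, alpha):
    reps, t = P.shape
    order = np.argsort(P, axis=1, kind="stable")
    p_sorted = np.take_along_axis(P, order, axis=1)
    thresholds = alpha / (t - np.arange(t))
    ok = np.cumprod(p_sorted <= thresholds, axis=1).astype(bool)
    rej = np.empty_like(ok)
    np.put_along_axis(rej, order, ok, axis=1)
    return rej


# --------------------------------------------------------------------------
# operating characteristics
# --------------------------------------------------------------------------

@dataclass
class OperatingCharacteristics:
    """Estimated FWER and disjunctive power (in %) per procedure.

    ``fwer`` is the fraction of replicates rejecting at least one true null
    hypothesis; ``power`` the fraction rejecting at least one false one.
    Entries are ``None`` when no hypothesis of that kind exists (matching
    the dashes in published operating-characteristic tables).
    """

    reps: int
    n_true: int
    n_false: int
    fwer: dict[str, float | None]
    power: dict[str, float | None]
    fwer_se: dict[str, float | None]
    power_se: dict[str, float | None]
    invalid_weight_events: int = 0

    @staticmethod
    def _rate(hits: np.ndarray | None, reps: int):
        if hits is None:
            return None, None
        p = float(hits.mean())
        return 100.0 * p, 100.0 * float(np.sqrt(p * (1.0 - p) / reps))


def estimate_oc(
    design: TrialDesign,
    rule: RandomizationRule,
    effects: EffectConfig,
    reps: int,
    seed: int,
    procedures: tuple[str, ...] = PROCEDURES,
) -> OperatingCharacteristics:
    """Estimate FWER and disjunctive power over ``reps`` simulated trials.

    Per replicate: draw a fresh uniform auxiliary design, simulate the trial
    under ``rule``, evaluate all requested multiplicity procedures, and
    accumulate rejections of true (delta_i <= 0) and false (delta_i > 0)
    hypotheses.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    unknown = set(procedures) - set(PROCEDURES)
    if unknown:
        raise ValueError(f"unknown procedures: {sorted(unknown)}")
    t = design.t
    A, X, ctrl = _simulate_batch(design, rule, effects, reps, seed)
    base = _auxiliary_batch(design, reps, seed)
    stats_fn = _adaptive_stats_block if design.is_block else _adaptive_stats_sequential

    hypos = all_hypotheses(t)
    need_adaptive = bool({"adaptive_closed", "holm_adaptive", "dual"} & set(procedures))
    adaptive_p, adaptive_valid = {}, {}
    invalid_events = 0
    if need_adaptive:
        for I in hypos:
            T, var, ok = stats_fn(A, X, base, I, design, ctrl)
            with np.errstate(invalid="ignore"):
                adaptive_p[I] = np.where(ok, _one_sided_p(T, var), 1.0)
            adaptive_valid[I] = ok
            invalid_events += int((~ok).sum())
    naive_p = {}
    for I in hypos:
        T, var = _naive_stats(A, X, I, design, ctrl)
        naive_p[I] = _one_sided_p(T, var)

    alpha = design.alpha
    ones = {I: np.ones(reps, dtype=bool) for I in hypos}
    rejections: dict[str, np.ndarray] = {}
    if "adaptive_closed" in procedures or "dual" in procedures:
        rejections["adaptive_closed"] = _closed_batch(adaptive_p, adaptive_valid, alpha, t)
    if "closed_z" in procedures or "dual" in procedures:
        rejections["closed_z"] = _closed_batch(naive_p, ones, alpha, t)
    if "holm_adaptive" in procedures:
        P = np.column_stack([adaptive_p[frozenset({i})] for i in range(1, t + 1)])
        rejections["holm_adaptive"] = _holm_batch(P, alpha)
    if "holm_z" in procedures or "bonferroni_z" in procedures:
        Pz = np.column_stack([naive_p[frozenset({i})] for i in range(1, t + 1)])
        if "holm_z" in procedures:
            rejections["holm_z"] = _holm_batch(Pz, alpha)
        if "bonferroni_z" in procedures:
            rejections["bonferroni_z"] = Pz <= alpha / t
    if "dual" in procedures:
        rejections["dual"] = rejections["adaptive_closed"] & rejections["closed_z"]

    deltas = np.asarray(effects.deltas)
    true_arms = deltas <= 0.0
    false_arms = deltas > 0.0
    fwer, power, fwer_se, power_se = {}, {}, {}, {}
    for name in procedures:
        rej = rejections[name]
        hits_true = rej[:, true_arms].any(axis=1) if true_arms.any() else None
        hits_false = rej[:, false_arms].any(axis=1) if false_arms.any() else None
        fwer[name], fwer_se[name] = OperatingCharacteristics._rate(hits_true, reps)
        power[name], power_se[name] = OperatingCharacteristics._rate(hits_false, reps)

    return OperatingCharacteristics(
        reps=reps,
        n_true=int(true_arms.sum()),
        n_false=int(false_arms.sum()),
        fwer=fwer,
        power=power,
        fwer_se=fwer_se,
        power_se=power_se,
        invalid_weight_events=invalid_events,
    )


# --------------------------------------------------------------------------
# scenario tables and configuration
# --------------------------------------------------------------------------

def _sequential_design(t: int, alpha: float = 0.05) -> TrialDesign:
    # 50 adaptively allocated patients after a 5-per-arm burn-in; 60/t controls
    return TrialDesign(
        t=t, n=5 * t + 50, n0=60 // t, burn_in=(5,) * t, alpha=alpha
    )


def _block_design(t: int, alpha: float = 0.05) -> TrialDesign:
    return TrialDesign(
        t=t,
        n=5 * t + 120,
        n0=65,
        burn_in=(5,) * t,
        block_sizes=(40, 40, 40),
        control_block_sizes=(20, 20, 20),
        control_burn_in=5,
        alpha=alpha,
    )


def _case_study_design() -> TrialDesign:
    return TrialDesign(
        t=2,
        n=61,
        n0=31,
        burn_in=(8, 8),
        block_sizes=(15, 15, 15),
        control_block_sizes=(8, 8, 8),
        control_burn_in=7,
    )


SCENARIO_PRESETS: dict[str, dict] = {
    "inflation_demo": {
        "design": lambda: TrialDesign(t=2, n=60, n0=60, burn_in=(5, 5)),
        "rule": ("inflator", {}),
        "scenarios": [(0.0, 1.0)],
    },
    "sequential_inflator": {
        "design": _sequential_design,
        "rule": ("inflator", {}),
        "scenarios": {
            2: [(0.0, 0.0), (0.0, 1.0), (0.5, 0.5)],
            3: [
                (0.0, 0.0, 0.0),
                (0.0, 0.0, 1.0),
                (0.0, 1.0, 1.0),
                (0.0, 0.5, 1.0),
                (0.5, 0.5, 0.5),
            ],
        },
    },
    "sequential_bar": {
        "design": _sequential_design,
        "rule": ("bar", {"gamma": 0.5}),
        "scenarios": {
            2: [(0.0, 0.0), (0.0, 0.5), (0.5, 0.5)],
            3: [
                (0.0, 0.0, 0.0),
                (0.0, 0.0, 1.0),
                (0.0, 1.0, 1.0),
                (0.0, 0.5, 1.0),
                (0.5, 0.5, 0.5),
            ],
        },
    },
    "block_inflator": {
        "design": _block_design,
        "rule": ("inflator", {}),
        "scenarios": {
            2: [(0.0, 0.0), (0.0, 1.0), (0.5, 0.5)],
            3: [
                (0.0, 0.0, 0.0),
                (0.0, 0.0, 1.0),
                (0.0, 1.0, 1.0),
                (0.0, 0.5, 1.0),
                (0.5, 0.5, 0.5),
            ],
        },
    },
    "block_bar": {
        "design": _block_design,
        "rule": ("bar", {"gamma": 0.5}),
        "scenarios": {
            2: [(0.0, 0.0), (0.0, 0.5), (0.5, 0.5)],
            3: [
                (0.0, 0.0, 0.0),
                (0.0, 0.0, 0.5),
                (0.0, 0.5, 0.5),
                (0.0, 0.25, 0.5),
                (0.5, 0.5, 0.5),
            ],
        },
    },
    "case_study": {
        "design": _case_study_design,
        "rule": ("bar", {"gamma": 0.5, "prior_means": (5.0, 5.0), "prior_vars": (1.0, 1.0)}),
        "scenarios": [((66.2 - 17.3) / 3.5, (72.3 - 17.3) / 3.5)],
        "mu": 17.3 / 3.5,
    },
}


def preset(name: str, t: int = 2):
    """Resolve a named scenario preset into (design, rule, effect configs)."""
    try:
        spec = SCENARIO_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; one of {sorted(SCENARIO_PRESETS)}")
    design_factory = spec["design"]
    design = design_factory(t) if design_factory.__code__.co_argcount else design_factory()
    rule_name, params = spec["rule"]
    rule = rule_from_config(rule_name, design.t, params)
    scen = spec["scenarios"]
    if isinstance(scen, dict):
        scen = scen[design.t]
    mu = spec.get("mu", 0.0)
    effects = [EffectConfig(deltas=d, mu=mu) for d in scen]
    return design, rule, effects


def scenario_table(
    design: TrialDesign,
    rule: RandomizationRule,
    scenarios: list[EffectConfig],
    reps: int,
    seed: int,
    procedures: tuple[str, ...] = PROCEDURES,
) -> pd.DataFrame:
    """Operating characteristics for a list of effect scenarios.

    One row per scenario; error/power columns per procedure, ``NaN`` where
    the quantity is undefined (no true / no false hypotheses).
    """
    rows = []
    for idx, eff in enumerate(scenarios, start=1):
        oc = estimate_oc(design, rule, eff, reps, seed + idx - 1, procedures)
        row: dict = {
            "scenario": idx,
            "deltas": ",".join(f"{d:g}" for d in eff.deltas),
        }
        for name in procedures:
            row[f"{name}_error"] = np.nan if oc.fwer[name] is None else oc.fwer[name]
            row[f"{name}_power"] = np.nan if oc.power[name] is None else oc.power[name]
        row["invalid_weight_events"] = oc.invalid_weight_events
        rows.append(row)
    return pd.DataFrame(rows)


def load_config(path):
    """Load a trial/simulation configuration from a YAML file.

    Expected keys: ``design`` (TrialDesign fields), ``rule`` (name +
    params), ``scenarios`` (list of {deltas, mu}), optional ``reps``,
    ``seed``, ``auxiliary`` (digit string for an explicit sequence).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    d = dict(cfg["design"])
    design = TrialDesign(
        t=int(d["t"]),
        n=int(d["n"]),
        n0=int(d["n0"]),
        burn_in=tuple(d["burn_in"]),
        block_sizes=tuple(d.get("block_sizes", ())),
        control_block_sizes=tuple(d.get("control_block_sizes", ())),
        control_burn_in=int(d.get("control_burn_in", 0)),
        control_split=tuple(d["control_split"]) if "control_split" in d else None,
        alpha=float(d.get("alpha", 0.05)),
    )
    r = cfg.get("rule", {"name": "equal"})
    rule = rule_from_config(r["name"], design.t, r.get("params", {}))
    scenarios = [
        EffectConfig(deltas=tuple(s["deltas"]), mu=float(s.get("mu", 0.0)))
        for s in cfg.get("scenarios", [])
    ]
    return {
        "design": design,
        "rule": rule,
        "scenarios": scenarios,
        "reps": int(cfg.get("reps", 10000)),
        "seed": int(cfg.get("seed", 0)),
        "auxiliary": cfg.get("auxiliary"),
    }
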