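# Methods

## Model and assumptions

A multi-armed trial allocates `n` patients to `t` experimental arms and
`n0` to a shared control.  Outcomes are independent normals with known unit
variance; arm `i` adds an incremental effect `delta_i` to the control mean
`mu`.  One-sided elementary hypotheses `H_i: delta_i = 0` (against
`delta_i > 0`) are combined through intersection hypotheses
`H_I = ∩_{i∈I} H_i` for the closure principle.  The experimental
allocation is response-adaptive after a fixed burn-in (`r_i > 0` patients
per arm).  In the fully sequential setting the control allocation is fixed
and the rule may not use control data; in the block-randomized setting the
rule sees all data, including control outcomes, up to the previous block
boundary.

## The adaptive statistic

For each `I` a fixed **auxiliary design** `b_1..b_n` is chosen before the
trial: the burn-in schedule, an arbitrary fixed middle section, and a final
slot `b_n` that must belong to `I`.  Write `n'_I` for the auxiliary in-I
total and `m_{I,k}` for the in-I count among slots `k..n`.  The adaptive
statistic

    T~_I = sum_{k: a_k in I} X_k / w_k^(I) - sum_j X_0j / w0_j

starts from the natural plan (`w = n'_I` on experimental in-I slots,
`w0 = n0` on controls, giving the auxiliary z-statistic) and treats the
realized trial as a stream of modifications of that plan.  Conditional
invariance requires that at every step the conditional null law of the
not-yet-observed part of the statistic is unchanged, for every value of the
nuisance mean `mu`.  Because that part is a linear form in iid normals, it
is pinned by two conserved quantities:

- **balance** — the sum of its coefficients (mean term),
- **variance** — the sum of squared coefficients,

which at completion become the package-wide invariants
`sum 1/w (experimental, used) = sum 1/w0` and
`sum 1/w^2 + sum 1/w0^2 = 1/n'_I + 1/n0`, checked to 1e-9 on every weight
set the package produces.

### Sequential recursion

State: the number `m` of remaining planned in-I slots, one common
coefficient `x` for those slots, one common coefficient `y` for the control
observations.  Processing slot `k`:

- **planned and filled** (`b_k ∈ I`, `a_k ∈ I`): the observation is
  consumed at weight `1/x`; `m` decreases.  Arm identity within `I` is
  irrelevant — under `H_I` all in-I arms share the control distribution.
- **miss** (`b_k ∈ I`, `a_k ∉ I`): the remaining pool shrinks to `m − 1`
  slots; new `(x', y')` solve the two conservation equations.
- **extra** (`b_k ∉ I`, `a_k ∈ I`): the observation joins the pool, which
  momentarily holds `m + 1` members at a new common `(x', y')`; the extra
  observation is consumed at `1/x'`.
- **terminal miss** (final slot, `a_n ∉ I`): no experimental unknowns
  remain, so the control group supplies both degrees of freedom: it splits
  into groups of sizes `(m01, m02)` — default `(n0 − 1, 1)` — with one
  coefficient each.  This is what keeps `n0 − 1` control weights near the
  natural `n0` while a single control observation absorbs the residual,
  possibly with a large or negative weight.

Each step reduces to the quadratic system `P u − Q v = A`,
`P u² + Q v² = B`; of its two roots the one closest to the current
coefficient is taken (the branch continuous with the no-deviation solution,
which is also the branch that reproduces the published two-arm worked
example digit for digit).  A negative discriminant means no real weights
exist; the weight set is flagged invalid, the affected hypothesis records
"no rejection" (conservative for FWER), and the event is counted.

The weights are a function of the allocation sequences and design constants
only — outcomes never enter — so the construction is predictable in the
martingale sense, which is what makes `T~_I` exactly
`N(0, 1/n'_I + 1/n0)` under `H_I` for any adaptive rule.  The test suite
verifies this calibration by simulation (mean, variance, and
Kolmogorov-Smirnov checks) under every shipped rule in both the sequential
and block settings.

### Block designs

With blocks, all observations in a block share one weight and updates
happen block-by-block.  Control patients are blocked too (`r_0` burn-in,
`d_0l` per block) because the rule may have seen them: control weights of
past blocks are frozen, and the adjustable control pool at block `l` is the
current plus future control blocks.  A block whose realized in-I count
equals its planned count leaves all weights unchanged; otherwise the pooled
system is re-solved exactly as above.  If the final block holds no in-I
observation at all, the terminal degrees of freedom come from splitting the
final control block `(d_0J − 1, 1)` — the reason the design requires
`d_0J > 1`.  When the control allocation is itself adaptive, the realized
control counts replace the planned ones in the pool sizes; this variant can
genuinely fail (for example, one realized control left where two are
needed), and failures are flagged with the offending block, never silently
mis-calibrated.

## Procedures

`adaptive_closed` applies the closure principle to the `2^t − 1` adaptive
statistics at local level alpha; `holm_adaptive` applies Holm step-down to
the adjusted p-values `p~_i = 1 − Phi((1/n'_i + 1/n0')^{-1/2} T~_i)`;
`closed_z`, `holm_z`, and `bonferroni_z` are the analogous z-test
procedures; `dual` rejects only where both the adaptive closed test and the
closed z-test reject.  Invalid weight sets enter every procedure as
p-value 1.  Holm ties are broken by hypothesis index (a measure-zero event,
for determinism only).

## Randomization rules

- `equal`, `fixed` — constant allocation probabilities.
- `inflator` — the threshold-switching rule used as an adversarial
  stress case: allocate to arm 2 once the running mean of arm-1 outcomes
  exceeds 0.5 (threshold configurable), else arm 1.  For `t ≥ 3` the
  remaining arms share the allocation uniformly once arm 1 stops; this is
  the minimal extension of the two-arm mechanism and is exercised by
  property tests only.
- `bar` — Bayesian adaptive randomization: conjugate normal posteriors
  (known unit outcome variance) per experimental arm, allocation
  probability proportional to `P(arm posterior-best)^gamma`, updated every
  patient (sequential) or every block.  Defaults follow the
  hypercholesterolemia case-study configuration: priors `N(5, 1)` and
  `gamma = 0.5`.  `gamma = 0` recovers equal randomization; an optional
  floor keeps every probability at or above a chosen minimum via
  `floor + (1 − t·floor)·p`.  P(best) is exact for two arms (normal
  difference CDF) and computed by 41-node Gauss-Hermite quadrature
  otherwise — a deterministic evaluation, so the scalar and vectorized
  simulation paths are numerically identical; quadrature agrees with a
  4·10^5-draw Monte-Carlo evaluation to three decimals in the tests.
  Probability-of-best is computed over the experimental arms only, since
  they are the allocation targets.

All rules consume only (counts, outcome sums) histories passed to them, so
past decisions replay exactly from truncated data.

## Auxiliary designs

The default simulation auxiliary is the equipoise choice: after the
burn-in, `n − r − 1` iid uniform draws on `{1..t}`, redrawn for every
simulated replicate from a dedicated RNG substream, with the final slot
resolved per hypothesis as `min(I)` (any fixed member of `I` would do; the
minimum is deterministic and reproducible).  Explicit sequences can be
supplied as digit strings.  For block designs without a user-supplied
sequence, a deterministic even split per block is available, remainders to
lower arm indices, the final block reserving its last slot.  The auxiliary
affects power — a plan close to the realized allocation keeps weights near
natural — but never error control.

## Synthetic data and what passing tests show

The generator draws exactly the outcome model above: independent unit-
variance normals, effects constant in time, outcomes available immediately
after allocation, no dropout, and a control stream independent of the
experimental one (per block in block designs, so rules may legitimately see
past control blocks).  Study dimensions follow the published scenarios:
fully sequential `t = 2` with 5-per-arm burn-in, 50 adaptive allocations,
`n0 = 30` (and `t = 3` analogues); blocks `(40, 40, 40)` experimental /
`(20, 20, 20)` control with 5-per-arm burn-in; the case-study block design
`(15, 15, 15)/(8, 8, 8)` with burn-in 8 per dose and 7 controls, effects
taken from the standardized LDL-C reductions (17.3/3.5 control, 66.2/3.5
and 72.3/3.5 on the doses).  Passing tests therefore demonstrate exact
calibration and strong FWER control *within this model* — they say nothing
about unknown variances, non-normal outcomes, time trends, or delayed
responses, which the method itself does not claim to cover (randomization
tests are the usual alternative there).

## Numerical choices and problem sizes

- Quadratic steps: discriminant tolerance 1e-9 (clipped to zero above
  −1e-9, invalid below); root selection by continuity as above.
- Weight identities are asserted to 1e-9 on every produced weight set.
- The Monte-Carlo engine advances all replicates one patient at a time
  with numpy; the scalar per-trial path is retained as the reference
  implementation and the two are equality-tested to 1e-10 on shared
  inputs.
- One global seed expands into four named substreams (outcomes, control,
  rule, auxiliary), so changing the rule leaves outcome draws untouched.
- The acceptance script uses 1e5 replicates per scenario (Monte-Carlo SE
  about 0.07 percentage points for a 5% rate); the test suite's stochastic
  checks use 1e4-1e5 replicates with tolerances stated per test, sizes
  chosen to keep the default suite around ten seconds.

## Known limitations

- Known, common outcome variance; normal outcomes only.
- Negative or complex weights cannot be ruled out in principle; they are
  flagged and treated as non-rejections rather than repaired.  None occur
  in the shipped scenarios.
- Under extreme rules (the inflator with a truly null arm 1) the adaptive
  tests pay a substantial power price relative to z-tests — the price of
  exact error control in a near-worst-case allocation pattern.
- The adaptive-control variant requires at least two realized controls in
  the final block to absorb a terminal deviation and fails (flagged)
  otherwise.
- Single-trial analysis requires the auxiliary design to have been fixed
  before the trial; the CLI draws one only as an explicitly noted
  convenience for exploration.
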