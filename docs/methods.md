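# Methods

## Model

A population of `N` agents invests into a common-pool resource. Agent `i`
chooses `x_i >= 0` (investment units are abstract, as are monetary units) and
receives

    E_i = r_i x_i P(x_tot) - c_i C_i(x_i),     x_tot = sum_j x_j.

Assumptions baked into the framework:

- the commons reacts instantaneously: `P` is a static, strictly decreasing
  function of total investment with `P(0) = 1` (no regeneration dynamics,
  no stochastic productivity);
- agents are price takers on the commons: each optimizes its own payoff
  holding others fixed, with `d x_tot / d x_i = 1`;
- agents stay in the market whenever their payoff is strictly positive,
  irrespective of its size, and quit otherwise;
- there is no direct interaction between agents beyond the shared `x_tot`.

A return multiplier `r_i` (how much extracted resource is worth to agent
`i`) is supported throughout via the exact reduction `(c, r) -> (c/r, 1)`
with payoffs rescaled by `r` (`tocsim.scenarios.effective_costs`).

### Productivity families

| family | `P(x)` | notes |
|---|---|---|
| exponential | `e^{-x}` | reference model; `x_tot -> N` as costs vanish, never diverges |
| power_law | `(1+x)^{-beta}`, `beta > 0` | resilient commons; runaway (`x_tot -> inf`) when costs vanish and `N >= beta` |
| linear_finite | `1 - x/x_max` on `[0, x_max]` | commons of finite size; closed-form equilibrium `(1-c̄) N x_max/(N+1)` |
| custom | user functions | an *analytic* slope is required; solvers never differentiate numerically |

### Cost families

Linear `C(x) = x`, or logarithmic `C(x) = log(1 + gamma x)/gamma` with
marginal cost `1/(1 + gamma x)`. Both satisfy `C(0) = 0`, `C'(0) = 1`, so
`c_i` is always the marginal cost of the first invested unit. `gamma > 0`
means falling marginal costs (economies of scale), `gamma < 0` rising
marginal costs with a divergence at `x = 1/|gamma|`; `gamma -> 0` recovers
the linear family (implemented through `log1p`, accurate to `|gamma| = 0`).
The Taylor expansion is `x - (gamma/2) x^2 + O(x^3)`; we parameterize
curvature by the logarithmic-family `gamma` itself throughout. No upper
bound is imposed on `gamma`: viability at large curvature is decided by the
bifurcation analysis, not by input validation. Per-agent curvature
overrides are accepted but every built-in scenario uses a single
population-level `gamma`.

## Equilibria

**Linear costs** (any productivity). Stationarity gives
`x_i = (c_max - c_i)/(-P')` with `c_max = P(x_tot)`, and averaging yields
the scalar self-consistency `P(x) - c̄ = -(x/N) P'(x)`, which depends on the
cost distribution only through `(N, c̄)`. For the exponential family the
root is bracketed in `[0, N(1-c̄)]`, where the residual provably changes
sign, and solved by Brent's method to `1e-13`; other families expand a
geometric bracket and raise a runaway error if the residual never changes
sign. `c̄ >= 1` returns a flagged no-investment state. Payoffs follow the
quadratic dispersion relation `E(c) = (c_max - c)^2/(-P')`; its decomposition
`mean(E) = (c_max - c̄)^2/(-P') + var(c)/(-P')` is exposed as a diagnostic.

**Cooperative protocol.** Equal shares `x_i = x_tot/N` with `x_tot` at the
single-investor optimum of the mean cost. This is the natural reference
(optimal for identical agents); richer welfare objectives (Gini-constrained
etc.) are deliberately out of scope. High-cost agents can still be
unprofitable and are decimated with the same loop as in the selfish case,
recomputing `c̄` each round.

**Curved costs** (exponential productivity). Stationarity is a quadratic in
`x_i`; the stable branch is the larger root for `gamma > 0` and the smaller
for `gamma < 0` (verified against the sign of the flow derivative). Roots
are evaluated with the cancellation-free quadratic formula so the
near-linear limit `gamma -> 0` stays accurate. The self-consistent state
solves `F(x_tot) = sum of stable roots at e^{-x_tot} - x_tot = 0`. Since
each stable root increases with `c_max` (both signs of `gamma`), `F` is
strictly decreasing, the root unique for a fixed member set, and a bracketed
Brent solve is unconditionally convergent — a damped fixed-point iteration
on `x_tot` was tried first and cycles on the reference scenario, which is
why the root formulation is used. If the member set straddles a root
disappearance (residual above `1e-8`), the solver defers to gradient flow.

**Gradient flow.** Projected explicit dynamics
`x <- max(0, x + eta dE/dx)` with default `eta = 0.01`, converged when the
per-step displacement falls below `1e-12` (so residual gradients are
~`1e-10`). The fixed point satisfies complementarity: active agents have
zero gradient, inactive ones non-positive gradient. Agents below `1e-9` at
convergence are classified as market exits; no freezing is applied during
the flow, so re-entry of a profitable agent (possible when `gamma < 1`,
where the origin is unstable for `c < c_max`) is never blocked.

## Decimation

Each round: solve the equilibrium of the current member set, remove every
agent whose survival predicate fails, renormalize `(N, c̄)`, repeat until
nothing changes. Survival means `c_i < c_max` (equivalently `x_i > 0`,
strictly, with a `1e-12` margin — threshold agents with `c_i = c_max` do not
survive) for linear costs, and *existence of a stable positive stationary
point with strictly positive payoff* for curved costs, honouring the
protected region `c_max < c_i <= c_node` that exists for `gamma > 1`.
Elimination is batch by default; a one-at-a-time option exists as a
sensitivity probe (both reach the same fixed point on all built-in
scenarios, which is tested). A mean cost at or above `P(0) = 1` removes only
the agents with `c_i >= 1` — they can never profit — and re-solves.

Initialization matters for curved costs: with entry barriers the Nash state
is history-dependent. The default policy starts from the member set and
total investment of the linear-cost decimated equilibrium of the same
population, so incumbents begin at finite investments and the protected
region is reachable; an `all` policy is available. After convergence an
entry test is applied: any eliminated agent with a positive payoff gradient
at `x = 0+` is readmitted (this never fires for `gamma >= 0` scenarios, but
keeps the final state entry-stable for convex costs, where the linear
initialization can be too conservative).

## Scenario generators

The generators encode the study conditions rather than free dials:

- **grid**: `c_i = 0.15 + 0.002 i`, 50 starting agents (any start at or
  above the 18-agent fixed point yields the same state; 50 also comfortably
  exceeds every curved-cost survivor count). The optional oligarch sits at
  `c = 0.1`, appended after the grid.
- **two-point oligarch**: one zero-cost agent (stored as `c = 1e-300`, the
  agent contract requires `c > 0`) against `N-1` identical bulk agents at
  `c̄ + alpha (c_max - c̄)`. We use the exact
  `alpha = c̄ / ((N-1)(c_max - c̄))`, so the empirical mean reproduces `c̄`
  to rounding; the commonly quoted `alpha ≈ 1/x_tot` is its large-`N`
  approximation. Feasibility requires `x_tot > 1` (else `alpha >= 1` and
  the bulk would be priced out), which is enforced.
- **random**: seeded uniform or truncated-normal costs clipped into the
  open unit interval, for property tests (e.g. a spread `~1/N` around the
  mean produces whole-population `1/N^2` poverty).

What the generators do *not* emulate: empirically measured cost
distributions, entry of new agents over time, or noise in returns. Passing
tests therefore demonstrate the self-consistency and scaling structure of
the equilibrium model, not the calibration of any real market or habitat.

## Numerical choices

- Root solves: Brent, `xtol <= 1e-13`, machine-precision relative
  tolerance; residuals checked post-hoc.
- Thresholds: survival margin `1e-12`; flow exit threshold `1e-9`;
  curved-cost residual guard `1e-8`.
- `c̄ -> 0` limits (runaway classification) are handled symbolically via an
  explicit limit branch, never by plugging in a tiny float.
- Scaling-law slopes are ordinary least squares on log-log values over
  `N in {10, 10^2, 10^3, 10^4}` — closed-form equilibria, so the experiment
  runs in milliseconds.
- Benchmark comparisons round half-to-even to 3 decimals, the printed
  precision of the reference table.

## Known limitations

- The computed total investment for the grid-plus-oligarch selfish
  configuration is `x_tot = 1.71893` (consistent with its `c_max = 0.179`
  and the oligarch payoff 0.035); published roundings of this quantity may
  differ in the final digit.
- For `gamma > 1` the survivor count is protocol-conditional: entry
  barriers create multiple Nash states, and only the documented default
  initialization is asserted.
- The frozen bifurcation diagram holds `x_tot` fixed; it is a local
  stability statement and breaks down far from equilibrium.
- No repeated-game strategies, punishment, reputation, or dynamic resource
  regeneration; the cooperative protocol is the basic equal-share one.
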