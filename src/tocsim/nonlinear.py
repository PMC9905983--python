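"""Equilibria for curved (logarithmic) cost functions under exponential productivity.

With C(x) = log(1 + gamma x)/gamma the stationarity condition dE_i/dx_i = 0,

    (1 - x_i) e^{-x_tot} = c_i / (1 + gamma x_i),

is quadratic in x_i.  Writing c_max = e^{-x_tot}, the candidate investments are

    x_i = (gamma-1)/(2 gamma) +/- sqrt( ((gamma-1)/(2 gamma))^2
                                        + (c_max - c_i)/(gamma c_max) ),

the '+' root being dynamically stable for gamma > 0 and the '-' root for
gamma < 0.  For gamma > 0 the two roots merge in a saddle-node bifurcation at
c_node = c_max (gamma+1)^2 / (4 gamma): agents costlier than c_node have no
stationary investment at all.  For gamma > 1 the zero-investment state is
locally stable whenever c_i > c_max, so incumbents in (c_max, c_node] are
protected by an entry barrier and leave the market by "sudden death" when
pushed past c_node.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .linear import EquilibriumState, allocate_investments, solve_total_investment
from .models import ConvergenceError, Population, payoff, payoff_gradient

logger = logging.getLogger(__name__)

__all__ = [
    "StationaryRoots",
    "BifurcationPoint",
    "FrozenDiagram",
    "FlowSummary",
    "stationary_roots",
    "saddle_node_threshold",
    "self_consistent_state",
    "gradient_flow",
    "frozen_bifurcation_diagram",
    "best_response_oracle",
]

_EXIT_THRESHOLD = 1e-9  # investments below this at convergence count as market exits


@dataclass(frozen=True)
class StationaryRoots:
    """The +/- roots of the stationarity quadratic for one agent."""

    root_minus: float | None
    root_plus: float | None
    stable: str  # "plus" for gamma > 0, "minus" for gamma < 0
    discriminant: float

    @property
    def stable_root(self) -> float | None:
        return self.root_plus if self.stable == "plus" else self.root_minus

    @property
    def unstable_root(self) -> float | None:
        return self.root_minus if self.stable == "plus" else self.root_plus


@dataclass(frozen=True)
class BifurcationPoint:
    c_node: float
    x_node: float


@dataclass
class FlowSummary:
    steps: int
    max_gradient: float
    exited_ids: tuple[int, ...]
    trajectory: pd.DataFrame | None = None


def stationary_roots(c_i: float, gamma: float, c_max: float) -> StationaryRoots:
    """Solve the stationarity quadratic for one agent at a frozen c_max.

    Uses the cancellation-free quadratic formula so the small root stays
    accurate in the near-linear limit gamma -> 0.
    """
    if gamma == 0.0:
        raise ValueError("gamma = 0 is the linear-cost case; use tocsim.linear")
    # gamma x^2 + (1 - gamma) x - (c_max - c)/c_max = 0
    B = 1.0 - gamma
    C = -(c_max - c_i) / c_max
    disc4 = B * B - 4.0 * gamma * C
    a = (gamma - 1.0) / (2.0 * gamma)
    disc = disc4 / (4.0 * gamma * gamma)  # in the (a, sqrt) parameterization
    stable = "plus" if gamma > 0 else "minus"
    if disc4 < 0:
        return StationaryRoots(None, None, stable, disc)
    q = -0.5 * (B + math.copysign(math.sqrt(disc4), B if B != 0 else 1.0))
    r1, r2 = q / gamma, (C / q if q != 0 else a)
    return StationaryRoots(min(r1, r2), max(r1, r2), stable, disc)


def _stable_roots_vec(c: np.ndarray, gamma: np.ndarray, c_max: float) -> np.ndarray:
    """Vectorized stable root; NaN where the discriminant is negative.

    Rows with gamma == 0 use the linear-cost limit (c_max - c)/c_max; the
    stable root is the larger one for gamma > 0, the smaller for gamma < 0.
    """
    out = np.empty_like(c)
    lin = gamma == 0.0
    out[lin] = (c_max - c[lin]) / c_max
    g = gamma[~lin]
    cc = c[~lin]
    B = 1.0 - g
    C = -(c_max - cc) / c_max
    disc4 = B * B - 4.0 * g * C
    ok = disc4 >= 0
    sq = np.sqrt(np.where(ok, disc4, 0.0))
    q = -0.5 * (B + np.where(B >= 0, sq, -sq))
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = q / g
        r2 = np.where(q != 0, C / q, (g - 1.0) / (2.0 * g))
    r = np.where(g > 0, np.maximum(r1, r2), np.minimum(r1, r2))
    out[~lin] = np.where(ok, r, np.nan)
    return out


def saddle_node_threshold(c_max: float, gamma: float) -> BifurcationPoint:
    """Cost c_node where the stable and unstable roots merge (gamma > 0).

    c_node = c_max (gamma+1)^2 / (4 gamma) >= c_max, with equality at
    gamma = 1; it diverges as gamma -> 0.  The merged investment is
    x_node = (gamma-1)/(2 gamma), finite — hence the square-root "sudden
    death" approach instead of a linear fade-out.
    """
    if gamma <= 0:
        raise ValueError("the saddle-node threshold is defined for gamma > 0")
    c_node = c_max * (gamma + 1.0) ** 2 / (4.0 * gamma)
    x_node = (gamma - 1.0) / (2.0 * gamma)
    return BifurcationPoint(c_node, x_node)


# ---------------------------------------------------------------------------
# self-consistent equilibrium
# ---------------------------------------------------------------------------

def _nl_payoffs(population: Population, x: np.ndarray, x_tot: float) -> np.ndarray:
    c_max = math.exp(-x_tot)
    g = population.gammas
    cost = np.empty_like(x)
    lin = g == 0.0
    cost[lin] = x[lin]
    cost[~lin] = np.log1p(g[~lin] * x[~lin]) / g[~lin]
    return population.rs * x * c_max - population.costs * cost


def self_consistent_state(
    population: Population,
    members: np.ndarray | None = None,
    x_tot0: float | None = None,
    tolerance: float = 1e-10,
) -> EquilibriumState:
    """Equilibrium with every member on its stable branch, c_max = e^{-x_tot}.

    Solves F(x_tot) = sum of stable roots at e^{-x_tot} minus x_tot, which is
    strictly decreasing in x_tot for a fixed member set, so the equilibrium is
    unique given the membership.  Members without a real positive root at the
    solution, or with non-positive payoff there, are marked as non-survivors
    (the decimation loop acts on those marks).
    """
    if population.productivity.family != "exponential":
        raise ValueError("the curved-cost solver is defined for exponential productivity")
    n = population.n
    members = np.ones(n, dtype=bool) if members is None else np.asarray(members, dtype=bool)
    c_eff = population.effective_costs
    g = population.gammas

    def member_roots(x_tot: float) -> np.ndarray:
        c_max = math.exp(-x_tot)
        r = _stable_roots_vec(c_eff, g, c_max)
        return np.where(members & np.isfinite(r) & (r > 0), r, 0.0)

    def F(x_tot: float) -> float:
        return member_roots(x_tot).sum() - x_tot

    if not members.any() or F(1e-14) <= 0:
        x_tot = 0.0
    else:
        hi = max(1.0, float(members.sum()), 2.0 * (x_tot0 or 0.0))
        while F(hi) > 0:
            hi *= 2.0
            if hi > 1e6:
                raise ConvergenceError("no finite self-consistent total investment")
        x_tot = brentq(F, 1e-14, hi, xtol=1e-14, rtol=8.9e-16)

    resid = abs(F(x_tot)) if x_tot > 0 else 0.0
    if resid > max(tolerance, 1e-8):
        raise ConvergenceError(
            f"self-consistency residual {resid:.3g}: the member set straddles a "
            "root disappearance; use gradient_flow",
            last_state=x_tot,
        )
    x = member_roots(x_tot)
    payoffs = _nl_payoffs(population, x, x_tot)
    survivors = members & (x > 0) & (payoffs > 1e-12)
    payoffs = np.where(x > 0, payoffs, 0.0)
    c_max = math.exp(-x_tot)
    gam = population.cost.gamma
    c_node = c_max * (gam + 1.0) ** 2 / (4.0 * gam) if gam > 0 else None
    logger.debug("self_consistent_state: n_members=%d -> x_tot=%.12g resid=%.3g",
                 members.sum(), x_tot, resid)
    return EquilibriumState(
        x=x, x_tot=float(x_tot), c_max=c_max, payoffs=payoffs,
        survivors=survivors, residual=resid, mode="selfish",
        ids=population.ids, c_node=c_node,
    )


# ---------------------------------------------------------------------------
# gradient flow
# ---------------------------------------------------------------------------

def gradient_flow(
    population: Population,
    x0: np.ndarray,
    step: float = 0.01,
    tol: float = 1e-12,
    max_steps: int = 2_000_000,
    record_every: int = 0,
) -> tuple[EquilibriumState, FlowSummary]:
    """Projected best-response dynamics: x <- max(0, x + step * dE/dx).

    Every agent climbs its own payoff gradient simultaneously; the projection
    enforces x >= 0.  The fixed point satisfies complementarity: positive
    investments have vanishing gradient, zero investments non-positive
    gradient.  Convergence is declared when the largest displacement per step
    falls below ``tol``.
    """
    if population.productivity.family != "exponential":
        raise ValueError("gradient flow is implemented for exponential productivity")
    x = np.asarray(x0, dtype=float).copy()
    if (x < 0).any():
        raise ValueError("initial investments must be >= 0")
    c = population.costs
    r = population.rs
    g = population.gammas
    rows = []
    step_count = max_steps
    for k in range(max_steps):
        x_tot = x.sum()
        grad = r * (1.0 - x) * math.exp(-x_tot) - c / (1.0 + g * x)
        x_new = np.maximum(0.0, x + step * grad)
        if record_every and k % record_every == 0:
            rows.extend(
                {"step": k, "agent_id": int(i), "x": float(v)}
                for i, v in zip(population.ids, x)
            )
        if np.abs(x_new - x).max() < tol:
            x = x_new
            step_count = k + 1
            break
        x = x_new
    else:
        raise ConvergenceError(
            f"gradient flow did not converge in {max_steps} steps", last_state=x
        )
    x_tot = float(x.sum())
    grad = r * (1.0 - x) * math.exp(-x_tot) - c / (1.0 + g * x)
    payoffs = _nl_payoffs(population, x, x_tot)
    alive = x > _EXIT_THRESHOLD
    survivors = alive & (payoffs > 1e-12)
    x = np.where(alive, x, 0.0)
    payoffs = np.where(alive, payoffs, 0.0)
    residual = float(np.abs(grad[alive]).max()) if alive.any() else 0.0
    c_max = math.exp(-x_tot)
    gam = population.cost.gamma
    c_node = c_max * (gam + 1.0) ** 2 / (4.0 * gam) if gam > 0 else None
    state = EquilibriumState(
        x=x, x_tot=x_tot, c_max=c_max, payoffs=payoffs, survivors=survivors,
        residual=residual, mode="selfish", ids=population.ids, c_node=c_node,
    )
    summary = FlowSummary(
        steps=step_count,
        max_gradient=residual,
        exited_ids=tuple(int(i) for i in population.ids[~alive]),
        trajectory=pd.DataFrame(rows) if rows else None,
    )
    logger.debug("gradient_flow: %d steps, max|grad|=%.3g, %d exits",
                 summary.steps, summary.max_gradient, len(summary.exited_ids))
    return state, summary


# ---------------------------------------------------------------------------
# frozen bifurcation diagram
# ---------------------------------------------------------------------------

@dataclass
class FrozenDiagram:
    """Stationary branches and flow signs at a frozen (constant) c_max.

    ``stable_branch``/``unstable_branch`` hold the root values over ``c_grid``
    (NaN beyond the saddle-node).  The transcritical point sits at
    (c_max, 0) — the zero-investment line switches stability there — and the
    saddle-node point at (c_node, x_node).  ``flow_sign(c, x)`` gives the sign
    of dE/dx at frozen total investment: for c in (c_max, c_node) the origin
    is stable while a stable positive branch coexists (entry barrier); beyond
    c_node all flow points to x = 0.
    """

    gamma: float
    c_max: float
    c_grid: np.ndarray
    stable_branch: np.ndarray
    unstable_branch: np.ndarray
    c_node: float
    x_node: float

    def flow_sign(self, c, x):
        x_tot = -math.log(self.c_max)
        c = np.asarray(c, dtype=float)
        x = np.asarray(x, dtype=float)
        grad = (1.0 - x) * self.c_max - c / (1.0 + self.gamma * x)
        return np.sign(grad)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for branch, vals in (("stable", self.stable_branch),
                             ("unstable", self.unstable_branch)):
            for c, v in zip(self.c_grid, vals):
                rows.append({"c": c, "branch": branch, "x": v,
                             "flow_sign": 0.0 if not np.isfinite(v)
                             else float(self.flow_sign(c, max(v, 0.0)))})
        return pd.DataFrame(rows)


def frozen_bifurcation_diagram(
    gamma: float, c_max: float, c_grid: np.ndarray
) -> FrozenDiagram:
    """Stationary branches over a cost grid with c_max held constant."""
    if gamma <= 0:
        raise ValueError("the frozen diagram targets concave costs, gamma > 0")
    c_grid = np.asarray(c_grid, dtype=float)
    bp = saddle_node_threshold(c_max, gamma)
    stable = np.full_like(c_grid, np.nan)
    unstable = np.full_like(c_grid, np.nan)
    for j, c in enumerate(c_grid):
        roots = stationary_roots(c, gamma, c_max)
        if roots.discriminant >= 0:
            stable[j] = roots.stable_root
            unstable[j] = roots.unstable_root
    return FrozenDiagram(gamma, c_max, c_grid, stable, unstable, bp.c_node, bp.x_node)


# ---------------------------------------------------------------------------
# independent verification oracle
# ---------------------------------------------------------------------------

def best_response_oracle(
    population: Population, state: EquilibriumState, agent_index: int
) -> float:
    """Payoff improvement a single agent can gain by re-optimizing its x_i.

    Derivative-free 1-D maximization of the agent's payoff with everybody
    else's investment fixed (the total co-moving with x_i).  At a true Nash
    state the improvement is numerically zero for every agent.
    """
    agent = population.agents[agent_index]
    x_i = float(state.x[agent_index])
    x_others = state.x_tot - max(x_i, 0.0)
    prod, cost = population.productivity, population.cost

    def neg_payoff(y: float) -> float:
        return -payoff(agent, y, x_others + y, prod, cost)

    # for exponential productivity the gradient is negative for x_i >= 1
    upper = 1.0 if prod.family == "exponential" else max(1.0, 4.0 * (x_i + 1.0))
    upper = min(upper, cost.with_gamma(agent.gamma).domain_max * (1 - 1e-9))
    res = minimize_scalar(neg_payoff, bounds=(0.0, upper), method="bounded",
                          options={"xatol": 1e-12})
    current = -neg_payoff(max(x_i, 0.0))
    best = max(-res.fun, -neg_payoff(0.0), current)
    return best - current
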