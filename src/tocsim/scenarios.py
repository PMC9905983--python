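"""Population generators for the worked configurations and for property tests.

The study conditions are a uniformly spaced cost grid c_i = c_min + i*dc
(defaults c_min = 0.15, dc = 0.002, 50 starting agents), optionally with one
low-cost "oligarch" added at c = 0.1; a two-point construction placing a
zero-cost oligarch against an identical bulk; and seeded random populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .linear import solve_total_investment
from .models import AgentSpec, CostModel, Population, ProductivityModel

__all__ = [
    "ScenarioSpec",
    "grid_population",
    "two_point_oligarch_population",
    "random_population",
    "effective_costs",
]

DEFAULT_C_MIN = 0.15
DEFAULT_DELTA_C = 0.002
DEFAULT_N_START = 50
DEFAULT_OLIGARCH_C = 0.1


def grid_population(
    c_min: float = DEFAULT_C_MIN,
    delta_c: float = DEFAULT_DELTA_C,
    n_start: int = DEFAULT_N_START,
    oligarch_c: float | None = None,
    productivity: ProductivityModel | None = None,
    cost: CostModel | None = None,
) -> Population:
    """Uniformly spaced costs c_i = c_min + i*delta_c, optional oligarch below."""
    if n_start < 1:
        raise ValueError("n_start must be >= 1")
    agents = [AgentSpec(i, c_min + i * delta_c) for i in range(n_start)]
    if oligarch_c is not None:
        agents.append(AgentSpec(n_start, float(oligarch_c)))
    return Population(
        tuple(agents),
        productivity or ProductivityModel.exponential(),
        cost or CostModel.linear(),
    )


def two_point_oligarch_population(
    N: int,
    c_mean: float,
    model: ProductivityModel | None = None,
) -> Population:
    """One zero-cost oligarch against N-1 identical bulk agents.

    The bulk sits at c_mean + alpha (c_max - c_mean) with the exact
    alpha = c_mean / ((N-1)(c_max - c_mean)), so the empirical mean equals
    c_mean to rounding.  Bulk profitability (alpha < 1) requires the
    equilibrium at (N, c_mean) to have x_tot > 1.  The oligarch's equilibrium
    payoff is c_max itself — finite however large N grows — while every bulk
    agent is caught in catastrophic poverty.

    A strictly zero cost is not representable by the agent contract (c > 0),
    so the oligarch carries a cost of 1e-300, indistinguishable from zero at
    working precision.
    """
    model = model or ProductivityModel.exponential()
    if N < 2:
        raise ValueError("the construction needs at least two agents")
    x_tot = solve_total_investment(N, c_mean, model)
    if x_tot <= 1.0:
        raise ValueError(
            f"construction infeasible: x_tot = {x_tot:.4g} <= 1 at (N={N}, "
            f"c_mean={c_mean}); the bulk would be unprofitable (alpha >= 1)"
        )
    c_max = model.value(x_tot)
    alpha = c_mean / ((N - 1) * (c_max - c_mean))
    c_bulk = c_mean + alpha * (c_max - c_mean)
    agents = [AgentSpec(0, 1e-300)]
    agents += [AgentSpec(i, c_bulk) for i in range(1, N)]
    return Population(tuple(agents), model, CostModel.linear())


def random_population(
    N: int,
    seed: int | np.random.Generator,
    distribution: str = "uniform",
    low: float = 0.05,
    high: float = 0.95,
    loc: float = 0.3,
    scale: float = 0.1,
    productivity: ProductivityModel | None = None,
    cost: CostModel | None = None,
) -> Population:
    """Seeded random costs: uniform on [low, high] or truncated normal.

    All costs are clipped into the open unit interval; identical seeds give
    identical populations.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if distribution == "uniform":
        c = rng.uniform(low, high, size=N)
    elif distribution == "truncnorm":
        a, b = (0.0 - loc) / scale, (1.0 - loc) / scale
        c = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=N, random_state=rng)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    c = np.clip(c, 1e-9, 1.0 - 1e-9)
    agents = tuple(AgentSpec(i, float(ci)) for i, ci in enumerate(c))
    return Population(
        agents,
        productivity or ProductivityModel.exponential(),
        cost or CostModel.linear(),
    )


def effective_costs(population: Population) -> tuple[Population, Callable[[np.ndarray], np.ndarray]]:
    """Fold return multipliers into the costs: (c, r) -> (c/r, 1).

    Returns the transformed population and a back-map rescaling its payoffs
    by r; equilibria of the original and transformed populations correspond
    exactly (the transformed payoff times r is the original one).
    """
    rs = population.rs
    agents = tuple(
        AgentSpec(a.id, a.c / a.r, gamma=a.gamma, r=1.0) for a in population.agents
    )
    transformed = Population(agents, population.productivity, population.cost)

    def back_map(payoffs: np.ndarray) -> np.ndarray:
        return np.asarray(payoffs, dtype=float) * rs

    return transformed, back_map


@dataclass
class ScenarioSpec:
    """Serializable recipe for a generated population."""

    kind: str  # grid | grid_plus_oligarch | two_point_oligarch | random
    c_min: float = DEFAULT_C_MIN
    delta_c: float = DEFAULT_DELTA_C
    n_start: int = DEFAULT_N_START
    oligarch_c: float = DEFAULT_OLIGARCH_C
    c_mean: float = 0.2
    distribution: str = "uniform"
    low: float = 0.05
    high: float = 0.95
    seed: int = 0
    gamma: float = 0.0
    productivity: dict = field(default_factory=lambda: {"family": "exponential"})

    def build(self) -> Population:
        prod = ProductivityModel.from_dict(self.productivity)
        cost = CostModel.linear() if self.gamma == 0.0 else CostModel.logarithmic(self.gamma)
        if self.kind == "grid":
            return grid_population(self.c_min, self.delta_c, self.n_start,
                                   productivity=prod, cost=cost)
        if self.kind == "grid_plus_oligarch":
            return grid_population(self.c_min, self.delta_c, self.n_start,
                                   oligarch_c=self.oligarch_c, productivity=prod, cost=cost)
        if self.kind == "two_point_oligarch":
            return two_point_oligarch_population(self.n_start, self.c_mean, prod)
        if self.kind == "random":
            return random_population(self.n_start, self.seed, self.distribution,
                                     low=self.low, high=self.high,
                                     productivity=prod, cost=cost)
        raise ValueError(f"unknown scenario kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "c_min": self.c_min, "delta_c": self.delta_c,
            "n_start": self.n_start, "oligarch_c": self.oligarch_c,
            "c_mean": self.c_mean, "distribution": self.distribution,
            "low": self.low, "high": self.high, "seed": self.seed,
            "gamma": self.gamma, "productivity": dict(self.productivity),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)
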