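"""Model primitives: productivity of the commons, cost functions, agents, payoffs.

The commons is described by a per-unit return ("productivity") P(x_tot) that is
1 at zero exploitation and strictly decreasing in the total investment x_tot.
Agent ``i`` invests ``x_i >= 0`` at a monetary per-unit cost ``c_i`` through a
dimensionless cost function ``C(x)`` with ``C(0) = 0`` and ``C'(0) = 1``, and
receives the payoff

    E_i = r_i * x_i * P(x_tot) - c_i * C_i(x_i),

where the optional return multiplier ``r_i`` encodes how much the extracted
resource is worth to that particular agent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "RunawayError",
    "ConvergenceError",
    "ProductivityModel",
    "CostModel",
    "AgentSpec",
    "Population",
    "payoff",
    "payoff_gradient",
]


class DomainError(ValueError):
    """An evaluation point lies outside the domain of a model function."""


class RunawayError(RuntimeError):
    """Total investment diverges: the self-consistency condition has no root."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_state=None, trace=None):
        super().__init__(message)
        self.last_state = last_state
        self.trace = trace


# ---------------------------------------------------------------------------
# productivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProductivityModel:
    """Per-unit return of the commons, P(x_tot), with P(0)=1 and P' < 0.

    Families
    --------
    exponential
        P(x) = exp(-x).  The reference choice; total investment stays finite
        for any number of agents, even for vanishing costs.
    power_law
        P(x) = (1 + x)^(-beta), beta > 0.  A resilient commons; admits
        runaway exploitation when costs vanish and N >= beta.
    linear_finite
        P(x) = 1 - x / x_max on 0 <= x <= x_max.  A commons of finite size
        x_max whose productivity vanishes at full exploitation.
    custom
        User-supplied value and (analytic) slope functions.  Solvers rely on
        the analytic slope; numerical differentiation is reserved for tests.
    """

    family: str
    beta: float | None = None
    x_max: float | None = None
    value_fn: Callable[[float], float] | None = None
    slope_fn: Callable[[float], float] | None = None

    def __post_init__(self):
        if self.family not in ("exponential", "power_law", "linear_finite", "custom"):
            raise ValueError(f"unknown productivity family {self.family!r}")
        if self.family == "power_law" and not (self.beta is not None and self.beta > 0):
            raise ValueError("power_law requires beta > 0")
        if self.family == "linear_finite" and not (self.x_max is not None and self.x_max > 0):
            raise ValueError("linear_finite requires x_max > 0")
        if self.family == "custom" and (self.value_fn is None or self.slope_fn is None):
            raise ValueError("custom requires a value function and an analytic slope function")

    # constructors ----------------------------------------------------------
    @classmethod
    def exponential(cls) -> "ProductivityModel":
        return cls("exponential")

    @classmethod
    def power_law(cls, beta: float) -> "ProductivityModel":
        return cls("power_law", beta=float(beta))

    @classmethod
    def linear_finite(cls, x_max: float) -> "ProductivityModel":
        return cls("linear_finite", x_max=float(x_max))

    @classmethod
    def custom(cls, value_fn, slope_fn) -> "ProductivityModel":
        return cls("custom", value_fn=value_fn, slope_fn=slope_fn)

    # evaluation ------------------------------------------------------------
    @property
    def domain_max(self) -> float:
        return self.x_max if self.family == "linear_finite" else math.inf

    def _check_domain(self, x_tot) -> None:
        x = np.asarray(x_tot, dtype=float)
        if np.any(x < 0):
            raise DomainError(f"total investment must be >= 0, got {x_tot}")
        if np.any(x > self.domain_max):
            raise DomainError(
                f"total investment {x_tot} exceeds the size of the commons x_max={self.x_max}"
            )

    def value(self, x_tot):
        """Per-unit return P(x_tot); in (0, 1] on the domain interior."""
        self._check_domain(x_tot)
        x = np.asarray(x_tot, dtype=float)
        if self.family == "exponential":
            out = np.exp(-x)
        elif self.family == "power_law":
            out = (1.0 + x) ** (-self.beta)
        elif self.family == "linear_finite":
            out = 1.0 - x / self.x_max
        else:
            out = np.vectorize(self.value_fn, otypes=[float])(x)
        return float(out) if np.isscalar(x_tot) else out

    def slope(self, x_tot):
        """dP/dx_tot; strictly negative."""
        self._check_domain(x_tot)
        x = np.asarray(x_tot, dtype=float)
        if self.family == "exponential":
            out = -np.exp(-x)
        elif self.family == "power_law":
            out = -self.beta * (1.0 + x) ** (-self.beta - 1.0)
        elif self.family == "linear_finite":
            out = np.full_like(x, -1.0 / self.x_max)
        else:
            out = np.vectorize(self.slope_fn, otypes=[float])(x)
        return float(out) if np.isscalar(x_tot) else out

    def to_dict(self) -> dict:
        d = {"family": self.family}
        if self.beta is not None:
            d["beta"] = self.beta
        if self.x_max is not None:
            d["x_max"] = self.x_max
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProductivityModel":
        return cls(d["family"], beta=d.get("beta"), x_max=d.get("x_max"))


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostModel:
    """Dimensionless cost function with C(0) = 0 and C'(0) = 1.

    ``linear`` is C(x) = x (constant marginal costs).  ``logarithmic`` is
    C(x) = log(1 + gamma x)/gamma, whose marginal cost 1/(1 + gamma x) falls
    with x for gamma > 0 (concave costs, economies of scale) and rises for
    gamma < 0 (convex costs, diverging at x = 1/|gamma|).  As gamma -> 0 the
    logarithmic family converges pointwise to linear.
    """

    family: str = "linear"
    gamma: float = 0.0

    def __post_init__(self):
        if self.family not in ("linear", "logarithmic"):
            raise ValueError(f"unknown cost family {self.family!r}")
        if self.family == "linear" and self.gamma != 0.0:
            raise ValueError("linear cost family has no curvature parameter")

    @classmethod
    def linear(cls) -> "CostModel":
        return cls("linear", 0.0)

    @classmethod
    def logarithmic(cls, gamma: float) -> "CostModel":
        return cls("logarithmic", float(gamma))

    @property
    def domain_max(self) -> float:
        if self.family == "logarithmic" and self.gamma < 0:
            return 1.0 / abs(self.gamma)
        return math.inf

    def _check_domain(self, x) -> None:
        xa = np.asarray(x, dtype=float)
        if np.any(xa < 0):
            raise DomainError(f"investment must be >= 0, got {x}")
        if np.any(xa >= self.domain_max):
            raise DomainError(
                f"investment {x} at or beyond the cost divergence x = 1/|gamma| = {self.domain_max}"
            )

    def value(self, x):
        self._check_domain(x)
        xa = np.asarray(x, dtype=float)
        if self.family == "linear" or self.gamma == 0.0:
            out = xa.copy()
        else:
            out = np.log1p(self.gamma * xa) / self.gamma
        return float(out) if np.isscalar(x) else out

    def marginal(self, x):
        """Marginal cost C'(x); equals 1 at x = 0."""
        self._check_domain(x)
        xa = np.asarray(x, dtype=float)
        if self.family == "linear" or self.gamma == 0.0:
            out = np.ones_like(xa)
        else:
            out = 1.0 / (1.0 + self.gamma * xa)
        return float(out) if np.isscalar(x) else out

    def with_gamma(self, gamma: float | None) -> "CostModel":
        """Per-agent curvature override (no-op for the linear family or None)."""
        if gamma is None or self.family == "linear" or gamma == self.gamma:
            return self
        return CostModel.logarithmic(gamma)

    def to_dict(self) -> dict:
        return {"family": self.family, "gamma": self.gamma}

    @classmethod
    def from_dict(cls, d: dict) -> "CostModel":
        return cls(d["family"], float(d.get("gamma", 0.0)))


# ---------------------------------------------------------------------------
# agents and populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentSpec:
    """One investor: per-unit cost c > 0, optional curvature and return multiplier."""

    id: int
    c: float
    gamma: float | None = None
    r: float = 1.0

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError(f"agent {self.id}: per-unit cost must be > 0, got {self.c}")
        if not self.r > 0:
            raise ValueError(f"agent {self.id}: return multiplier must be > 0, got {self.r}")


@dataclass(frozen=True)
class Population:
    """An ordered collection of agents with the attached model specification."""

    agents: tuple[AgentSpec, ...]
    productivity: ProductivityModel = field(default_factory=ProductivityModel.exponential)
    cost: CostModel = field(default_factory=CostModel.linear)

    def __post_init__(self):
        object.__setattr__(self, "agents", tuple(self.agents))
        if len(self.agents) == 0:
            raise ValueError("a population needs at least one agent")
        ids = [a.id for a in self.agents]
        if len(set(ids)) != len(ids):
            raise ValueError("agent ids must be unique")

    # derived quantities ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.agents)

    @property
    def ids(self) -> np.ndarray:
        return np.array([a.id for a in self.agents], dtype=int)

    @property
    def costs(self) -> np.ndarray:
        return np.array([a.c for a in self.agents], dtype=float)

    @property
    def rs(self) -> np.ndarray:
        return np.array([a.r for a in self.agents], dtype=float)

    @property
    def gammas(self) -> np.ndarray:
        """Per-agent curvature; agent overrides fall back to the population value."""
        g0 = self.cost.gamma
        return np.array([g0 if a.gamma is None else a.gamma for a in self.agents], dtype=float)

    @property
    def effective_costs(self) -> np.ndarray:
        """c_i / r_i — the cost scale that governs equilibrium behaviour."""
        return self.costs / self.rs

    @property
    def c_mean(self) -> float:
        return float(self.costs.mean())

    @property
    def c_var(self) -> float:
        return float(self.costs.var())

    def cost_model_for(self, agent: AgentSpec) -> CostModel:
        return self.cost.with_gamma(agent.gamma)

    def subset(self, mask) -> "Population":
        mask = np.asarray(mask, dtype=bool)
        kept = tuple(a for a, m in zip(self.agents, mask) if m)
        if not kept:
            raise ValueError("subset would leave an empty population")
        return replace(self, agents=kept)

    @classmethod
    def from_costs(
        cls,
        costs: Sequence[float],
        productivity: ProductivityModel | None = None,
        cost: CostModel | None = None,
        rs: Sequence[float] | None = None,
    ) -> "Population":
        agents = tuple(
            AgentSpec(i, float(c), r=1.0 if rs is None else float(rs[i]))
            for i, c in enumerate(costs)
        )
        return cls(
            agents,
            productivity or ProductivityModel.exponential(),
            cost or CostModel.linear(),
        )


# ---------------------------------------------------------------------------
# payoffs
# ---------------------------------------------------------------------------

def _check_consistent(x_i: float, x_tot: float) -> None:
    if x_i < 0:
        raise DomainError(f"investment must be >= 0, got {x_i}")
    if x_i > x_tot + 1e-12:
        raise ValueError(f"individual investment {x_i} exceeds the total {x_tot}")


def payoff(
    agent: AgentSpec,
    x_i: float,
    x_tot: float,
    productivity: ProductivityModel,
    cost: CostModel,
) -> float:
    """Payoff E_i = r x_i P(x_tot) - c C(x_i); zero at zero investment."""
    _check_consistent(x_i, x_tot)
    cm = cost.with_gamma(agent.gamma)
    return agent.r * x_i * productivity.value(x_tot) - agent.c * cm.value(x_i)


def payoff_gradient(
    agent: AgentSpec,
    x_i: float,
    x_tot: float,
    productivity: ProductivityModel,
    cost: CostModel,
) -> float:
    """Marginal payoff dE_i/dx_i along the constraint dx_tot/dx_i = 1.

    Equals r P(x_tot) - c at x_i = 0: the entry condition for a newcomer.
    """
    _check_consistent(x_i, x_tot)
    cm = cost.with_gamma(agent.gamma)
    p = productivity.value(x_tot)
    dp = productivity.slope(x_tot)
    return agent.r * (p + x_i * dp) - agent.c * cm.marginal(x_i)
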