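"""Closed-form Nash and cooperative equilibria for linear (constant marginal) costs.

With linear costs and any strictly decreasing productivity P, the selfish
stationarity condition P(x_tot) - c_i = -x_i P'(x_tot) averages to the scalar
self-consistency

    P(x_tot) - c_mean = -(x_tot / N) P'(x_tot),

so the total investment depends on the cost distribution only through
(N, c_mean).  The profitability threshold is c_max = P(x_tot) and the
individual allocations and payoffs follow in closed form:

    x_i = (c_max - c_i) / (-P'),      E_i = (c_max - c_i)^2 / (-P').

The quadratic "dispersion relation" E(c_i) is the origin of catastrophic
poverty: c_max - c_mean shrinks as 1/N, so typical payoffs shrink as 1/N^2,
while the cooperative protocol (equal shares of the single-investor optimum)
gives the classical 1/N scaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import (
    ConvergenceError,
    CostModel,
    DomainError,
    Population,
    ProductivityModel,
    RunawayError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EquilibriumState",
    "SolveResult",
    "RunawayDiagnosis",
    "solve_total_investment",
    "linear_finite_total_investment",
    "allocate_investments",
    "dispersion_payoff",
    "cooperative_state",
    "mean_payoff_decomposition",
    "participation_window",
    "profit_margin",
    "detect_runaway",
]

_TOL_THRESHOLD = 1e-12  # strictness margin at the profitability threshold


@dataclass
class EquilibriumState:
    """Per-agent investments and payoffs at an equilibrium of a population.

    Arrays are aligned with the population's agent order.  Agents priced out
    of the market keep their *nominal* (possibly negative) allocation so the
    decimation loop can see them; their payoff entry is 0 and their survivor
    flag is False.  ``c_max = P(x_tot)`` is the profitability threshold and,
    for concave-cost states, ``c_node`` the saddle-node threshold above which
    no positive stationary investment exists.
    """

    x: np.ndarray
    x_tot: float
    c_max: float
    payoffs: np.ndarray
    survivors: np.ndarray
    residual: float
    mode: str  # "selfish" | "cooperative"
    ids: np.ndarray | None = None
    c_node: float | None = None

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def n_survivors(self) -> int:
        return int(self.survivors.sum())

    @property
    def E_tot(self) -> float:
        return float(self.payoffs[self.survivors].sum())

    @property
    def mean_payoff(self) -> float:
        ns = self.n_survivors
        return self.E_tot / ns if ns else 0.0

    def to_frame(self, population: Population | None = None) -> pd.DataFrame:
        d = {
            "id": self.ids if self.ids is not None else np.arange(self.n),
            "x": self.x,
            "payoff": self.payoffs,
            "survivor": self.survivors,
        }
        if population is not None:
            d["c"] = population.costs
            d = {k: d[k] for k in ("id", "c", "x", "payoff", "survivor")}
        return pd.DataFrame(d)


@dataclass
class SolveResult:
    x_tot: float
    residual: float
    profitable: bool  # False when c_mean >= P(0): no profitable investment exists


@dataclass
class RunawayDiagnosis:
    runaway: bool
    x_tot: float  # limiting (or solved) total investment; inf when runaway
    note: str = ""


# ---------------------------------------------------------------------------
# total investment
# ---------------------------------------------------------------------------

def linear_finite_total_investment(N: int, c_mean: float, x_max: float) -> float:
    """Closed form for the finite commons: x_tot = (1 - c_mean) N x_max / (N + 1)."""
    return (1.0 - c_mean) * N * x_max / (N + 1.0)


def _residual(model: ProductivityModel, N: float, c_mean: float, x: float) -> float:
    return model.value(x) - c_mean + (x / N) * model.slope(x)


def solve_total_investment(
    N: int,
    c_mean: float,
    model: ProductivityModel | None = None,
    tolerance: float = 1e-12,
    full_output: bool = False,
):
    """Solve P(x) - c_mean = -(x/N) P'(x) for the total investment.

    Returns 0.0 (flagged unprofitable in ``full_output`` mode) when
    c_mean >= P(0) = 1.  Raises :class:`RunawayError` when no finite root
    exists, which can only happen away from the exponential and finite-commons
    families.
    """
    model = model or ProductivityModel.exponential()
    if N < 1:
        raise ValueError("need at least one agent")
    if c_mean >= 1.0:
        res = SolveResult(0.0, 0.0, profitable=False)
        return res if full_output else res.x_tot
    if c_mean <= 0.0:
        raise ValueError("c_mean must be positive; use detect_runaway for the c_mean -> 0 limit")

    f = lambda x: _residual(model, N, c_mean, x)

    if model.family == "exponential":
        # (1 - x/N) e^{-x} spans [1 - c_mean above 0] down to <= 0 on [0, N(1-c_mean)]
        lo, hi = 0.0, N * (1.0 - c_mean)
    elif model.family == "linear_finite":
        x = linear_finite_total_investment(N, c_mean, model.x_max)
        res = SolveResult(x, abs(f(x)), profitable=True)
        return res if full_output else res.x_tot
    else:
        # geometric bracket expansion; declare runaway only if the residual
        # never changes sign
        lo, hi = 0.0, float(N)
        expansions = 0
        while f(hi) > 0:
            hi *= 2.0
            expansions += 1
            if expansions > 200 or hi > model.domain_max:
                raise RunawayError(
                    f"no finite total investment for N={N}, c_mean={c_mean} "
                    f"under {model.family} productivity (runaway exploitation)"
                )
        hi = min(hi, model.domain_max)

    x = brentq(f, lo, hi, xtol=min(tolerance, 1e-13), rtol=8.9e-16)
    resid = abs(f(x))
    if resid > tolerance:
        raise ConvergenceError(f"self-consistency residual {resid} above tolerance {tolerance}")
    logger.debug("solve_total_investment: N=%d c_mean=%.6g -> x_tot=%.12g resid=%.3g",
                 N, c_mean, x, resid)
    res = SolveResult(x, resid, profitable=True)
    return res if full_output else res.x_tot


# ---------------------------------------------------------------------------
# allocations, payoffs, diagnostics
# ---------------------------------------------------------------------------

def allocate_investments(population: Population, x_tot: float) -> EquilibriumState:
    """Selfish Nash allocation x_i = (c_max - c_i)/(-P') at a solved x_tot.

    Agents with c_i > c_max get a negative nominal x_i: they are flagged as
    non-survivors but not clipped, so decimation can act on them.
    """
    model = population.productivity
    c_max = model.value(x_tot)
    neg_slope = -model.slope(x_tot)
    c_eff = population.effective_costs
    x = (c_max - c_eff) / neg_slope
    survivors = x > _TOL_THRESHOLD
    payoffs = np.where(survivors, population.rs * x * (c_max - c_eff), 0.0)
    n = population.n
    resid = abs(_residual(model, n, float(c_eff.mean()), x_tot))
    return EquilibriumState(
        x=x,
        x_tot=float(x_tot),
        c_max=float(c_max),
        payoffs=payoffs,
        survivors=survivors,
        residual=resid,
        mode="selfish",
        ids=population.ids,
    )


def dispersion_payoff(c_i, x_tot: float, model: ProductivityModel | None = None):
    """Equilibrium payoff E(c) = (c_max - c)^2 / (-P'(x_tot)).

    Quadratic over the whole participation range [0, c_max]; returns NaN for
    costs above c_max (non-participation marker).  Accepts scalars or arrays.
    """
    model = model or ProductivityModel.exponential()
    c_max = model.value(x_tot)
    neg_slope = -model.slope(x_tot)
    c = np.asarray(c_i, dtype=float)
    out = np.where(c <= c_max, (c_max - c) ** 2 / neg_slope, np.nan)
    return float(out) if np.isscalar(c_i) else out


def cooperative_state(population: Population, x_tot: float | None = None) -> EquilibriumState:
    """Equal-share cooperative equilibrium: the community acts as one investor.

    x_tot solves the single-investor optimum at the mean cost; every agent
    invests x_tot/N and receives E_i = (c_max - c_i) x_tot / N.  High-cost
    agents (c_i > c_max) are flagged for cooperative decimation.
    """
    if population.cost.family != "linear":
        raise ValueError("the cooperative protocol is defined for linear costs")
    model = population.productivity
    c_eff = population.effective_costs
    c_mean = float(c_eff.mean())
    n = population.n
    if x_tot is None:
        res = solve_total_investment(1, c_mean, model, full_output=True)
        x_tot = res.x_tot
        resid = res.residual
        if not res.profitable:
            return EquilibriumState(
                x=np.zeros(n), x_tot=0.0, c_max=model.value(0.0),
                payoffs=np.zeros(n), survivors=np.zeros(n, dtype=bool),
                residual=0.0, mode="cooperative", ids=population.ids,
            )
    else:
        resid = abs(_residual(model, 1, c_mean, x_tot))
    c_max = model.value(x_tot)
    x = np.full(n, x_tot / n)
    payoffs = population.rs * x * (c_max - c_eff)
    survivors = payoffs > _TOL_THRESHOLD
    payoffs = np.where(survivors, payoffs, np.where(payoffs < 0, payoffs, 0.0))
    return EquilibriumState(
        x=x, x_tot=float(x_tot), c_max=float(c_max), payoffs=payoffs,
        survivors=survivors, residual=resid, mode="cooperative", ids=population.ids,
    )


def mean_payoff_decomposition(
    population: Population, state: EquilibriumState
) -> tuple[float, float]:
    """Split the mean payoff into a systematic and a variance contribution.

    For the selfish linear-cost equilibrium of the surviving set,

        mean(E) = (c_max - c_mean)^2 / (-P') + var(c) / (-P'),

    so heterogeneity adds to the average payoff on top of the 1/N^2 term.
    """
    mask = state.survivors
    c = population.effective_costs[mask]
    neg_slope = -population.productivity.slope(state.x_tot)
    systematic = (state.c_max - c.mean()) ** 2 / neg_slope
    variance = c.var() / neg_slope
    return float(systematic), float(variance)


def participation_window(
    N: int, c_mean: float, model: ProductivityModel | None = None
) -> float:
    """Relative width (c_max - c_mean)/c_mean of the profitable cost window.

    For exponential productivity this equals x_tot/(N - x_tot); it diverges
    as c_mean -> 0 at fixed N and vanishes as c_mean -> 1.
    """
    model = model or ProductivityModel.exponential()
    x_tot = solve_total_investment(N, c_mean, model)
    c_max = model.value(x_tot)
    return (c_max - c_mean) / c_mean


def profit_margin(c_i, c_max: float):
    """Relative profit margin M(c) = E/(c x) = (c_max - c)/c at equilibrium."""
    c = np.asarray(c_i, dtype=float)
    out = (c_max - c) / c
    return float(out) if np.isscalar(c_i) else out


def detect_runaway(
    model: ProductivityModel,
    N: int,
    c_mean: float | None = None,
) -> RunawayDiagnosis:
    """Classify the c_mean -> 0 limit (or a finite c_mean) of total investment.

    ``c_mean=None`` requests the explicit vanishing-cost limit.  Power-law
    productivity with N >= beta then has no finite optimum (runaway
    exploitation); N < beta gives the finite limit N/(beta - N).  The
    exponential and finite-commons families never run away: their limits are
    N and N x_max/(N + 1) respectively.
    """
    if c_mean is not None and c_mean > 0:
        try:
            x = solve_total_investment(N, c_mean, model)
        except RunawayError:
            return RunawayDiagnosis(True, math.inf, "no finite root at this c_mean")
        return RunawayDiagnosis(False, x, "finite solution")
    # explicit c_mean -> 0 limit
    if model.family == "exponential":
        return RunawayDiagnosis(False, float(N), "x_tot -> N as costs vanish")
    if model.family == "linear_finite":
        return RunawayDiagnosis(False, N * model.x_max / (N + 1.0),
                                "bounded by the size of the commons")
    if model.family == "power_law":
        if N >= model.beta:
            return RunawayDiagnosis(True, math.inf, f"N >= beta = {model.beta}")
        return RunawayDiagnosis(False, N / (model.beta - N), "finite limit N/(beta - N)")
    raise ValueError("runaway classification needs a named productivity family")
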