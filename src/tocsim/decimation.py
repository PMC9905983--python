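"""Iterated elimination of unprofitable agents ("decimation").

Each round solves the equilibrium for the current survivor set, recomputes the
profitability threshold, and removes every agent that cannot profit there; N
and the mean cost are renormalized and the loop repeats until the survivor set
is stable.  The loop is generic over the equilibrium solver: closed-form
selfish or cooperative states for linear costs, or the curved-cost
self-consistent solver (with a gradient-flow fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import linear, nonlinear
from .models import ConvergenceError, Population

logger = logging.getLogger(__name__)

__all__ = ["DecimationRound", "DecimationTrace", "DecimationResult", "decimate"]

SOLVERS = ("linear_selfish", "cooperative", "nonlinear")


@dataclass(frozen=True)
class DecimationRound:
    iteration: int
    n: int
    c_mean: float
    x_tot: float
    c_max: float
    eliminated: tuple[int, ...]  # agent ids removed this round


@dataclass
class DecimationTrace:
    rounds: list[DecimationRound] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.rounds],
                "n": [r.n for r in self.rounds],
                "c_mean": [r.c_mean for r in self.rounds],
                "x_tot": [r.x_tot for r in self.rounds],
                "c_max": [r.c_max for r in self.rounds],
                "eliminated": [",".join(map(str, r.eliminated)) for r in self.rounds],
            }
        )


@dataclass
class DecimationResult:
    """Survivors, their equilibrium, and the per-round history.

    ``population`` and ``state`` are None for an empty market (every agent
    unprofitable from the start).
    """

    population: Population | None
    state: linear.EquilibriumState | None
    trace: DecimationTrace

    @property
    def empty(self) -> bool:
        return self.population is None

    @property
    def n_survivors(self) -> int:
        return 0 if self.empty else self.population.n


def _linear_round(population, mask, mode):
    sub = population.subset(mask)
    if mode == "cooperative":
        state = linear.cooperative_state(sub)
    else:
        res = linear.solve_total_investment(
            sub.n, float(sub.effective_costs.mean()), sub.productivity, full_output=True
        )
        if not res.profitable:
            return None
        state = linear.allocate_investments(sub, res.x_tot)
    return state


def decimate(
    population: Population,
    solver: str = "linear_selfish",
    one_at_a_time: bool = False,
    init: str = "linear",
    readmit: bool = True,
    max_rounds: int | None = None,
) -> DecimationResult:
    """Run the decimation loop until the survivor set is a fixed point.

    Parameters
    ----------
    solver:
        "linear_selfish" (closed form), "cooperative" (equal shares), or
        "nonlinear" (curved costs; exponential productivity).
    one_at_a_time:
        Remove only the costliest unprofitable agent per round instead of the
        whole batch (sensitivity probe; the printed scenarios give the same
        fixed point either way).
    init:
        Nonlinear initialization policy: "linear" starts from the member set
        and total investment of the linear-cost decimated equilibrium of the
        same population (incumbents at finite investments, so the protected
        region of the entry barrier is reachable); "all" starts with every
        agent in the candidate set.
    readmit:
        Nonlinear only: re-admit eliminated agents whose payoff gradient at
        zero investment is positive at the current state, so the final state
        is entry-stable.  Agents behind an entry barrier are never readmitted
        (their gradient at 0+ is negative).
    """
    if solver not in SOLVERS:
        raise ValueError(f"unknown solver {solver!r}; pick one of {SOLVERS}")
    n0 = population.n
    max_rounds = max_rounds or 2 * n0 + 2
    trace = DecimationTrace()
    mode = "cooperative" if solver == "cooperative" else "selfish"

    if solver == "nonlinear":
        return _decimate_nonlinear(population, trace, init, readmit, one_at_a_time, max_rounds)

    mask = np.ones(n0, dtype=bool)
    state = None
    for it in range(max_rounds):
        if not mask.any():
            trace.rounds.append(DecimationRound(it, 0, float("nan"), 0.0, 1.0, ()))
            return DecimationResult(None, None, trace)
        state = _linear_round(population, mask, mode)
        if state is None:
            # mean cost at/above P(0) = 1: no collective equilibrium yet, but
            # only agents with c >= 1 can never profit; drop those and retry
            hopeless = mask & (population.effective_costs >= 1.0)
            ids = tuple(int(i) for i in population.ids[hopeless])
            trace.rounds.append(
                DecimationRound(it, int(mask.sum()),
                                float(population.costs[mask].mean()), 0.0, 1.0, ids)
            )
            mask &= ~hopeless
            continue
        sub_ids = population.ids[mask]
        doomed = ~state.survivors
        if one_at_a_time and doomed.any():
            worst = np.argmax(np.where(doomed, population.effective_costs[mask], -np.inf))
            keep_one = np.zeros_like(doomed)
            keep_one[worst] = True
            doomed = keep_one
        eliminated = tuple(int(i) for i in sub_ids[doomed])
        trace.rounds.append(
            DecimationRound(it, int(mask.sum()), float(population.costs[mask].mean()),
                            state.x_tot, state.c_max, eliminated)
        )
        if not eliminated:
            sub = population.subset(mask)
            logger.debug("decimation converged after %d rounds: %d survivors", it + 1, sub.n)
            return DecimationResult(sub, state, trace)
        drop = np.isin(population.ids, eliminated)
        mask &= ~drop
    raise ConvergenceError("decimation did not reach a fixed point", trace=trace)


def _decimate_nonlinear(population, trace, init, readmit, one_at_a_time, max_rounds):
    n0 = population.n
    if init == "linear":
        lin_pop = Population(population.agents, population.productivity)
        lin = decimate(lin_pop, solver="linear_selfish")
        if lin.empty:
            mask = np.zeros(n0, dtype=bool)
            x_tot0 = None
        else:
            mask = np.isin(population.ids, lin.population.ids)
            x_tot0 = lin.state.x_tot
    elif init == "all":
        mask = np.ones(n0, dtype=bool)
        x_tot0 = None
    else:
        raise ValueError(f"unknown initialization policy {init!r}")

    c_eff = population.effective_costs
    for it in range(max_rounds):
        if not mask.any():
            trace.rounds.append(DecimationRound(it, 0, float("nan"), 0.0, 1.0, ()))
            return DecimationResult(None, None, trace)
        try:
            state = nonlinear.self_consistent_state(population, members=mask, x_tot0=x_tot0)
        except ConvergenceError:
            # member set straddles a root disappearance: let the flow decide
            x0 = np.where(mask, np.maximum(c_eff.max(), 0.1), 0.0)
            state, _ = nonlinear.gradient_flow(population, x0)
        x_tot0 = state.x_tot
        doomed = mask & ~state.survivors
        if one_at_a_time and doomed.any():
            worst = np.argmax(np.where(doomed, c_eff, -np.inf))
            doomed = np.zeros_like(doomed)
            doomed[worst] = True
        entrants = np.zeros_like(mask)
        if readmit and not doomed.any():
            # entry test at x = 0+: positive gradient means the exit was wrong
            entrants = ~mask & (population.rs * state.c_max - population.costs > 1e-12)
        eliminated = tuple(int(i) for i in population.ids[doomed])
        trace.rounds.append(
            DecimationRound(it, int(mask.sum()), float(population.costs[mask].mean()),
                            state.x_tot, state.c_max, eliminated)
        )
        if not doomed.any() and not entrants.any():
            sub = population.subset(mask)
            sub_state = nonlinear.self_consistent_state(sub, x_tot0=state.x_tot)
            logger.debug("nonlinear decimation converged after %d rounds: %d survivors",
                         it + 1, sub.n)
            return DecimationResult(sub, sub_state, trace)
        mask = (mask & ~doomed) | entrants
    raise ConvergenceError("nonlinear decimation did not reach a fixed point", trace=trace)
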