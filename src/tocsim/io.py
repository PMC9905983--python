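"""Tabular I/O: population CSVs, per-agent result tables, JSON run summaries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decimation import DecimationResult, DecimationTrace
from .linear import EquilibriumState
from .models import AgentSpec, CostModel, Population, ProductivityModel
from .scenarios import ScenarioSpec

__all__ = [
    "PopulationParseError",
    "RunConfig",
    "read_population_csv",
    "write_population_csv",
    "write_results",
]

POPULATION_COLUMNS = ("id", "c", "gamma", "r")


class PopulationParseError(ValueError):
    """A population CSV is malformed; the message names the offending row."""


def write_population_csv(population: Population, path) -> None:
    """Serialize with full (up to 17 significant digit) shortest round-trip
    representations so costs survive a write/read cycle bit-exactly."""
    rows = []
    for a in population.agents:
        rows.append(
            {
                "id": a.id,
                "c": repr(float(a.c)),
                "gamma": "" if a.gamma is None else repr(float(a.gamma)),
                "r": repr(float(a.r)),
            }
        )
    pd.DataFrame(rows, columns=list(POPULATION_COLUMNS)).to_csv(path, index=False)


def read_population_csv(
    path,
    productivity: ProductivityModel | None = None,
    cost: CostModel | None = None,
) -> Population:
    try:
        df = pd.read_csv(path, dtype={"id": "Int64"}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PopulationParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in ("id", "c") if c not in df.columns]
    if missing:
        raise PopulationParseError(f"{path}: missing required column(s) {missing}")
    agents = []
    seen = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            aid = int(row.id)
            c = float(row.c)
        except (TypeError, ValueError) as exc:
            raise PopulationParseError(f"{path}: non-numeric id/cost in row {row_no}") from exc
        if not np.isfinite(c) or c <= 0:
            raise PopulationParseError(f"{path}: row {row_no} has non-positive cost {row.c}")
        if aid in seen:
            raise PopulationParseError(f"{path}: row {row_no} duplicates id {aid}")
        seen.add(aid)
        gamma = getattr(row, "gamma", None)
        gamma = None if gamma is None or (isinstance(gamma, float) and np.isnan(gamma)) else float(gamma)
        r = getattr(row, "r", 1.0)
        r = 1.0 if (isinstance(r, float) and np.isnan(r)) else float(r)
        try:
            agents.append(AgentSpec(aid, c, gamma=gamma, r=r))
        except ValueError as exc:
            raise PopulationParseError(f"{path}: row {row_no}: {exc}") from exc
    if not agents:
        raise PopulationParseError(f"{path}: no agents")
    return Population(
        tuple(agents),
        productivity or ProductivityModel.exponential(),
        cost or CostModel.linear(),
    )


def write_results(
    out_dir,
    population: Population | None = None,
    state: EquilibriumState | None = None,
    trace: DecimationTrace | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
    summary_extra: dict | None = None,
) -> dict:
    """Write per-agent CSV, optional trace/tables, and a JSON run summary.

    Returns the summary dict that was written to ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = dict(summary_extra or {})
    if state is not None:
        frame = state.to_frame(population)
        frame.to_csv(out / "agents.csv", index=False)
        summary.update(
            {
                "x_tot": state.x_tot,
                "c_max": state.c_max,
                "c_node": state.c_node,
                "E_tot": state.E_tot,
                "N": state.n_survivors,
                "mode": state.mode,
                "residual": state.residual,
            }
        )
    if trace is not None:
        trace.to_frame().to_csv(out / "decimation_trace.csv", index=False)
        summary["decimation_rounds"] = len(trace.rounds)
    for name, table in (tables or {}).items():
        table.to_csv(out / f"{name}.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: scenario, models, solver knobs."""

    scenario: ScenarioSpec
    solver: str = "linear_selfish"
    tolerance: float = 1e-12
    step: float = 0.01
    max_steps: int = 2_000_000
    init: str = "linear"
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "scenario": self.scenario.to_dict(),
            "solver": self.solver,
            "tolerance": self.tolerance,
            "step": self.step,
            "max_steps": self.max_steps,
            "init": self.init,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["scenario"] = ScenarioSpec.from_dict(d["scenario"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
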