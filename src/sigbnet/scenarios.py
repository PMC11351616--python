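"""Perturbation scenarios: what controls the free SigB pool?

A :class:`Scenario` multiplies selected driving profiles (whole
trajectories — values *and* derivatives, an "amount" perturbation models
a proportional change in expression over the full window) and selected
rate constants.  The reference grid explores the four levers of the
partner-switching circuit:

* phosphatase supply — RsbU divided by 2, 10, 20;
* anti-anti-sigma abundance — AAS (total RsbV) divided by 2, 3, 5;
* dephosphorylation rate — k7+ divided by 5, 10, 100;
* anti-sigma abundance — AS (total RsbW) halved, doubled, times five;
* the SigB–RsbW2 binding equilibrium — k5+ multiplied by 10 and 100
  while k5- is divided by the same factor.

Summaries report the final and window-mean free SigB, the figures of
merit for sigma-factor availability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SigbnetError
from .model import SPECIES, KineticConstants
from .profiles import DrivingProfiles
from .simulate import (
    SimulationResult,
    SolverOptions,
    initial_state,
    simulate,
)

#: Profile names that may carry an amount multiplier.
AMOUNT_KEYS = ("S", "AS", "AAS", "RsbU", "RsbP")

#: Rate-constant names that may carry a rate multiplier.
RATE_KEYS = (
    "k1p", "k1m", "k2p", "k2m", "k3p", "k4p",
    "k5p", "k5m", "k6p", "k6m", "k7p",
)

#: Solver settings for grid runs: between-scenario differences in final
#: free SigB can be as small as ~1e-8 on the y scale (weak-binding regime
#: at order-1 abundances), so the integration error must sit well below
#: that for trend comparisons to be meaningful.
GRID_SOLVER_OPTIONS = SolverOptions(rtol=1e-10, atol=1e-14)


@dataclass(frozen=True)
class Scenario:
    """One perturbation: multiplicative factors on amounts and rates.

    Unlisted keys default to 1.  AAS amount scaling propagates to the
    initial phosphorylated pool, because initialization reads AAS(0) from
    the already-scaled profile.
    """

    name: str
    amount_multipliers: Mapping[str, float] = field(default_factory=dict)
    rate_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "amount_multipliers", dict(self.amount_multipliers)
        )
        object.__setattr__(self, "rate_multipliers", dict(self.rate_multipliers))
        for key, factor in self.amount_multipliers.items():
            if key not in AMOUNT_KEYS:
                raise ConfigurationError(f"unknown amount multiplier {key!r}")
            if factor <= 0:
                raise ConfigurationError(
                    f"amount multiplier {key} must be > 0, got {factor}"
                )
        for key, factor in self.rate_multipliers.items():
            if key not in RATE_KEYS:
                raise ConfigurationError(f"unknown rate multiplier {key!r}")
            if factor <= 0:
                raise ConfigurationError(
                    f"rate multiplier {key} must be > 0, got {factor}"
                )

    def amount(self, key: str) -> float:
        return self.amount_multipliers.get(key, 1.0)

    def rate(self, key: str) -> float:
        return self.rate_multipliers.get(key, 1.0)

    @property
    def is_identity(self) -> bool:
        return all(v == 1.0 for v in self.amount_multipliers.values()) and all(
            v == 1.0 for v in self.rate_multipliers.values()
        )


def reference_scenario_grid() -> list[Scenario]:
    """The canonical perturbation grid: one shared baseline plus the
    RsbU, AAS, k7+, AS and k5 families (15 scenarios in total)."""
    grid = [Scenario("baseline")]
    for f in (0.5, 0.1, 0.05):
        grid.append(Scenario(f"RsbU_x{f:g}", amount_multipliers={"RsbU": f}))
    for f in (0.5, 1.0 / 3.0, 0.2):
        grid.append(Scenario(f"AAS_x{f:.3g}", amount_multipliers={"AAS": f}))
    for f in (0.2, 0.1, 0.01):
        grid.append(Scenario(f"k7p_x{f:g}", rate_multipliers={"k7p": f}))
    for f in (0.5, 2.0, 5.0):
        grid.append(Scenario(f"AS_x{f:g}", amount_multipliers={"AS": f}))
    for f in (10.0, 100.0):
        grid.append(
            Scenario(
                f"k5_shift_x{f:g}",
                rate_multipliers={"k5p": f, "k5m": 1.0 / f},
            )
        )
    return grid


def apply_scenario(
    driving: DrivingProfiles,
    k: KineticConstants,
    scenario: Scenario,
) -> tuple[DrivingProfiles, KineticConstants]:
    """Return perturbed copies of the forcing and the constants.

    The originals are untouched; profile derivatives are scaled by the
    same factor as the values, so a scaled profile is again a consistent
    (value, derivative) pair.
    """
    replacements = {}
    for key, factor in scenario.amount_multipliers.items():
        if factor != 1.0:
            replacements[key] = getattr(driving, key).scaled(factor)
    new_driving = driving.replace(**replacements) if replacements else driving
    new_k = k.with_multipliers(scenario.rate_multipliers)
    return new_driving, new_k


@dataclass(frozen=True)
class ScenarioSummary:
    """Scalar summary of one scenario run on the simulation grid."""

    name: str
    final_free_sigb: float
    mean_free_sigb: float
    final_values: Mapping[str, float]
    error: str | None = None


@dataclass(frozen=True)
class ScenarioRun:
    scenario: Scenario
    result: SimulationResult | None
    summary: ScenarioSummary


def summarize(scenario: Scenario, result: SimulationResult) -> ScenarioSummary:
    free_sigb = result.species("SigB_free")
    return ScenarioSummary(
        name=scenario.name,
        final_free_sigb=float(free_sigb[-1]),
        mean_free_sigb=float(free_sigb.mean()),
        final_values={
            name: float(result.states[-1, j]) for j, name in enumerate(SPECIES)
        },
    )


def run_grid(
    driving: DrivingProfiles,
    k: KineticConstants,
    grid: Sequence[Scenario] | None = None,
    *,
    vp_fraction: float = 1.0,
    solver_opts: SolverOptions | None = None,
) -> list[ScenarioRun]:
    """Simulate every scenario with identical solver settings.

    Initialization is recomputed per scenario from the *perturbed*
    profiles (so amount changes propagate to the initial state).
    Per-scenario integration failures are collected in the summaries,
    not raised, so one pathological scenario cannot abort the grid.
    """
    scenarios = list(grid) if grid is not None else reference_scenario_grid()
    opts = solver_opts or GRID_SOLVER_OPTIONS
    runs = []
    for scenario in scenarios:
        try:
            pert_driving, pert_k = apply_scenario(driving, k, scenario)
            init = initial_state(pert_driving, vp_fraction)
            result = simulate(pert_driving, pert_k, init, solver_opts=opts)
            runs.append(ScenarioRun(scenario, result, summarize(scenario, result)))
        except SigbnetError as exc:
            runs.append(
                ScenarioRun(
                    scenario,
                    None,
                    ScenarioSummary(
                        name=scenario.name,
                        final_free_sigb=float("nan"),
                        mean_free_sigb=float("nan"),
                        final_values={},
                        error=str(exc),
                    ),
                )
            )
    return runs


def summary_frame(runs: Iterable[ScenarioRun]) -> pd.DataFrame:
    """Flat summary table: one row per scenario with multipliers and the
    free-SigB figures of merit."""
    rows = []
    for run in runs:
        row = {"scenario": run.scenario.name}
        for key in AMOUNT_KEYS:
            row[f"amount_{key}"] = run.scenario.amount(key)
        for key in RATE_KEYS:
            row[f"rate_{key}"] = run.scenario.rate(key)
        row["final_free_sigb"] = run.summary.final_free_sigb
        row["mean_free_sigb"] = run.summary.mean_free_sigb
        row["error"] = run.summary.error or ""
        rows.append(row)
    return pd.DataFrame(rows)
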