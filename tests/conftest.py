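"""Shared fixtures: one synthetic dataset and its derived objects.

The expensive objects (smoothed driving profiles, the baseline run and
the scenario grid) are session-scoped so every test file works on the
same forcing data without re-integrating.
"""

from __future__ import annotations

import numpy as np
import pytest

from sigbnet.model import KineticConstants
from sigbnet.profiles import (
    ExpressionSeries,
    build_driving_profiles,
    profiles_from_table,
    smooth_and_resample,
)
from sigbnet.scenarios import run_grid
from sigbnet.simulate import initial_state, simulate
from sigbnet.synthetic import GeneratorSpec, generate_dataset

#: Seed of the session dataset; every derived expectation in the tests
#: refers to this realization.
DATASET_SEED = 1

TIMES = np.arange(0.0, 140.0, 10.0)


def make_flat_driving(S=2.0, AS=1.5, AAS=1.8, RsbU=1.0, RsbP=0.0):
    """Driving profiles that are constant in time (zero forcing).

    Values are given directly on the y scale; the profiles go through
    the real smoothing pipeline (scale divisor 1), so a constant series
    yields a constant spline with (numerically) zero derivative.
    """
    levels = {"SigB": S, "RsbW": AS, "RsbV": AAS, "RsbU": RsbU, "RsbP": RsbP}
    smoothed = {}
    for protein, level in levels.items():
        series = ExpressionSeries(
            protein, TIMES, np.full((1, TIMES.size), float(level))
        )
        smoothed[protein] = smooth_and_resample(series, scale_divisor=1.0)
    return build_driving_profiles(smoothed)


@pytest.fixture(scope="session")
def synth_spec():
    return GeneratorSpec(seed=DATASET_SEED)


@pytest.fixture(scope="session")
def synth_dataset(synth_spec, tmp_path_factory):
    """(csv path, ground-truth curves) for the session dataset."""
    table, truth = generate_dataset(synth_spec)
    path = tmp_path_factory.mktemp("data") / "synthetic.csv"
    table.to_csv(path, index=False)
    return path, truth


@pytest.fixture(scope="session")
def driving(synth_dataset):
    path, _ = synth_dataset
    return profiles_from_table(path)


@pytest.fixture(scope="session")
def constants():
    return KineticConstants()


@pytest.fixture(scope="session")
def baseline_result(driving, constants):
    """Baseline simulation with default solver settings."""
    init = initial_state(driving, vp_fraction=1.0)
    return simulate(driving, constants, init)


@pytest.fixture(scope="session")
def grid_runs(driving, constants):
    """The full reference perturbation grid, simulated once."""
    return run_grid(driving, constants)


@pytest.fixture(scope="session")
def grid_summaries(grid_runs):
    return {run.scenario.name: run.summary for run in grid_runs}
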