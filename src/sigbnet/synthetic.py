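"""Synthetic proteomic-like replicate time series with known ground truth.

Emulates the statistical structure of the measured dataset the pipeline
is designed for: five proteins (SigB, RsbW, RsbV, RsbU, RsbP) sampled
every 10 minutes over 0–130 min in three biological replicates, smooth
underlying trajectories, multiplicative lognormal replicate noise, and a
near-zero RsbP.  The noise-free generating curves are returned alongside
the table so that smoothing accuracy can be tested against a known
truth.

Default shapes: the three operon partners SigB/RsbW/RsbV rise as
logistics sharing one midpoint (co-expression from a common operon);
RsbU is a moderate level with a mild linear drift; RsbP is a small
constant (two orders of magnitude below the SigB amplitude).  Intensities
are of order 1e4–1e5, so division by the global 3.7e4 scaling yields
order-1 values on the y scale of the kinetic constants.  These are shape
stand-ins with the right magnitudes and noise structure, not fits to any
particular culture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

CURVE_FAMILIES = ("logistic", "linear_plateau", "constant")

DEFAULT_TIMES = tuple(float(t) for t in range(0, 140, 10))


@dataclass(frozen=True)
class CurveSpec:
    """One protein's noise-free generating curve.

    * ``logistic``: baseline + amplitude / (1 + exp(-steepness (t - midpoint)))
    * ``linear_plateau``: baseline + amplitude * clip(t / midpoint, 0, 1)
      (a linear ramp reaching the plateau at ``midpoint`` minutes)
    * ``constant``: baseline

    Units: baseline and amplitude in raw MS intensity, midpoint in
    minutes, steepness per minute.
    """

    family: str
    baseline: float
    amplitude: float = 0.0
    midpoint: float = 60.0
    steepness: float = 0.1

    def __post_init__(self):
        if self.family not in CURVE_FAMILIES:
            raise ConfigurationError(f"unknown curve family {self.family!r}")
        if self.baseline <= 0:
            raise ConfigurationError("baseline intensity must be positive")
        if self.family != "constant" and self.amplitude <= 0:
            raise ConfigurationError(
                f"{self.family} curve needs a positive amplitude"
            )
        if self.family == "linear_plateau" and self.midpoint <= 0:
            raise ConfigurationError("linear_plateau midpoint must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "logistic":
            return self.baseline + self.amplitude / (
                1.0 + np.exp(-self.steepness * (t - self.midpoint))
            )
        if self.family == "linear_plateau":
            return self.baseline + self.amplitude * np.clip(
                t / self.midpoint, 0.0, 1.0
            )
        return self.baseline * np.ones_like(t)


def default_curves() -> dict[str, CurveSpec]:
    """Generating curves with realistic magnitudes for the five proteins."""
    return {
        "SigB": CurveSpec("logistic", 1.5e4, 9.5e4, midpoint=60.0, steepness=0.12),
        "RsbW": CurveSpec("logistic", 1.2e4, 7.4e4, midpoint=60.0, steepness=0.12),
        "RsbV": CurveSpec("logistic", 1.3e4, 8.6e4, midpoint=60.0, steepness=0.12),
        "RsbU": CurveSpec("linear_plateau", 3.2e4, 1.3e4, midpoint=130.0),
        "RsbP": CurveSpec("constant", 3.0e2),
    }


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of one synthetic dataset.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal replicate noise (MS intensities are positive with error
    roughly proportional to signal); the noise is mean-one, so replicate
    averages are unbiased estimates of the generating curve.
    """

    curves: Mapping[str, CurveSpec] = field(default_factory=default_curves)
    noise_cv: float = 0.1
    n_replicates: int = 3
    times: tuple = DEFAULT_TIMES
    seed: int = 12345

    def __post_init__(self):
        object.__setattr__(self, "curves", dict(self.curves))
        object.__setattr__(
            self, "times", tuple(float(t) for t in self.times)
        )
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be nonnegative")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one replicate")
        if len(self.times) < 2 or np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        rsbp = self.curves.get("RsbP")
        sigb = self.curves.get("SigB")
        if rsbp is not None and sigb is not None and sigb.amplitude > 0:
            peak = float(np.max(rsbp(np.asarray(self.times))))
            if peak > 0.01 * sigb.amplitude:
                raise ConfigurationError(
                    "RsbP must stay within 1% of the SigB amplitude "
                    "(near-zero phosphatase regime)"
                )

    def with_seed(self, seed: int) -> "GeneratorSpec":
        return replace(self, seed=int(seed))


def generate_dataset(
    spec: GeneratorSpec | None = None,
) -> tuple[pd.DataFrame, dict[str, Callable]]:
    """Draw one replicate table plus its ground-truth curves.

    Returns ``(table, truth)`` where ``table`` has the exact layout the
    loader expects (``protein_id,time_min,replicate,intensity``) and
    ``truth`` maps each protein to its noise-free generating curve as a
    vectorized callable of time.  Fully reproducible from ``spec.seed``.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times)
    # mean-one lognormal: E[exp(N(-s^2/2, s))] = 1, CV = sqrt(exp(s^2)-1) = cv
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))

    rows = []
    for protein, curve in spec.curves.items():
        truth_values = curve(times)
        for replicate in range(1, spec.n_replicates + 1):
            if sigma > 0:
                noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, times.size))
            else:
                noise = np.ones(times.size)
            intensities = truth_values * noise
            for t, value in zip(times, intensities):
                rows.append((protein, t, replicate, value))
    table = pd.DataFrame(
        rows, columns=["protein_id", "time_min", "replicate", "intensity"]
    )
    if (table["intensity"] <= 0).any():
        raise ConfigurationError("generated intensities must be positive")
    truth = dict(spec.curves)
    return table, truth


def truth_frame(spec: GeneratorSpec, grid_step: float = 1.0) -> pd.DataFrame:
    """Ground-truth curves evaluated on a regular grid, in tidy form."""
    t0, t1 = spec.times[0], spec.times[-1]
    grid = t0 + grid_step * np.arange(int(np.floor((t1 - t0) / grid_step)) + 1)
    frames = []
    for protein, curve in spec.curves.items():
        frames.append(pd.DataFrame({
            "protein_id": protein, "time_min": grid, "intensity": curve(grid),
        }))
    return pd.concat(frames, ignore_index=True)
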