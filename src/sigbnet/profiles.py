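"""Measured expression series and their smoothed driving profiles.

The kinetic model is forced by *measured* total protein abundances rather
than by synthesis/degradation terms: the time courses of SigB (S), RsbW
(AS, the anti-sigma factor) and RsbV (AAS, the anti-anti-sigma factor)
enter the ODE right-hand side through their time derivatives, and the
phosphatases RsbU and RsbP enter through their values.  This module turns
raw replicate mass-spectrometry intensities into those forcing terms:

1. average biological replicates at each time point,
2. fit a cubic least-squares B-spline to the averaged series,
3. rescale intensities by a global divisor so that literature rate
   constants (calibrated on the dimensionless ``y`` scale) apply,
4. evaluate the spline and its *analytic* derivative on a 1-minute grid.

Derivatives always come from the fitted spline, never from finite
differences of the resampled values: the integrator may request the
forcing at arbitrary times between grid points.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_lsq_spline

from .errors import (
    ConfigurationError,
    ExtrapolationError,
    GridAlignmentError,
    InsufficientDataError,
    IntensityParseError,
    ProteinLookupError,
    TableFormatError,
)

#: Global intensity divisor putting measured MS intensities on the
#: dimensionless y scale on which the literature rate constants are valid.
DEFAULT_SCALE_DIVISOR = 3.7e4

#: Default number of evenly spaced interior knots for the smoothing spline.
DEFAULT_KNOT_COUNT = 6

#: Default resampling step in minutes.
DEFAULT_GRID_STEP = 1.0

#: The five measured proteins of the network and their model symbols.
PROTEIN_SYMBOLS = {
    "SigB": "S",
    "RsbW": "AS",
    "RsbV": "AAS",
    "RsbU": "RsbU",
    "RsbP": "RsbP",
}

REQUIRED_COLUMNS = ("protein_id", "time_min", "replicate", "intensity")


@dataclass(frozen=True)
class ExpressionSeries:
    """Raw replicate measurements of one protein over time.

    ``replicate_values`` has shape ``(n_replicates, n_times)``; every
    replicate must provide a value at every time point (incomplete tables
    are rejected at load time).
    """

    protein_id: str
    times: np.ndarray
    replicate_values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.replicate_values, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "replicate_values", values)
        if times.ndim != 1 or times.size == 0:
            raise TableFormatError(f"{self.protein_id}: empty time vector")
        if np.any(np.diff(times) <= 0):
            raise TableFormatError(
                f"{self.protein_id}: times must be strictly increasing"
            )
        if np.any(times < 0):
            raise TableFormatError(f"{self.protein_id}: negative time values")
        if values.shape[1] != times.size:
            raise TableFormatError(
                f"{self.protein_id}: replicate matrix has {values.shape[1]} "
                f"columns for {times.size} time points"
            )
        if not np.all(np.isfinite(values)):
            raise TableFormatError(f"{self.protein_id}: non-finite intensities")
        if np.any(values < 0):
            raise TableFormatError(f"{self.protein_id}: negative intensities")

    @property
    def n_replicates(self) -> int:
        return self.replicate_values.shape[0]


def load_expression_table(
    path: str | os.PathLike,
    proteins: Iterable[str] | None = None,
) -> list[ExpressionSeries]:
    """Read a delimited replicate table into one series per protein.

    The table must have columns ``protein_id,time_min,replicate,intensity``;
    the delimiter is inferred from the extension (``.tsv``/``.tab`` means
    tab, anything else comma).  ``proteins`` restricts and orders the
    result; absent proteins raise :class:`ProteinLookupError` naming them.
    """
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise TableFormatError(
            f"{path}: missing column(s) {', '.join(missing_cols)}"
        )
    intensities = pd.to_numeric(frame["intensity"], errors="coerce")
    bad = intensities.isna() & frame["intensity"].notna()
    if frame["intensity"].isna().any():
        bad |= frame["intensity"].isna()
    if bad.any():
        # +2: header line plus 1-based indexing of the file.
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise IntensityParseError(
            f"{path}: non-numeric intensity at row {row}", row=row
        )
    frame = frame.assign(intensity=intensities)

    available = list(dict.fromkeys(frame["protein_id"]))
    wanted = list(proteins) if proteins is not None else available
    absent = [p for p in wanted if p not in available]
    if absent:
        raise ProteinLookupError(absent)

    out = []
    for protein in wanted:
        sub = frame[frame["protein_id"] == protein]
        pivot = sub.pivot_table(
            index="replicate", columns="time_min", values="intensity",
            aggfunc="first",
        )
        if pivot.isna().any().any():
            raise TableFormatError(
                f"{path}: protein {protein} has missing replicate/time entries"
            )
        times = pivot.columns.to_numpy(dtype=float)
        out.append(
            ExpressionSeries(
                protein_id=protein,
                times=times,
                replicate_values=pivot.to_numpy(dtype=float),
            )
        )
    return out


def average_replicates(series: ExpressionSeries) -> ExpressionSeries:
    """Arithmetic mean over replicates at each time point."""
    return ExpressionSeries(
        protein_id=series.protein_id,
        times=series.times,
        replicate_values=series.replicate_values.mean(axis=0, keepdims=True),
    )


@dataclass(frozen=True)
class SmoothedProfile:
    """Smoothed, rescaled trajectory of one protein with its derivative.

    ``values`` are the fitted spline on the 1-minute grid, clipped at zero
    (intensities are physical amounts); ``derivatives`` are the analytic
    spline derivative, left unclipped so that the fundamental-theorem
    identity between derivative and values is preserved.  Continuous
    evaluation between grid points goes through :meth:`value` and
    :meth:`derivative`, which query the underlying spline directly.
    """

    protein_id: str
    grid: np.ndarray
    values: np.ndarray
    derivatives: np.ndarray
    scale_divisor: float = DEFAULT_SCALE_DIVISOR
    spline: BSpline = field(repr=False, default=None)
    _dspline: BSpline = field(repr=False, default=None)

    @property
    def t_min(self) -> float:
        return float(self.grid[0])

    @property
    def t_max(self) -> float:
        return float(self.grid[-1])

    def _check_window(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_min - 1e-9) or np.any(t > self.t_max + 1e-9):
            raise ExtrapolationError(
                f"{self.protein_id}: requested t outside the measured "
                f"window [{self.t_min}, {self.t_max}] min"
            )
        return t

    def value(self, t):
        """Spline value at ``t`` (clipped at zero), scalar in/scalar out."""
        t = self._check_window(t)
        return np.clip(self.spline(t), 0.0, None)

    def derivative(self, t):
        """Analytic spline derivative at ``t``."""
        t = self._check_window(t)
        return self._dspline(t)

    def scaled(self, factor: float) -> "SmoothedProfile":
        """Rescale the whole trajectory (values and derivatives) by ``factor``."""
        if factor <= 0:
            raise ConfigurationError("scale factor must be positive")
        spline = BSpline(self.spline.t, self.spline.c * factor, self.spline.k)
        return SmoothedProfile(
            protein_id=self.protein_id,
            grid=self.grid,
            values=self.values * factor,
            derivatives=self.derivatives * factor,
            scale_divisor=self.scale_divisor,
            spline=spline,
            _dspline=spline.derivative(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.grid,
                "value": self.values,
                "derivative": self.derivatives,
            }
        )


def smooth_and_resample(
    series: ExpressionSeries,
    scale_divisor: float = DEFAULT_SCALE_DIVISOR,
    knot_count: int = DEFAULT_KNOT_COUNT,
    grid_step: float = DEFAULT_GRID_STEP,
) -> SmoothedProfile:
    """Fit a cubic least-squares B-spline and resample on a regular grid.

    Replicates are averaged first and intensities divided by
    ``scale_divisor``.  The spline uses ``knot_count`` evenly spaced
    interior knots over the measured window; derivatives are the analytic
    derivative of the fit.  Negative spline excursions are clipped to zero
    in ``values`` only.
    """
    if scale_divisor <= 0:
        raise ConfigurationError("scale_divisor must be positive")
    if grid_step <= 0:
        raise ConfigurationError("grid_step must be positive")
    if knot_count < 0:
        raise ConfigurationError("knot_count must be nonnegative")

    averaged = average_replicates(series)
    x = averaged.times
    if x.size < 4:
        raise InsufficientDataError(
            f"{series.protein_id}: cubic spline needs >= 4 time points, "
            f"got {x.size}"
        )
    y = averaged.replicate_values[0] / scale_divisor

    n_coef = knot_count + 4
    if n_coef > x.size:
        raise ConfigurationError(
            f"{series.protein_id}: {knot_count} interior knots need at "
            f"least {n_coef} data points, got {x.size}"
        )
    interior = np.linspace(x[0], x[-1], knot_count + 2)[1:-1]
    knots = np.concatenate([[x[0]] * 4, interior, [x[-1]] * 4])
    try:
        spline = make_lsq_spline(x, y, knots, k=3)
    except Exception as exc:  # singular design etc.
        raise ConfigurationError(
            f"{series.protein_id}: spline fit failed for knot_count="
            f"{knot_count}: {exc}"
        ) from exc
    dspline = spline.derivative()

    n_steps = int(np.floor((x[-1] - x[0]) / grid_step + 1e-9))
    grid = x[0] + grid_step * np.arange(n_steps + 1)
    values = np.clip(spline(grid), 0.0, None)
    derivatives = dspline(grid)
    return SmoothedProfile(
        protein_id=series.protein_id,
        grid=grid,
        values=values,
        derivatives=derivatives,
        scale_divisor=scale_divisor,
        spline=spline,
        _dspline=dspline,
    )


@dataclass(frozen=True)
class DrivingProfiles:
    """The five smoothed trajectories that force the kinetic model.

    ``S``, ``AS`` and ``AAS`` are the measured totals of SigB, RsbW and
    RsbV (free plus complex-bound); their derivatives drive the mass
    balances.  ``RsbU`` and ``RsbP`` are the phosphatase abundances and
    enter the dephosphorylation flux through their values only.
    """

    S: SmoothedProfile
    AS: SmoothedProfile
    AAS: SmoothedProfile
    RsbU: SmoothedProfile
    RsbP: SmoothedProfile

    def __post_init__(self):
        ref = self.S.grid
        for name in ("AS", "AAS", "RsbU", "RsbP"):
            grid = getattr(self, name).grid
            if grid.shape != ref.shape or not np.allclose(grid, ref):
                raise GridAlignmentError(
                    f"profile {name} is not on the same grid as S"
                )

    @property
    def grid(self) -> np.ndarray:
        return self.S.grid

    @property
    def t_min(self) -> float:
        return self.S.t_min

    @property
    def t_max(self) -> float:
        return self.S.t_max

    def replace(self, **profiles: SmoothedProfile) -> "DrivingProfiles":
        fields = {n: getattr(self, n) for n in ("S", "AS", "AAS", "RsbU", "RsbP")}
        for name, prof in profiles.items():
            if name not in fields:
                raise ConfigurationError(f"unknown profile name {name!r}")
            fields[name] = prof
        return DrivingProfiles(**fields)


def build_driving_profiles(
    profile_set: Mapping[str, SmoothedProfile],
) -> DrivingProfiles:
    """Map protein names to model symbols and assemble the forcing set.

    ``profile_set`` is keyed by protein name (SigB, RsbW, RsbV, RsbU,
    RsbP).  All five must be present and share one grid.
    """
    absent = [p for p in PROTEIN_SYMBOLS if p not in profile_set]
    if absent:
        raise ProteinLookupError(absent)
    return DrivingProfiles(
        S=profile_set["SigB"],
        AS=profile_set["RsbW"],
        AAS=profile_set["RsbV"],
        RsbU=profile_set["RsbU"],
        RsbP=profile_set["RsbP"],
    )


def profiles_from_table(
    path: str | os.PathLike,
    scale_divisor: float = DEFAULT_SCALE_DIVISOR,
    knot_count: int = DEFAULT_KNOT_COUNT,
    grid_step: float = DEFAULT_GRID_STEP,
) -> DrivingProfiles:
    """Convenience pipeline: table file -> DrivingProfiles."""
    series = load_expression_table(path, PROTEIN_SYMBOLS)
    smoothed = {
        s.protein_id: smooth_and_resample(s, scale_divisor, knot_count, grid_step)
        for s in series
    }
    return build_driving_profiles(smoothed)
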