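"""Mass-action core of the SigB partner-switching network.

Species (all on the dimensionless y intensity scale):

* ``SigB_free`` — free sigma factor, the quantity of biological interest;
* ``W2_free``   — free anti-sigma factor dimer RsbW2;
* ``V_free``    — free dephosphorylated anti-anti-sigma factor RsbV;
* ``W2SigB``    — sequestration complex RsbW2·SigB;
* ``W2V``, ``W2V2`` — RsbW2 bound by one / two RsbV;
* ``VP``        — phosphorylated RsbV.

Reactions: RsbW2 binds RsbV (k1±) and a second RsbV (k2±); RsbW2
phosphorylates free RsbV (k3+) and the inner RsbV of W2V2 (k4+); RsbW2
binds SigB (k5±); RsbV displaces SigB from W2SigB (k6±); the phosphatases
RsbU and RsbP dephosphorylate VP with a shared rate constant (k7+).

The measured totals close the system: S = SigB_free + W2SigB,
AS = 2(W2_free + W2V + W2V2 + W2SigB), AAS = V_free + W2V + 2 W2V2 + VP.
Differentiating these balances supplies the free-form equations, so
synthesis and degradation never appear explicitly — they are absorbed in
the measured dS/dt, dAS/dt, dAAS/dt forcing.  RsbU and RsbP are measured
driving profiles, not dynamic states.  Free phosphate is implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping, Tuple

import numpy as np

from .errors import ConfigurationError
from .profiles import DrivingProfiles

#: Column/species names used in tidy trajectory output, in state order.
SPECIES = ("SigB_free", "W2_free", "V_free", "W2SigB", "W2V", "W2V2", "VP")

#: Names of the three model totals in tidy output.
TOTALS = ("S_total_model", "AS_total_model", "AAS_total_model")


@dataclass(frozen=True)
class KineticConstants:
    """The eleven rate constants of the partner-switching reactions.

    Association/displacement constants (k1p, k2p, k5p, k6p, k6m, k7p and
    the kinase k3p, which multiplies two species) are per-y per-minute;
    dissociation constants (k1m, k2m, k5m) and the intramolecular kinase
    step k4p are per-minute.  Defaults are the literature values
    calibrated on the y scale (intensity / 3.7e4).
    """

    k1p: float = 6e-5
    k1m: float = 0.3
    k2p: float = 6e-5
    k2m: float = 0.3
    k3p: float = 0.6
    k4p: float = 0.6
    k5p: float = 6e-5
    k5m: float = 0.3
    k6p: float = 3e-4
    k6m: float = 3e-4
    k7p: float = 3.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(
                    f"rate constant {f.name} must be finite and >= 0, got {v}"
                )

    _CONFIG_NAMES = {
        "k1_plus": "k1p", "k1_minus": "k1m",
        "k2_plus": "k2p", "k2_minus": "k2m",
        "k3_plus": "k3p", "k4_plus": "k4p",
        "k5_plus": "k5p", "k5_minus": "k5m",
        "k6_plus": "k6p", "k6_minus": "k6m",
        "k7_plus": "k7p",
    }

    @classmethod
    def from_config(cls, kinetics: Mapping[str, float]) -> "KineticConstants":
        """Build from a config mapping with k1_plus ... k7_plus keys."""
        kwargs = {}
        for key, value in kinetics.items():
            if key not in cls._CONFIG_NAMES:
                raise ConfigurationError(f"unknown kinetic constant {key!r}")
            kwargs[cls._CONFIG_NAMES[key]] = float(value)
        return cls(**kwargs)

    def with_multipliers(self, multipliers: Mapping[str, float]) -> "KineticConstants":
        """Return a copy with selected constants multiplied by a factor."""
        valid = {f.name for f in fields(self)}
        changes = {}
        for key, factor in multipliers.items():
            if key not in valid:
                raise ConfigurationError(f"unknown rate multiplier key {key!r}")
            if factor <= 0:
                raise ConfigurationError(f"rate multiplier {key} must be > 0")
            changes[key] = getattr(self, key) * factor
        return replace(self, **changes)


@dataclass(frozen=True)
class NetworkState:
    """One point of the seven-species dynamic state (y units)."""

    sigb_free: float = 0.0
    w2_free: float = 0.0
    v_free: float = 0.0
    w2_sigb: float = 0.0
    w2v: float = 0.0
    w2v2: float = 0.0
    vp: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sigb_free, self.w2_free, self.v_free,
             self.w2_sigb, self.w2v, self.w2v2, self.vp]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NetworkState":
        y = np.asarray(y, dtype=float)
        return cls(*y.tolist())


def rhs_array(
    t: float,
    y: np.ndarray,
    driving: DrivingProfiles,
    k: KineticConstants,
) -> np.ndarray:
    """Time derivatives of the seven species as a flat array.

    Complex and VP dynamics follow mass action; the free forms follow the
    differentiated mass balances, so the model totals track the measured
    totals by construction.  Raises if the state is non-finite or ``t``
    lies outside the measured window (profile evaluation refuses to
    extrapolate).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state at t={t}: {y}")
    sigb_f, w2_f, v_f, w2sigb, w2v, w2v2, vp = y

    rsbu = float(driving.RsbU.value(t))
    rsbp = float(driving.RsbP.value(t))
    dS = float(driving.S.derivative(t))
    dAS = float(driving.AS.derivative(t))
    dAAS = float(driving.AAS.derivative(t))

    d_w2sigb = (
        k.k5p * w2_f * sigb_f - k.k5m * w2sigb
        - k.k6p * w2sigb * v_f + k.k6m * w2v * sigb_f
    )
    d_w2v = (
        k.k2m * w2v2 - k.k2p * w2v * v_f + k.k4p * w2v2
        + k.k1p * w2_f * v_f - k.k1m * w2v
        + k.k6p * w2sigb * v_f - k.k6m * w2v * sigb_f
    )
    d_w2v2 = k.k2p * w2v * v_f - k.k2m * w2v2 - k.k4p * w2v2
    d_vp = (
        k.k3p * w2_f * v_f + k.k4p * w2v2
        - k.k7p * vp * rsbp - k.k7p * vp * rsbu
    )
    d_sigb_f = dS - d_w2sigb
    d_w2_f = 0.5 * dAS - d_w2v - d_w2v2 - d_w2sigb
    d_v_f = dAAS - d_w2v - 2.0 * d_w2v2 - d_vp

    return np.array([d_sigb_f, d_w2_f, d_v_f, d_w2sigb, d_w2v, d_w2v2, d_vp])


def rhs(
    t: float,
    state: NetworkState,
    driving: DrivingProfiles,
    k: KineticConstants,
) -> NetworkState:
    """Typed wrapper around :func:`rhs_array`."""
    return NetworkState.from_array(rhs_array(t, state.as_array(), driving, k))


def totals_from_array(y: np.ndarray) -> np.ndarray:
    """Model totals (S, AS, AAS) for a state array or trajectory.

    Accepts shape ``(7,)`` or ``(n, 7)``; returns shape ``(3,)`` or
    ``(n, 3)``.
    """
    y = np.asarray(y, dtype=float)
    s = y[..., 0] + y[..., 3]
    as_ = 2.0 * (y[..., 1] + y[..., 4] + y[..., 5] + y[..., 3])
    aas = y[..., 2] + y[..., 4] + 2.0 * y[..., 5] + y[..., 6]
    return np.stack([s, as_, aas], axis=-1)


def totals_from_state(state: NetworkState) -> Tuple[float, float, float]:
    """Model totals (S, AS, AAS) implied by one state."""
    t = totals_from_array(state.as_array())
    return float(t[0]), float(t[1]), float(t[2])


def algebraic_free_forms(
    complexes: Tuple[float, float, float, float],
    driving: DrivingProfiles,
    t: float,
) -> Tuple[float, float, float]:
    """Free forms implied by the mass balances given the bound species.

    ``complexes`` is ``(W2SigB, W2V, W2V2, VP)``.  May return negative
    values; the caller interprets those as an infeasible state.
    """
    w2sigb, w2v, w2v2, vp = complexes
    sigb_f = float(driving.S.value(t)) - w2sigb
    w2_f = float(driving.AS.value(t)) / 2.0 - w2v - w2v2 - w2sigb
    v_f = float(driving.AAS.value(t)) - w2v - 2.0 * w2v2 - vp
    return sigb_f, w2_f, v_f
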