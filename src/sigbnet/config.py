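"""Structured YAML configuration.

One file holds everything a run needs: the intensity scaling divisor,
smoothing settings, the kinetic constants (keys ``k1_plus`` ...
``k7_plus`` named after the published table rows), solver settings, and
optional custom scenario definitions.  Unknown keys are rejected so that
typos do not silently fall back to defaults.
"""

from __future__ import annotations

import copy
import os
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .model import KineticConstants
from .scenarios import Scenario
from .simulate import SolverOptions

DEFAULT_CONFIG: dict[str, Any] = {
    "scale_divisor": 3.7e4,
    "knot_count": 6,
    "grid_step_min": 1.0,
    "kinetics": {
        "k1_plus": 6e-5, "k1_minus": 0.3,
        "k2_plus": 6e-5, "k2_minus": 0.3,
        "k3_plus": 0.6, "k4_plus": 0.6,
        "k5_plus": 6e-5, "k5_minus": 0.3,
        "k6_plus": 3e-4, "k6_minus": 3e-4,
        "k7_plus": 3.0,
    },
    "solver": {
        "method": "LSODA",
        "rtol": 1e-6,
        "atol": 1e-12,
        "vp_fraction": 1.0,
    },
    "scenarios": [],
}


def default_config() -> dict[str, Any]:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | os.PathLike | None) -> dict[str, Any]:
    """Read a YAML config and merge it over the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    for key, value in user.items():
        if key not in cfg:
            raise ConfigurationError(f"{path}: unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"{path}: {key} must be a mapping")
            unknown = set(value) - set(cfg[key])
            if unknown:
                raise ConfigurationError(
                    f"{path}: unknown {key} key(s) {sorted(unknown)}"
                )
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def kinetic_constants_from_config(cfg: Mapping[str, Any]) -> KineticConstants:
    return KineticConstants.from_config(cfg["kinetics"])


def solver_options_from_config(cfg: Mapping[str, Any]) -> SolverOptions:
    solver = cfg["solver"]
    return SolverOptions(
        method=solver["method"],
        rtol=float(solver["rtol"]),
        atol=float(solver["atol"]),
    )


def scenarios_from_config(cfg: Mapping[str, Any]) -> list[Scenario]:
    """Custom scenario grid from config (empty list if none defined)."""
    out = []
    for entry in cfg["scenarios"]:
        if not isinstance(entry, dict) or "name" not in entry:
            raise ConfigurationError(
                "each scenario needs at least a 'name' key"
            )
        out.append(
            Scenario(
                name=str(entry["name"]),
                amount_multipliers=entry.get("amount_multipliers", {}),
                rate_multipliers=entry.get("rate_multipliers", {}),
            )
        )
    return out
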