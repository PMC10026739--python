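"""Model parameter handling.

All physiological, biophysical and numerical constants used by the
thermoregulatory model live in one JSON document.  The copy shipped with the
package (``coweda/data/default_params.json``) holds the documented defaults;
every value can be overridden by loading a user file with :func:`load_params`.

The parameter file is deliberately flat and data-driven: distribution factors,
tissue constants and controller gains are stored as data, not code, so an
alternative parameterisation (e.g. a different anthropometric atlas) can be
swapped in without touching the model source.
"""

from __future__ import annotations

import copy
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "SEGMENTS",
    "COMPARTMENTS",
    "N_SEGMENTS",
    "N_COMPARTMENTS",
    "CLO_TO_M2KW",
    "ModelParams",
    "load_params",
    "default_params",
    "ValidationError",
    "ConfigurationError",
]

#: Canonical segment order used for every per-segment array in the package.
SEGMENTS = ("head", "trunk", "arms", "legs", "hands", "feet")
#: Concentric compartment order, innermost first.
COMPARTMENTS = ("core", "muscle", "fat", "skin")

N_SEGMENTS = len(SEGMENTS)
N_COMPARTMENTS = len(COMPARTMENTS)

#: 1 clo of clothing insulation expressed in SI units (m²·K/W).
CLO_TO_M2KW = 0.155


class ValidationError(ValueError):
    """A physical quantity or input record is outside its allowed range."""


class ConfigurationError(ValueError):
    """A parameter set or configuration file is internally inconsistent."""


def _seg_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_SEGMENTS,):
        raise ConfigurationError(
            f"{name}: expected {N_SEGMENTS} per-segment values, got shape {arr.shape}"
        )
    return arr


def _check_sums_to_one(arr: np.ndarray, name: str) -> None:
    total = float(arr.sum())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1.0 (got {total!r})")


class ModelParams:
    """Validated container for the full model parameter set.

    The raw dictionary is kept (``.raw``) so unknown sections survive a
    round-trip, but the sections the model consumes are exposed as numpy
    arrays in the canonical segment/compartment order.
    """

    def __init__(self, data: Mapping[str, Any]):
        self.raw = copy.deepcopy(dict(data))
        d = self.raw

        dist = d["distribution"]
        self.area_fraction = _seg_array(dist["area"], "distribution.area")
        self.volume_fraction = _seg_array(dist["volume"], "distribution.volume")
        self.basal_met_fraction = _seg_array(dist["basal_met"], "distribution.basal_met")
        self.basal_skin_flow_fraction = _seg_array(
            dist["basal_skin_flow"], "distribution.basal_skin_flow"
        )
        for arr, name in [
            (self.area_fraction, "distribution.area"),
            (self.volume_fraction, "distribution.volume"),
            (self.basal_met_fraction, "distribution.basal_met"),
            (self.basal_skin_flow_fraction, "distribution.basal_skin_flow"),
        ]:
            if np.any(arr < 0):
                raise ConfigurationError(f"{name} contains negative factors")
            _check_sums_to_one(arr, name)

        geo = d["geometry"]
        self.skin_thickness = _seg_array(geo["skin_thickness_m"], "geometry.skin_thickness_m")
        self.muscle_interior_fraction = _seg_array(
            geo["muscle_interior_fraction"], "geometry.muscle_interior_fraction"
        )
        self.min_shell_thickness = float(geo["min_shell_thickness_m"])

        tis = d["tissue"]
        cond = tis["conductivity"]
        self.conductivity = np.array(
            [cond[c] for c in COMPARTMENTS], dtype=float
        )  # W/(m·K), per compartment
        self.specific_heat = float(tis["specific_heat"])
        self.fat_density = float(tis["fat_density"])
        self.lean_density = float(tis["lean_density"])
        self.blood_specific_heat = float(tis["blood_specific_heat"])
        self.blood_density = float(tis["blood_density"])
        self.blood_volume_per_kg = float(tis["blood_volume_L_per_kg"])
        self.latent_heat = float(tis["latent_heat_vaporisation"])  # J/g

        bas = d["basal"]
        self.basal_met_per_m2 = float(bas["met_W_per_m2"])
        self.basal_skin_flow_total = float(bas["skin_blood_flow_total_L_h"])
        self.perfusion_per_watt = float(bas["perfusion_W_per_K_per_W"])
        split = bas["met_node_split"]
        self.met_node_split = np.array([split[c] for c in COMPARTMENTS], dtype=float)
        _check_sums_to_one(self.met_node_split, "basal.met_node_split")

        self.controller = dict(d["controller"])
        _check_sums_to_one(
            _seg_array(self.controller["skin_weights"], "controller.skin_weights"),
            "controller.skin_weights",
        )
        _check_sums_to_one(
            _seg_array(self.controller["core_weights"], "controller.core_weights"),
            "controller.core_weights",
        )

        self.boundary = dict(d["boundary"])
        self.respiration = dict(d["respiration"])
        self.activity_levels = dict(d["activity"])
        rates = [self.activity_levels[k] for k in ("rest", "light", "moderate", "heavy")]
        if not all(a < b for a, b in zip(rates, rates[1:])):
            raise ConfigurationError("activity levels must map to strictly increasing rates")
        self.activity_muscle_split = _seg_array(
            d["activity_muscle_split"], "activity_muscle_split"
        )
        _check_sums_to_one(self.activity_muscle_split, "activity_muscle_split")

        self.thresholds = dict(d["thresholds"])
        init = d["initial_state"]
        self.initial_temperatures = np.asarray(init["temperatures"], dtype=float)
        if self.initial_temperatures.shape != (N_SEGMENTS, N_COMPARTMENTS):
            raise ConfigurationError(
                "initial_state.temperatures must be a 6x4 matrix "
                f"(got shape {self.initial_temperatures.shape})"
            )
        self.initial_blood = float(init["blood"])
        self.wct_bands = dict(d["wct_bands"])
        self.simulation = dict(d["simulation"])

    # -- convenience -------------------------------------------------------

    def basal_met(self, surface_area: float) -> float:
        """Basal metabolic heat production (W) for a given body surface area."""
        return self.basal_met_per_m2 * surface_area

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ModelParams":
        """Return a new parameter set with (nested) overrides merged in."""
        merged = copy.deepcopy(self.raw)
        _deep_update(merged, overrides)
        return ModelParams(merged)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.raw, indent=2) + "\n")


def _deep_update(base: dict, upd: Mapping[str, Any]) -> None:
    for key, value in upd.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def default_params() -> ModelParams:
    """The parameter set shipped with the package."""
    text = resources.files("coweda.data").joinpath("default_params.json").read_text()
    return ModelParams(json.loads(text))


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load model parameters from ``path`` (JSON), or the shipped defaults.

    A user file only needs the sections it overrides; missing sections are
    filled from the defaults.
    """
    base = default_params()
    if path is None:
        return base
    data = json.loads(Path(path).read_text())
    return base.with_overrides(data)
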