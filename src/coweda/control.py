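"""Thermoregulatory controller: shivering, vasomotor tone and sweating.

The controller reduces the 6x4 temperature field to two scalar error
signals — a weighted core error and a weighted mean-skin error relative to
their setpoints (negative = cold) — and maps them to effector outputs with
bilinear (error, error and product) response curves, each hard-clamped at
its physiological limit:

- shivering heat production, W, distributed over muscle by mass;
- skin blood flow per segment, L/h, constricted towards a per-segment floor
  in the cold (extremities carry the strongest constriction and the lowest
  floor) and dilated towards a ceiling in the warmth;
- sweat rate, g/min, converted to per-segment skin wettedness with an
  insensible-diffusion floor of 0.06.

Static errors only; no receptor rate terms, acclimatisation or shivering
fatigue are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import (
    N_SEGMENTS,
    ConfigurationError,
    ModelParams,
    ValidationError,
    default_params,
)

__all__ = [
    "ControllerParams",
    "EffectorOutputs",
    "thermal_signal",
    "shivering",
    "vasomotor",
    "sweating",
    "wettedness_from_sweat",
    "effector_outputs",
]

_REFERENCE_BASAL_MET = 45.8 * 1.936  # W, reference adult used when no body is given


@dataclass
class ControllerParams:
    """Setpoints, receptor weights, gains and limits of the controller."""

    setpoint_core: float
    setpoint_skin: float
    skin_weights: np.ndarray
    core_weights: np.ndarray
    shiver_gain_core: float
    shiver_gain_skin: float
    shiver_gain_product: float
    shiver_skin_saturation: float
    shiver_peak_core: float
    shiver_fail_core: float
    max_shivering: float
    constrict_gain_core: float
    constrict_gain_skin: float
    constrict_segment_factor: np.ndarray
    dilate_gain: float
    dilate_core_weight: float
    basal_skin_flow: np.ndarray
    min_skin_flow: np.ndarray
    max_skin_flow: np.ndarray
    sweat_gain_skin: float
    sweat_gain_product: float
    max_sweat: float
    wettedness_floor: float

    def __post_init__(self):
        for name in (
            "skin_weights",
            "core_weights",
            "constrict_segment_factor",
            "basal_skin_flow",
            "min_skin_flow",
            "max_skin_flow",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape[-1] != N_SEGMENTS:
                raise ConfigurationError(f"{name} must have {N_SEGMENTS} per-segment values")
        for weights, name in ((self.skin_weights, "skin_weights"), (self.core_weights, "core_weights")):
            if abs(float(weights.sum()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1.0")
        if self.max_shivering <= 0 or self.max_sweat <= 0:
            raise ConfigurationError("effector limits must be positive")
        if np.any(self.min_skin_flow <= 0) or np.any(self.max_skin_flow <= self.min_skin_flow):
            raise ConfigurationError("skin blood flow limits must satisfy 0 < min < max")

    @classmethod
    def from_params(
        cls, params: ModelParams | None = None, basal_met: float | None = None
    ) -> "ControllerParams":
        """Build from a model parameter file.

        ``basal_met`` (W) sets the shivering cap via the configured multiple
        of the basal metabolic rate; defaults to the reference adult's.
        """
        p = params or default_params()
        c = p.controller
        basal = _REFERENCE_BASAL_MET if basal_met is None else float(basal_met)
        return cls(
            setpoint_core=c["setpoint_core"],
            setpoint_skin=c["setpoint_skin"],
            skin_weights=np.asarray(c["skin_weights"], dtype=float),
            core_weights=np.asarray(c["core_weights"], dtype=float),
            shiver_gain_core=c["shiver_gain_core"],
            shiver_gain_skin=c["shiver_gain_skin"],
            shiver_gain_product=c["shiver_gain_product"],
            shiver_skin_saturation=c["shiver_skin_saturation_C"],
            shiver_peak_core=c["shiver_peak_core_C"],
            shiver_fail_core=c["shiver_fail_core_C"],
            max_shivering=c["shiver_cap_multiple_basal"] * basal,
            constrict_gain_core=c["constrict_gain_core"],
            constrict_gain_skin=c["constrict_gain_skin"],
            constrict_segment_factor=np.asarray(c["constrict_segment_factor"], dtype=float),
            dilate_gain=c["dilate_gain_L_h_per_K"],
            dilate_core_weight=c["dilate_core_weight"],
            basal_skin_flow=p.basal_skin_flow_total * p.basal_skin_flow_fraction,
            min_skin_flow=np.asarray(c["min_skin_flow_L_h"], dtype=float),
            max_skin_flow=np.asarray(c["max_skin_flow_L_h"], dtype=float),
            sweat_gain_skin=c["sweat_gain_skin"],
            sweat_gain_product=c["sweat_gain_product"],
            max_sweat=c["max_sweat_g_min"],
            wettedness_floor=c["wettedness_floor"],
        )


@dataclass
class EffectorOutputs:
    """Controller outputs for one state evaluation."""

    shivering_heat: float
    skin_blood_flow: np.ndarray  # (6,), L/h
    sweat_rate: float  # g/min, whole body
    wettedness: np.ndarray  # (6,)

    @classmethod
    def zero(cls) -> "EffectorOutputs":
        """All effectors off, including the insensible-diffusion wettedness.

        Useful for exercising the pure passive system.
        """
        return cls(0.0, np.zeros(N_SEGMENTS), 0.0, np.zeros(N_SEGMENTS))


# ---------------------------------------------------------------------------
# Signals and effectors (array-friendly: scalars in -> scalars out)
# ---------------------------------------------------------------------------


def thermal_signal(state, params: ControllerParams):
    """Weighted core and mean-skin errors, °C; negative = cold.

    ``state`` may be a :class:`~coweda.body.BodyState` or a batched (B,6,4)
    temperature array.
    """
    T = np.asarray(getattr(state, "temperatures", state), dtype=float)
    core = T[..., 0] @ params.core_weights - params.setpoint_core
    skin = T[..., 3] @ params.skin_weights - params.setpoint_skin
    return core, skin


def shivering(core_error, skin_error, params: ControllerParams):
    """Shivering heat production, W.

    Bilinear in the cold errors (core, skin and their product), with the
    skin cold signal saturating at ``shiver_skin_saturation`` °C below the
    setpoint (receptor/recruitment ceiling) and the total hard-capped at the
    physiological maximum.
    """
    coldc = np.maximum(0.0, -np.asarray(core_error, dtype=float))
    colds = np.maximum(0.0, -np.asarray(skin_error, dtype=float))
    colds = np.minimum(colds, params.shiver_skin_saturation)
    q = (
        params.shiver_gain_core * coldc
        + params.shiver_gain_skin * colds
        + params.shiver_gain_product * coldc * colds
    )
    core_temp = params.setpoint_core + np.asarray(core_error, dtype=float)
    efficacy = np.clip(
        (core_temp - params.shiver_fail_core)
        / (params.shiver_peak_core - params.shiver_fail_core),
        0.0,
        1.0,
    )
    return efficacy * np.minimum(q, params.max_shivering)


def vasomotor(core_error, skin_error, params: ControllerParams, basal_flow=None,
              min_flow=None, max_flow=None):
    """Per-segment skin blood flow, L/h.

    Basal flow is divided by a constriction term driven by the cold errors
    (scaled per segment, strongest at the extremities) and augmented by a
    dilation term driven by the warm errors; the result is clamped to the
    per-segment [min, max] range.  Broadcasts over a leading batch axis.
    """
    coldc = np.maximum(0.0, -np.asarray(core_error, dtype=float))[..., None]
    colds = np.maximum(0.0, -np.asarray(skin_error, dtype=float))[..., None]
    warmc = np.maximum(0.0, np.asarray(core_error, dtype=float))[..., None]
    warms = np.maximum(0.0, np.asarray(skin_error, dtype=float))[..., None]
    basal = params.basal_skin_flow if basal_flow is None else np.asarray(basal_flow)
    lo = params.min_skin_flow if min_flow is None else np.asarray(min_flow)
    hi = params.max_skin_flow if max_flow is None else np.asarray(max_flow)
    constrict = 1.0 + params.constrict_segment_factor * (
        params.constrict_gain_core * coldc + params.constrict_gain_skin * colds
    )
    share = basal / basal.sum(axis=-1, keepdims=True)
    dilate = share * params.dilate_gain * (params.dilate_core_weight * warmc + warms)
    return np.clip(basal / constrict + dilate, lo, hi)


def sweating(core_error, skin_error, params: ControllerParams):
    """Whole-body sweat rate, g/min.

    Requires a warm skin signal (so sweating shuts off whenever the skin is
    below its setpoint, keeping it mutually exclusive with shivering during
    cold exposure) and grows bilinearly with a warm core; capped at the
    maximum sweat rate.
    """
    warmc = np.maximum(0.0, np.asarray(core_error, dtype=float))
    warms = np.maximum(0.0, np.asarray(skin_error, dtype=float))
    rate = warms * (params.sweat_gain_skin + params.sweat_gain_product * warmc)
    return np.minimum(rate, params.max_sweat)


def wettedness_from_sweat(
    sweat_rate,
    skin_temp,
    area,
    ret_total,
    ambient_vp,
    params: ControllerParams,
    latent_heat: float = 2426.0,
):
    """Per-segment skin wettedness implied by a whole-body sweat rate.

    The sweat rate (g/min) is apportioned over the segments by surface area;
    each segment's wettedness is the required evaporative power divided by
    its maximum (fully wet) evaporative power, with the insensible-diffusion
    floor and full saturation as bounds.  Where no evaporation is possible
    (zero vapour-pressure gradient) the wettedness saturates at 1.
    """
    from .environment import saturation_vapour_pressure  # local to avoid cycle

    sweat = np.asarray(sweat_rate, dtype=float)[..., None]
    t_sk = np.asarray(skin_temp, dtype=float)
    area = np.asarray(area, dtype=float)
    e_req = sweat * latent_heat / 60.0 * (area / area.sum(axis=-1, keepdims=True))
    gradient = np.clip(saturation_vapour_pressure(t_sk) - ambient_vp, 0.0, None)
    e_max = gradient * area / np.asarray(ret_total, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        demand = np.where(e_max > 1e-12, e_req / np.maximum(e_max, 1e-12), 1.0)
    return np.clip(params.wettedness_floor + demand, params.wettedness_floor, 1.0)


def effector_outputs(state, params: ControllerParams, body=None) -> EffectorOutputs:
    """Convenience: evaluate all effectors for one :class:`BodyState`.

    ``body`` (a :class:`~coweda.body.ThermalBody`) supplies individual-specific
    basal/min/max skin flows; without it the reference-adult values are used.
    Wettedness is returned at the diffusion floor — environment-dependent
    sweating wettedness is resolved by the simulator, which knows the
    evaporative resistances.
    """
    core_err, skin_err = thermal_signal(state, params)
    if body is not None:
        flows = vasomotor(
            core_err, skin_err, params,
            basal_flow=body.basal_skin_flow[0],
            min_flow=body.min_skin_flow[0],
            max_flow=body.max_skin_flow[0],
        )
    else:
        flows = vasomotor(core_err, skin_err, params)
    return EffectorOutputs(
        shivering_heat=float(shivering(core_err, skin_err, params)),
        skin_blood_flow=np.asarray(flows, dtype=float),
        sweat_rate=float(sweating(core_err, skin_err, params)),
        wettedness=np.full(N_SEGMENTS, params.wettedness_floor),
    )
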