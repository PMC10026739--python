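"""Exposure environments, activity levels and the wind-chill comparison index.

The environment is deliberately simple: cold air is described by temperature,
wind speed and relative humidity, and cold water by its temperature.  Solar
load, precipitation and altitude are outside the model's scope.

The Wind Chill Temperature (WCT) implemented here is the index published by
the US National Weather Service / Environment Canada, used only as a
comparison baseline for the model's own frostbite-risk endurance times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .params import ModelParams, ValidationError, default_params

__all__ = [
    "Environment",
    "Activity",
    "ExposurePhase",
    "ExposureScenario",
    "metabolic_rate_for",
    "wind_chill_temperature",
    "wct_frostbite_category",
    "saturation_vapour_pressure",
]

Medium = Literal["air", "water"]


@dataclass(frozen=True)
class Environment:
    """Ambient conditions for one exposure phase.

    Parameters
    ----------
    medium:
        ``"air"`` for cold-air exposure or ``"water"`` for immersion.
    air_temp:
        Air temperature, °C.  For immersion this is the temperature of the
        air breathed above the surface and defaults to the water temperature.
    wind_speed:
        Wind speed at body level, m/s (ignored in water).
    rh:
        Relative humidity, % (ignored in water).
    water_temp:
        Water temperature, °C; required when ``medium == "water"``.
    """

    medium: Medium = "air"
    air_temp: float = 0.0
    wind_speed: float = 0.4
    rh: float = 50.0
    water_temp: float | None = None

    def __post_init__(self):
        if self.medium not in ("air", "water"):
            raise ValidationError(f"medium must be 'air' or 'water', got {self.medium!r}")
        if not -60.0 <= self.air_temp <= 50.0:
            raise ValidationError(f"air_temp {self.air_temp} °C outside [-60, 50]")
        if self.wind_speed < 0:
            raise ValidationError(f"wind_speed must be >= 0, got {self.wind_speed}")
        if not 0.0 <= self.rh <= 100.0:
            raise ValidationError(f"rh {self.rh} % outside [0, 100]")
        if self.medium == "water":
            if self.water_temp is None:
                object.__setattr__(self, "water_temp", self.air_temp)
            if not -2.0 <= float(self.water_temp) <= 35.0:
                raise ValidationError(f"water_temp {self.water_temp} °C outside [-2, 35]")

    @property
    def ambient_temp(self) -> float:
        """Temperature of the medium in contact with the body surface."""
        return float(self.water_temp) if self.medium == "water" else self.air_temp

    @property
    def vapour_pressure(self) -> float:
        """Ambient water-vapour partial pressure, Pa (zero gradient in water)."""
        return self.rh / 100.0 * saturation_vapour_pressure(self.air_temp)


ACTIVITY_LEVELS = ("rest", "light", "moderate", "heavy")


@dataclass(frozen=True)
class Activity:
    """A physical activity level resolved to a whole-body metabolic rate.

    ``metabolic_rate`` may be supplied directly (W, total heat production);
    otherwise it is looked up from the level menu in the parameter file.
    """

    level: str = "rest"
    metabolic_rate: float | None = None

    def resolve(self, params: ModelParams | None = None) -> float:
        if self.metabolic_rate is not None:
            return float(self.metabolic_rate)
        return metabolic_rate_for(self.level, params)


def metabolic_rate_for(level: str, params: ModelParams | None = None) -> float:
    """Metabolic rate (W) for a named activity level.

    The menu maps rest/light/moderate/heavy to strictly increasing rates;
    the default table is 105/250/400/600 W for a standard adult.
    """
    params = params or default_params()
    try:
        return float(params.activity_levels[level])
    except KeyError:
        valid = ", ".join(sorted(params.activity_levels))
        raise ValidationError(f"unknown activity level {level!r}; valid levels: {valid}") from None


@dataclass(frozen=True)
class ExposurePhase:
    """One homogeneous stretch of an exposure scenario."""

    environment: Environment
    activity: Activity
    ensemble: object  # EnsembleResistances or ensemble id resolved by the caller
    duration_min: float

    def __post_init__(self):
        if self.duration_min <= 0:
            raise ValidationError("phase duration must be positive")


@dataclass(frozen=True)
class ExposureScenario:
    """An ordered sequence of exposure phases.

    The final state of each phase is the initial state of the next, so
    phases concatenate without discontinuity.
    """

    phases: Sequence[ExposurePhase]
    max_horizon_min: float | None = None

    def __post_init__(self):
        if len(self.phases) == 0:
            raise ValidationError("scenario needs at least one phase")

    @property
    def total_duration_min(self) -> float:
        total = sum(p.duration_min for p in self.phases)
        if self.max_horizon_min is not None:
            total = min(total, self.max_horizon_min)
        return total


# ---------------------------------------------------------------------------
# Wind Chill Temperature (comparison index)
# ---------------------------------------------------------------------------

#: The NWS/Environment Canada regression is defined for T <= 10 °C and
#: wind >= 4.8 km/h (1.34 m/s); outside that range the air temperature is
#: returned unchanged with ``in_range=False``.
WCT_MIN_WIND_MS = 1.34
WCT_MAX_TEMP_C = 10.0


def wind_chill_temperature(air_temp: float, wind_speed: float) -> tuple[float, bool]:
    """Wind Chill Temperature, °C.

    Evaluates ``13.12 + 0.6215 T + (0.3965 T - 11.37) V^0.16`` with ``V`` the
    wind speed in km/h.  Returns ``(wct, in_range)``; outside the chart's
    applicable range the air temperature itself is returned, flagged.
    """
    if wind_speed < 0:
        raise ValidationError("wind_speed must be >= 0")
    if air_temp > WCT_MAX_TEMP_C or wind_speed < WCT_MIN_WIND_MS:
        return float(air_temp), False
    v_kmh = wind_speed * 3.6
    wct = 13.12 + 0.6215 * air_temp + (0.3965 * air_temp - 11.37) * v_kmh**0.16
    return float(min(wct, air_temp)), True


def wct_frostbite_category(
    air_temp: float, wind_speed: float, params: ModelParams | None = None
) -> str:
    """Frostbite-time band of the published WCT chart.

    Returns one of ``"none"``, ``"30 min"``, ``"10 min"``, ``"5 min"``.
    Band boundaries are stored as data (``wct_bands`` in the parameter file);
    a WCT exactly on a boundary maps to the shorter time.
    """
    params = params or default_params()
    bands = params.wct_bands
    wct, in_range = wind_chill_temperature(air_temp, wind_speed)
    if not in_range or wct > bands["none_above"]:
        return "none"
    if wct > bands["thirty_above"]:
        return "30 min"
    if wct > bands["ten_above"]:
        return "10 min"
    return "5 min"


def saturation_vapour_pressure(temp_c):
    """Saturation water-vapour pressure over liquid water, Pa (Magnus form).

    Accurate to well under 1 % between −40 and 50 °C; strictly increasing.
    Accepts scalars or arrays.
    """
    t = np.asarray(temp_c, dtype=float)
    p = 610.94 * np.exp(17.625 * t / (t + 243.04))
    return float(p) if np.isscalar(temp_c) or p.ndim == 0 else p
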