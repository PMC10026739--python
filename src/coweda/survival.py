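"""Cold-water immersion survival for individuals and populations.

The immersion variant runs the same coupled body/controller system with the
water-side clothing physics (thin convective water film, flooded clothing
retaining a documented fraction of its dry insulation, no evaporation) and a
deep-hypothermia endpoint: survival time is when the weighted core
temperature falls to 28 °C, or when cumulative fluid loss exceeds a fraction
of body mass (dehydration — normally not reached in cold water, where
sweating is suppressed), or the 72 h horizon.

Populations are sampled from truncated normal anthropometric distributions
with a seeded generator; all individuals integrate simultaneously as one
batch, so a 100-victim curve costs little more than a single simulation.
Survival curves are empirical (fraction of the population not yet past the
endpoint) and medians are read off the curve by linear interpolation of its
50 % crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .body import Anthropometry, ThermalBody
from .clothing import EnsembleResistances
from .environment import Environment
from .params import ModelParams, ValidationError, default_params
from .simulate import PhaseContext, Thresholds, detect_crossing, initial_state, rk4_step

__all__ = [
    "Individual",
    "PopulationSpec",
    "SurvivalResult",
    "SurvivalCurve",
    "survival_time",
    "sample_population",
    "population_survival",
    "dehydration_time",
]


@dataclass(frozen=True)
class Individual:
    """One member of an immersion population."""

    anthropometry: Anthropometry
    id: str = "individual"


@dataclass(frozen=True)
class PopulationSpec:
    """Truncated-normal anthropometric distributions for a sampled population.

    Defaults describe a general adult population: height 175 ± 10 cm,
    mass 78 ± 12 kg, fat fraction 0.20 ± 0.06, truncated to the validity
    ranges of the anthropometry type.
    """

    n: int = 100
    height_mean: float = 175.0
    height_sd: float = 10.0
    height_bounds: tuple[float, float] = (150.0, 205.0)
    mass_mean: float = 78.0
    mass_sd: float = 12.0
    mass_bounds: tuple[float, float] = (45.0, 130.0)
    fat_mean: float = 0.20
    fat_sd: float = 0.06
    fat_bounds: tuple[float, float] = (0.06, 0.45)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("population size must be >= 1")
        for sd in (self.height_sd, self.mass_sd, self.fat_sd):
            if sd < 0:
                raise ValidationError("standard deviations must be >= 0")
        for lo, hi, name in (
            (*self.height_bounds, "height"),
            (*self.mass_bounds, "mass"),
            (*self.fat_bounds, "fat"),
        ):
            if not lo < hi:
                raise ValidationError(f"{name}_bounds must be an increasing pair")


@dataclass
class SurvivalResult:
    """Predicted survival for one individual at one water temperature."""

    id: str
    survival_time_h: float
    limiting_factor: str  # "hypothermia" | "dehydration" | "horizon"
    water_temp: float

    def __post_init__(self):
        if self.survival_time_h <= 0:
            raise ValidationError("survival time must be positive")


@dataclass
class SurvivalCurve:
    """Empirical population survival curve at one water temperature."""

    water_temp: float
    time_h: np.ndarray
    fraction_surviving: np.ndarray

    def median_h(self) -> float | None:
        """Time at which the surviving fraction crosses 0.5 (linear
        interpolation); ``None`` if more than half the population outlasts
        the horizon."""
        return detect_crossing(self.time_h, self.fraction_surviving, 0.5, "falling")


def _truncated_normal(rng, mean, sd, bounds, size):
    lo, hi = bounds
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValidationError("degenerate distribution mean outside bounds")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(200):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ValidationError("rejection sampling failed; bounds too tight for distribution")


def sample_population(spec: PopulationSpec) -> list[Individual]:
    """Draw ``spec.n`` individuals; deterministic under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    h = _truncated_normal(rng, spec.height_mean, spec.height_sd, spec.height_bounds, spec.n)
    m = _truncated_normal(rng, spec.mass_mean, spec.mass_sd, spec.mass_bounds, spec.n)
    f = _truncated_normal(rng, spec.fat_mean, spec.fat_sd, spec.fat_bounds, spec.n)
    return [
        Individual(Anthropometry(h[i], m[i], f[i]), id=f"victim_{i:03d}")
        for i in range(spec.n)
    ]


# ---------------------------------------------------------------------------
# Immersion simulation
# ---------------------------------------------------------------------------


def _immersion_batch(
    bodies: ThermalBody,
    water_temp: float,
    ensemble: EnsembleResistances,
    thresholds: Thresholds,
    params: ModelParams,
    timestep: float,
    horizon_h: float,
):
    """Integrate a batch through immersion; return per-individual
    (survival_time_h, limiting_factor) pairs.

    Integration stops once every batch element has crossed an endpoint.
    """
    env = Environment(medium="water", air_temp=water_temp, water_temp=water_temp)
    met = np.full(bodies.B, params.activity_levels["rest"], dtype=float)
    ctx = PhaseContext(bodies, env, met, ensemble, params)
    T, Tb, fluid = initial_state(params, B=bodies.B)
    w_core = np.asarray(params.controller["core_weights"], dtype=float)
    fluid_limit = thresholds.dehydration_fraction * bodies.mass

    n_steps = int(math.ceil(horizon_h * 3600.0 / timestep))
    core = np.empty((n_steps + 1, bodies.B))
    fl = np.empty((n_steps + 1, bodies.B))
    core[0] = T[..., 0] @ w_core
    fl[0] = fluid
    running_min = core[0].copy()
    last = n_steps
    for k in range(1, n_steps + 1):
        T, Tb, fluid, _, _ = rk4_step(ctx, T, Tb, fluid, timestep)
        core[k] = T[..., 0] @ w_core
        fl[k] = fluid
        np.minimum(running_min, core[k], out=running_min)
        done = (running_min <= thresholds.survival_core) | (fluid >= fluid_limit)
        if done.all():
            last = k
            break
    t_h = np.arange(last + 1) * timestep / 3600.0
    results = []
    for b in range(bodies.B):
        t_hypo = detect_crossing(t_h, core[: last + 1, b], thresholds.survival_core, "falling")
        t_dehy = detect_crossing(t_h, fl[: last + 1, b], float(fluid_limit[b]), "rising")
        candidates = [
            (t_hypo, "hypothermia"),
            (t_dehy, "dehydration"),
            (horizon_h, "horizon"),
        ]
        t_s, factor = min(
            ((t, f) for t, f in candidates if t is not None), key=lambda tf: tf[0]
        )
        results.append((max(float(t_s), timestep / 3600.0), factor))
    return results


def survival_time(
    individual: Individual,
    env: Environment,
    ensemble: EnsembleResistances,
    thresholds: Thresholds | None = None,
    params: ModelParams | None = None,
    timestep: float | None = None,
) -> SurvivalResult:
    """Predicted survival time for one individual in cold water.

    Hypothermia only (no cold shock or swimming failure): the endpoint is
    the weighted core temperature crossing ``thresholds.survival_core``
    (default 28 °C), with dehydration and the 72 h horizon as secondary
    limits.
    """
    p = params or default_params()
    if env.medium != "water":
        raise ValidationError("survival_time requires a water environment")
    th = thresholds or Thresholds.from_params(p)
    dt = float(timestep if timestep is not None else p.simulation["default_timestep_s"])
    a = individual.anthropometry
    body = ThermalBody(a.height, a.mass, a.fat_fraction, params=p)
    (t_s, factor), = _immersion_batch(
        body, float(env.water_temp), ensemble, th, p, dt, p.simulation["max_horizon_h"]
    )
    return SurvivalResult(
        id=individual.id, survival_time_h=t_s, limiting_factor=factor,
        water_temp=float(env.water_temp),
    )


def population_survival(
    spec: PopulationSpec,
    water_temps: Sequence[float],
    ensemble: EnsembleResistances,
    thresholds: Thresholds | None = None,
    params: ModelParams | None = None,
    timestep: float | None = None,
    curve_resolution_h: float = 0.1,
):
    """Survival curves and medians for a sampled population.

    Returns ``(curves, medians, results)``: one :class:`SurvivalCurve` and
    median per water temperature, plus the per-individual
    :class:`SurvivalResult` table.  The same sampled population is reused at
    every temperature.
    """
    if len(water_temps) == 0:
        raise ValidationError("at least one water temperature required")
    p = params or default_params()
    th = thresholds or Thresholds.from_params(p)
    dt = float(timestep if timestep is not None else p.simulation["default_timestep_s"])
    population = sample_population(spec)
    bodies = ThermalBody(
        np.array([i.anthropometry.height for i in population]),
        np.array([i.anthropometry.mass for i in population]),
        np.array([i.anthropometry.fat_fraction for i in population]),
        params=p,
    )
    horizon = p.simulation["max_horizon_h"]
    curves: list[SurvivalCurve] = []
    medians: list[float | None] = []
    results: list[SurvivalResult] = []
    for tw in water_temps:
        pairs = _immersion_batch(bodies, float(tw), ensemble, th, p, dt, horizon)
        times = np.array([t for t, _ in pairs])
        for ind, (t_s, factor) in zip(population, pairs):
            results.append(
                SurvivalResult(
                    id=ind.id, survival_time_h=t_s, limiting_factor=factor,
                    water_temp=float(tw),
                )
            )
        grid = np.arange(0.0, min(times.max(), horizon) + curve_resolution_h,
                         curve_resolution_h)
        frac = (times[None, :] > grid[:, None]).mean(axis=1)
        frac[0] = 1.0
        curve = SurvivalCurve(water_temp=float(tw), time_h=grid, fraction_surviving=frac)
        curves.append(curve)
        medians.append(curve.median_h())
    return curves, medians, results


def dehydration_time(result, mass: float, limit_fraction: float = 0.05) -> float | None:
    """Rising crossing of cumulative fluid loss at ``limit_fraction × mass``.

    ``result`` is a :class:`~coweda.simulate.SimulationResult`; the return
    value is in hours, ``None`` if the limit is never reached.  A zero limit
    reports 0 h by the standard boundary rule.
    """
    if limit_fraction < 0:
        raise ValidationError("limit_fraction must be >= 0")
    t_min = detect_crossing(
        result.time_min, result.fluid_loss, limit_fraction * mass, "rising"
    )
    return None if t_min is None else t_min / 60.0
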