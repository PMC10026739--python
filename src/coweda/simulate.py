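"""Coupled simulation and endurance-time extraction.

The passive body, the thermoregulatory controller and the clothing layer are
integrated through an exposure scenario with a fixed-step classical
Runge-Kutta (RK4) scheme.  The outer reporting step defaults to 30 s; inside
each outer step the integrator takes as many equal substeps as a
conservative stability estimate of the fastest node requires (thin shells on
lean extremities in cold water are the stiffest case), so the scheme stays
stable without changing the reporting grid.

Endurance times are threshold crossings of the simulated trajectories,
located by linear interpolation between bracketing samples:

- frostbite risk of fingers/toes: hand/foot skin temperature falling to 5 °C
  (a conservative risk proxy, not tissue freezing);
- hypothermia: weighted core temperature falling to 36 °C;
- comfort: maximum segment wettedness rising to 0.5;
- manual performance: hand skin temperature falling to 15 °C, where task
  performance has declined by 20 %.

The hand criterion uses the hand-segment skin node as a finger proxy — the
six-cylinder body has no finger node, which is the known weak point of
hand-temperature prediction at this resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

log = logging.getLogger(__name__)

from .body import BodyState, ThermalBody, Anthropometry
from .clothing import EnsembleResistances, total_resistances
from .control import ControllerParams, wettedness_from_sweat
from .environment import Activity, Environment, ExposurePhase, ExposureScenario, saturation_vapour_pressure
from .params import (
    N_SEGMENTS,
    SEGMENTS,
    ConfigurationError,
    ModelParams,
    ValidationError,
    default_params,
)

__all__ = [
    "Thresholds",
    "SimulationResult",
    "EnduranceTimes",
    "simulate",
    "detect_crossing",
    "endurance_times",
    "endurance_grid",
    "manual_performance_fraction",
    "manual_performance_duration",
    "NOT_REACHED",
]

#: Sentinel for a criterion never crossed within the scenario horizon.
NOT_REACHED = None


@dataclass(frozen=True)
class Thresholds:
    """Physiological criteria defining the endurance and survival endpoints (°C / wettedness)."""

    hypothermia_core: float = 36.0
    extremity_frostbite_risk: float = 5.0
    comfort_wettedness: float = 0.5
    manual_performance_hand: float = 15.0
    survival_core: float = 28.0
    dehydration_fraction: float = 0.05

    def __post_init__(self):
        if not self.survival_core < self.hypothermia_core:
            raise ValidationError("survival_core must be below hypothermia_core")
        if not self.extremity_frostbite_risk < self.manual_performance_hand:
            raise ValidationError(
                "extremity threshold must be below the manual-performance threshold"
            )

    @classmethod
    def from_params(cls, params: ModelParams) -> "Thresholds":
        return cls(**params.thresholds)


@dataclass
class SimulationResult:
    """Simulated trajectories on the reporting time grid.

    ``temperatures`` is (n, 6, 4) °C; effector and wettedness trajectories
    are evaluated at each grid point; ``energy_residual`` is the per-step
    absolute energy-balance residual (W) of the integrator audit.
    """

    time_min: np.ndarray
    temperatures: np.ndarray
    blood: np.ndarray
    shivering: np.ndarray
    skin_blood_flow: np.ndarray
    sweat_rate: np.ndarray
    wettedness: np.ndarray
    fluid_loss: np.ndarray
    energy_residual: np.ndarray
    core_weights: np.ndarray

    @property
    def core_temperature(self) -> np.ndarray:
        """Weighted core-signal trajectory, °C."""
        return self.temperatures[:, :, 0] @ self.core_weights

    @property
    def hand_skin(self) -> np.ndarray:
        return self.temperatures[:, SEGMENTS.index("hands"), 3]

    @property
    def foot_skin(self) -> np.ndarray:
        return self.temperatures[:, SEGMENTS.index("feet"), 3]

    @property
    def max_wettedness(self) -> np.ndarray:
        return self.wettedness.max(axis=1)

    def to_frame(self):
        """Trajectory as a pandas DataFrame (time + 24 temperature columns +
        effectors + wettedness), for CSV export."""
        import pandas as pd

        data = {"time_min": self.time_min}
        from .params import COMPARTMENTS

        for i, seg in enumerate(SEGMENTS):
            for j, comp in enumerate(COMPARTMENTS):
                data[f"T_{seg}_{comp}"] = self.temperatures[:, i, j]
        data["T_blood"] = self.blood
        data["shivering_W"] = self.shivering
        for i, seg in enumerate(SEGMENTS):
            data[f"sbf_{seg}_L_h"] = self.skin_blood_flow[:, i]
        data["sweat_g_min"] = self.sweat_rate
        for i, seg in enumerate(SEGMENTS):
            data[f"wettedness_{seg}"] = self.wettedness[:, i]
        data["fluid_loss_kg"] = self.fluid_loss
        data["energy_residual_W"] = self.energy_residual
        return pd.DataFrame(data)


@dataclass
class EnduranceTimes:
    """Threshold-crossing times in minutes; ``None`` = not reached."""

    finger_frostbite_risk: float | None
    toe_frostbite_risk: float | None
    hypothermia: float | None
    comfort_limit: float | None
    manual_performance_limit: float | None
    horizon_min: float = math.nan

    def to_dict(self) -> dict:
        return {
            "finger_frostbite_risk_min": self.finger_frostbite_risk,
            "toe_frostbite_risk_min": self.toe_frostbite_risk,
            "hypothermia_min": self.hypothermia,
            "comfort_limit_min": self.comfort_limit,
            "manual_performance_limit_min": self.manual_performance_limit,
            "horizon_min": self.horizon_min,
        }


# ---------------------------------------------------------------------------
# Integration engine (batched)
# ---------------------------------------------------------------------------


class PhaseContext:
    """Precomputed arrays for one homogeneous exposure phase of a batch."""

    def __init__(
        self,
        body: ThermalBody,
        env: Environment | Sequence[Environment],
        met_rate,
        resistances: EnsembleResistances | Sequence[EnsembleResistances],
        params: ModelParams | None = None,
    ):
        p = params or body.params
        self.body = body
        self.params = p
        B = body.B
        envs = [env] * B if isinstance(env, Environment) else list(env)
        if len(envs) != B:
            raise ConfigurationError("one environment (or one per batch element) required")
        media = {e.medium for e in envs}
        if len(media) > 1:
            raise ConfigurationError("a phase batch must share one medium")
        self.medium = media.pop()
        self.T_amb = np.array([e.ambient_temp for e in envs])
        self.P_amb = np.array(
            [0.0 if e.medium == "water" else e.vapour_pressure for e in envs]
        )
        self.air_temp = np.array([e.air_temp for e in envs])

        if isinstance(resistances, EnsembleResistances):
            res_list = [resistances] * B
        else:
            res_list = list(resistances)
        totals = [
            total_resistances(r, e.wind_speed, e.medium, p) if r.rct_total is None else r
            for r, e in zip(res_list, envs)
        ]
        self.rct_total = np.stack([t.rct_total for t in totals])
        self.ret_total = np.stack([t.ret_total for t in totals])

        self.met = np.broadcast_to(np.asarray(met_rate, dtype=float), (B,)).copy()
        self.q_met_node = body.metabolic_sources(self.met)

        c = p.controller
        self.sp_core = c["setpoint_core"]
        self.sp_skin = c["setpoint_skin"]
        self.w_skin = np.asarray(c["skin_weights"])
        self.w_core = np.asarray(c["core_weights"])
        self.g_shiv = (c["shiver_gain_core"], c["shiver_gain_skin"], c["shiver_gain_product"])
        # peak shivering cap in air; in water only a lower, sustainable
        # multiple of basal rate is available (prolonged-immersion ceiling)
        cap_key = (
            "water_shiver_cap_multiple_basal"
            if self.medium == "water"
            else "shiver_cap_multiple_basal"
        )
        self.shiver_cap = c[cap_key] * body.basal_met
        self.shiver_sat = c["shiver_skin_saturation_C"]
        self.shiver_peak = c["shiver_peak_core_C"]
        self.shiver_fail = c["shiver_fail_core_C"]
        self.g_con = (c["constrict_gain_core"], c["constrict_gain_skin"])
        self.con_seg = np.asarray(c["constrict_segment_factor"])
        self.con_interior = np.asarray(c["interior_constrict_factor"])
        self.g_dil = c["dilate_gain_L_h_per_K"]
        self.dil_core_w = c["dilate_core_weight"]
        self.g_sw = (c["sweat_gain_skin"], c["sweat_gain_product"])
        self.max_sweat = c["max_sweat_g_min"]
        self.w_floor = c["wettedness_floor"]

        r = p.respiration
        if self.medium == "water":
            self.q_resp = np.zeros(B)
        else:
            self.q_resp = self.met * (
                r["dry_coeff"] * np.clip(r["ref_temp"] - self.air_temp, 0.0, None)
                + r["latent_coeff"]
                * np.clip(r["ref_vp_kPa"] - self.P_amb / 1000.0, 0.0, None)
            )
        self.latent = p.latent_heat

        self.n_sub = self._substeps_for_stability()

    def _substeps_for_stability(self, dt_ref: float | None = None) -> Callable[[float], int]:
        """Conservative per-node rate bound -> substep count for a given dt."""
        body = self.body
        K_in = np.zeros_like(body.capacity)
        K_in[..., :3] += body.conductance
        K_in[..., 1:] += body.conductance
        K_env = body.area / self.rct_total  # W/K at the skin
        K_in[..., 3] += K_env
        W_max = np.zeros_like(body.capacity)
        W_max[..., 3] = body.max_skin_flow * body.flow_to_WK
        W_max[..., 1] = (
            self.params.perfusion_per_watt
            * (self.q_met_node[..., 1] + self.shiver_cap[:, None] * body.muscle_share)
        )
        W_max[..., 0] = self.params.perfusion_per_watt * self.q_met_node[..., 0]
        rate = (K_in + W_max) / body.capacity
        lam = float(rate.max())

        def n_sub(dt: float) -> int:
            return max(1, int(math.ceil(dt * lam / 2.0)))

        return n_sub

    # -- controller + passive rates ---------------------------------------

    def derivatives(self, T, Tb):
        """State derivative and audit terms at one controller evaluation."""
        body = self.body
        core_err = T[..., 0] @ self.w_core - self.sp_core
        skin_err = T[..., 3] @ self.w_skin - self.sp_skin
        coldc = np.maximum(0.0, -core_err)
        colds = np.maximum(0.0, -skin_err)
        warmc = np.maximum(0.0, core_err)
        warms = np.maximum(0.0, skin_err)

        gc, gs, gp = self.g_shiv
        colds_eff = np.minimum(colds, self.shiver_sat)  # skin cold-signal saturation
        core_sig = T[..., 0] @ self.w_core
        # shivering efficacy wanes as the core itself cools (hypothermic
        # impairment), vanishing at the deep-hypothermia failure temperature
        efficacy = np.clip(
            (core_sig - self.shiver_fail) / (self.shiver_peak - self.shiver_fail),
            0.0,
            1.0,
        )
        shiv = efficacy * np.minimum(
            gc * coldc + gs * colds_eff + gp * coldc * colds_eff, self.shiver_cap
        )

        cc, cs = self.g_con
        constrict = 1.0 + self.con_seg[None, :] * (cc * coldc + cs * colds)[:, None]
        share = body.basal_skin_flow / body.basal_skin_flow.sum(axis=1, keepdims=True)
        dilate = share * self.g_dil * (self.dil_core_w * warmc + warms)[:, None]
        skin_flow = np.clip(
            body.basal_skin_flow / constrict + dilate,
            body.min_skin_flow,
            body.max_skin_flow,
        )

        g1, g2 = self.g_sw
        sweat = np.minimum(warms * (g1 + g2 * warmc), self.max_sweat)

        if self.medium == "water":
            wet = np.full_like(T[..., 3], self.w_floor)
        else:
            e_req = (
                sweat[:, None]
                * self.latent
                / 60.0
                * (body.area / body.area.sum(axis=1, keepdims=True))
            )
            gradient = np.clip(
                saturation_vapour_pressure(T[..., 3]) - self.P_amb[:, None], 0.0, None
            )
            e_max = gradient * body.area / self.ret_total
            demand = np.where(e_max > 1e-12, e_req / np.maximum(e_max, 1e-12), 1.0)
            wet = np.clip(self.w_floor + demand, self.w_floor, 1.0)

        q_source = body.metabolic_sources(self.met, T)
        q_source[..., 1] += shiv[:, None] * body.muscle_share
        # deep perfusion follows local heat production, but limb and
        # extremity interiors also vasoconstrict in the cold
        con_int = 1.0 + self.con_interior[None, :] * (cc * coldc + cs * colds)[:, None]
        interior_flow = (
            self.params.perfusion_per_watt
            * np.stack([q_source[..., 0], q_source[..., 1]], axis=-1)
            / con_int[..., None]
        )
        dT, dTb, q_dry, q_evap = body.passive_rates(
            T,
            Tb,
            q_source=q_source,
            skin_flow_WK=skin_flow * body.flow_to_WK,
            interior_flow_WK=interior_flow,
            wettedness=wet,
            T_amb=self.T_amb,
            P_amb=self.P_amb,
            rct_total=self.rct_total,
            ret_total=self.ret_total,
            q_resp=self.q_resp,
        )
        # net heat into the body, for the energy audit
        q_net = q_source.sum(axis=(1, 2)) - q_dry - q_evap - self.q_resp
        # fluid loss: sweat plus the latent fraction of respiratory loss
        latent_resp = (
            0.0 * self.met
            if self.medium == "water"
            else self.met
            * self.params.respiration["latent_coeff"]
            * np.clip(
                self.params.respiration["ref_vp_kPa"] - self.P_amb / 1000.0, 0.0, None
            )
        )
        dfluid = sweat / 60.0 / 1000.0 + latent_resp / self.latent / 1000.0  # kg/s
        aux = {
            "shivering": shiv,
            "skin_blood_flow": skin_flow,
            "sweat_rate": sweat,
            "wettedness": wet,
            "q_net": q_net,
        }
        return dT, dTb, dfluid, aux


def rk4_step(ctx: PhaseContext, T, Tb, fluid, dt: float):
    """One RK4 step of ``dt`` seconds (split into stability substeps).

    Returns the new state, the effector aux dict evaluated at the step
    start, and the absolute energy-balance residual (W) over the step:
    stored-energy rate of change minus net heat input, both accumulated
    with the same quadrature weights.
    """
    n = ctx.n_sub(dt)
    h = dt / n
    body = ctx.body
    aux0 = None
    residual = np.zeros(body.B)
    for _ in range(n):
        k1T, k1b, k1f, aux = ctx.derivatives(T, Tb)
        if aux0 is None:
            aux0 = aux
        k2T, k2b, k2f, aux2 = ctx.derivatives(T + 0.5 * h * k1T, Tb + 0.5 * h * k1b)
        k3T, k3b, k3f, aux3 = ctx.derivatives(T + 0.5 * h * k2T, Tb + 0.5 * h * k2b)
        k4T, k4b, k4f, aux4 = ctx.derivatives(T + h * k3T, Tb + h * k3b)
        dT = (k1T + 2 * k2T + 2 * k3T + k4T) / 6.0
        dTb = (k1b + 2 * k2b + 2 * k3b + k4b) / 6.0
        dfl = (k1f + 2 * k2f + 2 * k3f + k4f) / 6.0
        storage = (body.capacity * dT).sum(axis=(1, 2)) + body.blood_capacity * dTb
        q_in = (
            aux["q_net"] + 2 * aux2["q_net"] + 2 * aux3["q_net"] + aux4["q_net"]
        ) / 6.0
        residual = np.maximum(residual, np.abs(storage - q_in))
        T = T + h * dT
        Tb = Tb + h * dTb
        fluid = fluid + h * dfl
        if not np.all(np.isfinite(T)):
            b, i, j = np.argwhere(~np.isfinite(T))[0]
            from .params import COMPARTMENTS

            raise ValidationError(
                f"integration instability: non-finite temperature in segment "
                f"{SEGMENTS[i]}, compartment {COMPARTMENTS[j]} (batch element {b})"
            )
    return T, Tb, fluid, aux0, residual


# ---------------------------------------------------------------------------
# Public simulation API
# ---------------------------------------------------------------------------


def initial_state(params: ModelParams | None = None, B: int = 1):
    """Documented neutral initial condition (enter the cold from shelter)."""
    p = params or default_params()
    T = np.broadcast_to(p.initial_temperatures, (B, 6, 4)).copy()
    Tb = np.full(B, p.initial_blood)
    fluid = np.zeros(B)
    return T, Tb, fluid


def simulate(
    scenario: ExposureScenario,
    anthropometry: Anthropometry,
    params: ModelParams | None = None,
    timestep: float | None = None,
) -> SimulationResult:
    """Integrate one individual through an exposure scenario.

    ``timestep`` is the reporting step in seconds (default from the
    parameter file, 30 s; accepted range (0.1, 120]).  Each scenario phase
    supplies its environment, activity and ensemble (an
    :class:`EnsembleResistances`, aggregated intrinsic values); total
    resistances are resolved per phase from the wind speed and medium.
    """
    p = params or default_params()
    dt = float(timestep if timestep is not None else p.simulation["default_timestep_s"])
    if not 0.1 < dt <= 120.0:
        raise ValidationError(f"timestep {dt} s outside (0.1, 120]")
    horizon = scenario.total_duration_min
    if horizon > p.simulation["max_horizon_h"] * 60.0:
        raise ValidationError("scenario horizon exceeds the 72 h maximum")

    body = ThermalBody(
        anthropometry.height, anthropometry.mass, anthropometry.fat_fraction, params=p
    )
    T, Tb, fluid = initial_state(p, B=1)

    times = [0.0]
    temps = [T[0].copy()]
    bloods = [Tb[0]]
    fluids = [0.0]
    shiv_tr, sbf_tr, sweat_tr, wet_tr, resid_tr = [], [], [], [], []

    elapsed = 0.0
    for phase in scenario.phases:
        met = phase.activity.resolve(p)
        ctx = PhaseContext(body, phase.environment, met, phase.ensemble, p)
        remaining = min(phase.duration_min, horizon - elapsed)
        n_steps = max(1, int(round(remaining * 60.0 / dt)))
        step_s = remaining * 60.0 / n_steps
        for _ in range(n_steps):
            T, Tb, fluid, aux, resid = rk4_step(ctx, T, Tb, fluid, step_s)
            elapsed += step_s / 60.0
            times.append(elapsed)
            temps.append(T[0].copy())
            bloods.append(Tb[0])
            fluids.append(fluid[0])
            shiv_tr.append(aux["shivering"][0])
            sbf_tr.append(aux["skin_blood_flow"][0].copy())
            sweat_tr.append(aux["sweat_rate"][0])
            wet_tr.append(aux["wettedness"][0].copy())
            resid_tr.append(resid[0])
        log.info(
            "phase done at t=%.1f min: max |energy residual| %.2e W",
            elapsed,
            max(resid_tr[-n_steps:]) if resid_tr else 0.0,
        )
        if elapsed >= horizon - 1e-9:
            break

    # the per-step aux is evaluated at each step start; add the final grid
    # point so every trajectory aligns with the time grid
    _, _, _, aux_end = ctx.derivatives(T, Tb)
    shiv_tr.append(aux_end["shivering"][0])
    sbf_tr.append(aux_end["skin_blood_flow"][0].copy())
    sweat_tr.append(aux_end["sweat_rate"][0])
    wet_tr.append(aux_end["wettedness"][0].copy())
    resid_tr.append(resid_tr[-1] if resid_tr else 0.0)

    return SimulationResult(
        time_min=np.asarray(times),
        temperatures=np.asarray(temps),
        blood=np.asarray(bloods),
        shivering=np.asarray(shiv_tr),
        skin_blood_flow=np.asarray(sbf_tr),
        sweat_rate=np.asarray(sweat_tr),
        wettedness=np.asarray(wet_tr),
        fluid_loss=np.asarray(fluids),
        energy_residual=np.asarray(resid_tr),
        core_weights=np.asarray(p.controller["core_weights"], dtype=float),
    )


def detect_crossing(
    time_min: np.ndarray,
    trajectory: np.ndarray,
    threshold: float,
    direction: str = "falling",
) -> float | None:
    """First threshold crossing of a sampled trajectory, minutes.

    Located by linear interpolation between the bracketing samples; a
    trajectory already beyond the threshold at t=0 reports 0 (documented
    boundary rule); ``None`` when no crossing occurs within the horizon.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(trajectory, dtype=float)
    if t.shape != y.shape:
        raise ValidationError("trajectory must align with the time grid")
    if direction not in ("falling", "rising"):
        raise ValidationError("direction must be 'falling' or 'rising'")
    sign = -1.0 if direction == "falling" else 1.0
    excess = sign * (y - threshold)  # >= 0 once crossed
    if excess[0] >= 0:
        return 0.0
    crossed = np.nonzero(excess >= 0)[0]
    if crossed.size == 0:
        return None
    k = crossed[0]
    y0, y1 = excess[k - 1], excess[k]
    frac = -y0 / (y1 - y0)
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def endurance_times(result: SimulationResult, thresholds: Thresholds) -> EnduranceTimes:
    """Evaluate every endurance criterion on its trajectory."""
    t = result.time_min
    return EnduranceTimes(
        finger_frostbite_risk=detect_crossing(
            t, result.hand_skin, thresholds.extremity_frostbite_risk, "falling"
        ),
        toe_frostbite_risk=detect_crossing(
            t, result.foot_skin, thresholds.extremity_frostbite_risk, "falling"
        ),
        hypothermia=detect_crossing(
            t, result.core_temperature, thresholds.hypothermia_core, "falling"
        ),
        comfort_limit=detect_crossing(
            t, result.max_wettedness, thresholds.comfort_wettedness, "rising"
        ),
        manual_performance_limit=detect_crossing(
            t, result.hand_skin, thresholds.manual_performance_hand, "falling"
        ),
        horizon_min=float(t[-1]),
    )


def manual_performance_fraction(hand_skin_temp):
    """Normalised manual performance as a function of hand skin temperature.

    Piecewise linear through (33 °C, 1.00), (15 °C, 0.80) and (5 °C, 0.50):
    performance declines by 20 % at 15 °C and by 50 % at 5 °C, clamped at
    1.0 for warm hands and at 0.50 below 5 °C.
    """
    t = np.asarray(hand_skin_temp, dtype=float)
    out = np.interp(t, [5.0, 15.0, 33.0], [0.50, 0.80, 1.00])
    return float(out) if out.ndim == 0 else out


def endurance_grid(
    air_temps: Sequence[float],
    wind_speeds: Sequence[float],
    ensemble: EnsembleResistances,
    activity: Activity,
    anthropometry: Anthropometry,
    params: ModelParams | None = None,
    thresholds: Thresholds | None = None,
    horizon_min: float = 1440.0,
    timestep: float | None = None,
    rh: float = 70.0,
) -> list[dict]:
    """Endurance times over a (temperature × wind) grid, one batched run.

    Every grid cell integrates simultaneously as one batch element, so a
    15-cell sweep costs little more than a single simulation.  Returns one
    record per cell with the air temperature, wind speed and the five
    endurance criteria (minutes, ``None`` = not reached within the horizon).
    """
    p = params or default_params()
    th = thresholds or Thresholds.from_params(p)
    dt = float(timestep if timestep is not None else p.simulation["default_timestep_s"])
    cells = [(t, v) for t in air_temps for v in wind_speeds]
    if not cells:
        return []
    envs = [Environment(air_temp=t, wind_speed=v, rh=rh) for t, v in cells]
    B = len(cells)
    body = ThermalBody(
        np.full(B, anthropometry.height),
        np.full(B, anthropometry.mass),
        np.full(B, anthropometry.fat_fraction),
        params=p,
    )
    met = activity.resolve(p)
    ctx = PhaseContext(body, envs, met, ensemble, p)
    T, Tb, fluid = initial_state(p, B=B)
    n_steps = int(round(horizon_min * 60.0 / dt))
    hand_i, foot_i = SEGMENTS.index("hands"), SEGMENTS.index("feet")
    core = np.empty((n_steps + 1, B))
    hand = np.empty((n_steps + 1, B))
    foot = np.empty((n_steps + 1, B))
    wet = np.empty((n_steps + 1, B))
    w_core = ctx.w_core
    core[0] = T[..., 0] @ w_core
    hand[0] = T[:, hand_i, 3]
    foot[0] = T[:, foot_i, 3]
    _, _, _, aux0 = ctx.derivatives(T, Tb)
    wet[0] = aux0["wettedness"].max(axis=1)
    for k in range(1, n_steps + 1):
        T, Tb, fluid, aux, _ = rk4_step(ctx, T, Tb, fluid, dt)
        core[k] = T[..., 0] @ w_core
        hand[k] = T[:, hand_i, 3]
        foot[k] = T[:, foot_i, 3]
        wet[k] = aux["wettedness"].max(axis=1)
    t_min = np.arange(n_steps + 1) * dt / 60.0
    records = []
    for b, (t_air, v) in enumerate(cells):
        records.append(
            {
                "air_temp": t_air,
                "wind_speed": v,
                "finger_frostbite_risk_min": detect_crossing(
                    t_min, hand[:, b], th.extremity_frostbite_risk, "falling"
                ),
                "toe_frostbite_risk_min": detect_crossing(
                    t_min, foot[:, b], th.extremity_frostbite_risk, "falling"
                ),
                "hypothermia_min": detect_crossing(
                    t_min, core[:, b], th.hypothermia_core, "falling"
                ),
                "comfort_limit_min": detect_crossing(
                    t_min, wet[:, b], th.comfort_wettedness, "rising"
                ),
                "manual_performance_limit_min": detect_crossing(
                    t_min, hand[:, b], th.manual_performance_hand, "falling"
                ),
            }
        )
    return records


def manual_performance_duration(
    result: SimulationResult, thresholds: Thresholds
) -> float | None:
    """Duration of effective manual performance, minutes (hand skin → 15 °C)."""
    return detect_crossing(
        result.time_min, result.hand_skin, thresholds.manual_performance_hand, "falling"
    )
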