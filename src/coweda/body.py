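"""Six-cylinder passive body model.

The body is represented as six cylinders (head, trunk, arms, legs, hands,
feet), each split into four concentric compartments: core, muscle, fat and
skin.  Whole-body surface area (DuBois) and volume (two-compartment density
from the fat fraction) are distributed to the segments by configurable
distribution factors; each cylinder's length and radius then follow exactly
from its area/volume pair, and the compartment boundary radii from the
compartment volumes.

The passive system is a compartment (Pennes-style) bioheat network: radial
conduction between adjacent shells, convective exchange of every perfused
compartment with a single central blood pool, metabolic heat sources, and
dry/evaporative/respiratory losses at the boundaries.  All physics is
vectorised over a leading batch axis so that populations of individuals (or
grids of scenarios) integrate in single numpy operations.

Sign convention: heat loss terms are positive when heat leaves the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .environment import Environment, saturation_vapour_pressure
from .params import (
    COMPARTMENTS,
    N_COMPARTMENTS,
    N_SEGMENTS,
    SEGMENTS,
    ConfigurationError,
    ModelParams,
    ValidationError,
    default_params,
)

__all__ = [
    "Anthropometry",
    "DistributionFactors",
    "SegmentGeometry",
    "SegmentSet",
    "BodyState",
    "ThermalBody",
    "body_surface_area",
    "body_density",
    "build_segments",
    "passive_derivatives",
    "dry_heat_loss",
    "evaporative_heat_loss",
]

_REFERENCE_BSA = 1.936  # m², reference adult (180 cm, 74.4 kg) used to scale flows


@dataclass(frozen=True)
class Anthropometry:
    """Individual characteristics driving geometry and thermal inertia.

    height in cm, mass in kg, fat_fraction as a fraction of body mass.
    """

    height: float
    mass: float
    fat_fraction: float

    def __post_init__(self):
        if not 100.0 < self.height < 230.0:
            raise ValidationError(f"height {self.height} cm outside (100, 230)")
        if not 30.0 < self.mass < 200.0:
            raise ValidationError(f"mass {self.mass} kg outside (30, 200)")
        if not 0.03 < self.fat_fraction < 0.6:
            raise ValidationError(
                f"fat_fraction {self.fat_fraction} outside (0.03, 0.6)"
            )


@dataclass(frozen=True)
class DistributionFactors:
    """Per-segment fractions of whole-body area, volume, basal heat and skin flow."""

    area: np.ndarray
    volume: np.ndarray
    basal_met: np.ndarray
    basal_skin_flow: np.ndarray

    def __post_init__(self):
        for name in ("area", "volume", "basal_met", "basal_skin_flow"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (N_SEGMENTS,):
                raise ConfigurationError(f"{name} factors must have {N_SEGMENTS} entries")
            if abs(float(arr.sum()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} factors must sum to 1.0")

    @classmethod
    def from_params(cls, params: ModelParams) -> "DistributionFactors":
        return cls(
            area=params.area_fraction.copy(),
            volume=params.volume_fraction.copy(),
            basal_met=params.basal_met_fraction.copy(),
            basal_skin_flow=params.basal_skin_flow_fraction.copy(),
        )


@dataclass(frozen=True)
class SegmentGeometry:
    """Geometry of one body cylinder (units: m, m², m³)."""

    segment: str
    surface_area: float
    volume: float
    length: float
    outer_radius: float
    compartment_radii: tuple[float, float, float, float]
    degenerate: bool = False

    def __post_init__(self):
        r = self.compartment_radii
        if not all(b > a for a, b in zip(r, r[1:])):
            raise ValidationError(f"{self.segment}: compartment radii must be increasing")
        if abs(r[-1] - self.outer_radius) > 1e-12 * max(self.outer_radius, 1.0):
            raise ValidationError(f"{self.segment}: last compartment radius != outer radius")


class SegmentSet(Sequence):
    """The six segment geometries of one individual, plus the thermal network.

    Behaves as a sequence of :class:`SegmentGeometry`; the attached
    :class:`ThermalBody` carries the derived heat capacities, conductances
    and basal source terms the simulator needs.
    """

    def __init__(self, segments: list[SegmentGeometry], body: "ThermalBody"):
        self._segments = segments
        self.body = body

    def __len__(self):
        return len(self._segments)

    def __getitem__(self, i):
        return self._segments[i]


@dataclass
class BodyState:
    """Instantaneous thermal state: 6x4 temperature matrix plus blood pool.

    ``temperatures[i, j]`` is segment i (canonical order), compartment j
    (core, muscle, fat, skin), °C.  ``fluid_loss`` is cumulative body water
    lost (kg), non-decreasing along any trajectory.
    """

    temperatures: np.ndarray
    blood_temperature: float
    fluid_loss: float = 0.0

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.shape != (N_SEGMENTS, N_COMPARTMENTS):
            raise ValidationError(
                f"temperatures must be {N_SEGMENTS}x{N_COMPARTMENTS}, "
                f"got {self.temperatures.shape}"
            )
        if not np.all(np.isfinite(self.temperatures)):
            bad = np.argwhere(~np.isfinite(self.temperatures))[0]
            raise ValidationError(
                f"non-finite temperature in segment {SEGMENTS[bad[0]]}, "
                f"compartment {COMPARTMENTS[bad[1]]}"
            )
        if np.any(self.temperatures <= -5.0) or np.any(self.temperatures >= 45.0):
            raise ValidationError("temperatures outside physiological range (-5, 45) °C")
        if self.fluid_loss < 0:
            raise ValidationError("fluid_loss must be >= 0")


# ---------------------------------------------------------------------------
# Anthropometric closed forms
# ---------------------------------------------------------------------------


def body_surface_area(anthropometry: Anthropometry) -> float:
    """Whole-body surface area, m² (DuBois & DuBois).

    ``BSA = 0.007184 · height^0.725 · mass^0.425`` with height in cm and
    mass in kg; strictly increasing in both arguments.
    """
    return 0.007184 * anthropometry.height**0.725 * anthropometry.mass**0.425


def body_density(fat_fraction, fat_density: float = 900.0, lean_density: float = 1100.0):
    """Whole-body density, kg/m³, from the two-compartment (Siri) relation."""
    f = np.asarray(fat_fraction, dtype=float)
    rho = 1.0 / (f / fat_density + (1.0 - f) / lean_density)
    return float(rho) if rho.ndim == 0 else rho


# ---------------------------------------------------------------------------
# Batched geometry / network construction
# ---------------------------------------------------------------------------


class ThermalBody:
    """Derived thermal network for a batch of individuals.

    All arrays have a leading batch axis ``B``; scalar anthropometry inputs
    give ``B == 1``.  Quantities:

    - ``area`` (B,6) segment surface areas, m²
    - ``capacity`` (B,6,4) node heat capacities, J/K
    - ``conductance`` (B,6,3) radial conductances between adjacent shells, W/K
    - ``blood_capacity`` (B,) central pool heat capacity, J/K
    - ``basal_met`` (B,) whole-body basal heat production, W
    - ``basal_met_node`` (B,6,4) its distribution over nodes, W
    - ``muscle_share`` (B,6) distribution of shivering heat over muscle nodes
    - ``basal_skin_flow``, ``min_skin_flow``, ``max_skin_flow`` (B,6), L/h
    """

    def __init__(
        self,
        height_cm,
        mass_kg,
        fat_fraction,
        params: ModelParams | None = None,
        factors: DistributionFactors | None = None,
    ):
        p = params or default_params()
        self.params = p
        factors = factors or DistributionFactors.from_params(p)
        self.factors = factors
        h = np.atleast_1d(np.asarray(height_cm, dtype=float))
        m = np.atleast_1d(np.asarray(mass_kg, dtype=float))
        f = np.atleast_1d(np.asarray(fat_fraction, dtype=float))
        h, m, f = np.broadcast_arrays(h, m, f)
        self.B = h.shape[0]
        self.height, self.mass, self.fat_fraction = h, m, f

        self.bsa = 0.007184 * h**0.725 * m**0.425  # m²
        rho = body_density(f, p.fat_density, p.lean_density)  # kg/m³
        v_total = m / rho  # m³
        self.total_volume = v_total

        A = self.bsa[:, None] * factors.area[None, :]  # (B,6)
        V = v_total[:, None] * factors.volume[None, :]
        # segments assigned (near-)zero factors are kept at a benign tiny
        # size and flagged degenerate rather than producing 0/0 geometry
        self.degenerate = (factors.area < 1e-9) | (factors.volume < 1e-9)
        A = np.maximum(A, 1e-8)
        V = np.maximum(V, 1e-12)
        self.area = A
        self.volume = V
        # cylinder solving 2πrL = A, πr²L = V
        r4 = 2.0 * V / A
        L = A**2 / (4.0 * np.pi * V)
        self.length = L
        self.outer_radius = r4

        tmin = p.min_shell_thickness
        # skin shell from fixed thickness (clamped to keep an interior)
        t_skin = np.maximum(p.skin_thickness[None, :], tmin)
        r3 = np.maximum(r4 - t_skin, 0.4 * r4)
        v_skin = np.pi * (r4**2 - r3**2) * L
        # fat shell: whole-body fat volume fraction apportioned uniformly
        fat_vol_frac = (f * m / (p.fat_density)) / v_total  # dimensionless
        v_fat = fat_vol_frac[:, None] * V
        v_fat_min = np.pi * (r3**2 - np.maximum(r3 - tmin, 0.1 * r3) ** 2) * L
        v_fat = np.clip(v_fat, v_fat_min, 0.5 * (V - v_skin))
        r2 = np.sqrt(r3**2 - v_fat / (np.pi * L))
        interior = np.pi * r2**2 * L
        v_mus = np.clip(
            p.muscle_interior_fraction[None, :] * interior,
            np.pi * (r2**2 - np.maximum(r2 - tmin, 0.1 * r2) ** 2) * L,
            0.9 * interior,
        )
        r1 = np.sqrt(r2**2 - v_mus / (np.pi * L))
        v_core = interior - v_mus

        self.radii = np.stack([r1, r2, r3, r4], axis=-1)  # (B,6,4)
        self.node_volume = np.stack([v_core, v_mus, v_fat, v_skin], axis=-1)

        dens = np.array([p.lean_density, p.lean_density, p.fat_density, p.lean_density])
        node_mass = self.node_volume * dens[None, None, :]
        blood_mass = p.blood_volume_per_kg * m * p.blood_density / 1000.0  # kg
        # carve the blood pool's mass out of the tissue so total heat capacity
        # stays consistent with body mass
        scale = (m - blood_mass) / node_mass.sum(axis=(1, 2))
        self.capacity = node_mass * scale[:, None, None] * p.specific_heat
        self.blood_capacity = blood_mass * p.blood_specific_heat

        self.conductance = self._radial_conductances(L, p)

        self.basal_met = p.basal_met_per_m2 * self.bsa
        self.basal_met_node = (
            self.basal_met[:, None, None]
            * factors.basal_met[None, :, None]
            * p.met_node_split[None, None, :]
        )
        mus_mass = node_mass[:, :, 1]
        self.muscle_share = mus_mass / mus_mass.sum(axis=1, keepdims=True)

        size = (self.bsa / _REFERENCE_BSA)[:, None]
        self.basal_skin_flow = (
            p.basal_skin_flow_total * factors.basal_skin_flow[None, :] * size
        )
        c = p.controller
        self.min_skin_flow = np.asarray(c["min_skin_flow_L_h"])[None, :] * size
        self.max_skin_flow = np.asarray(c["max_skin_flow_L_h"])[None, :] * size
        #: W/K carried per L/h of blood flow
        self.flow_to_WK = p.blood_density / 1000.0 * p.blood_specific_heat / 3600.0

    def _radial_conductances(self, L, p: ModelParams) -> np.ndarray:
        """Shell-to-shell conductances from the log-radius conduction form.

        Node centres sit at the equal-area radius of each shell; the path
        between neighbours crosses half of each shell with that shell's
        conductivity: ``1/K = ln(r_b/rc_i)/(2π k_i L) + ln(rc_o/r_b)/(2π k_o L)``.
        """
        r = self.radii
        rc = np.empty_like(r)
        rc[..., 0] = r[..., 0] / np.sqrt(2.0)
        for j in range(1, 4):
            rc[..., j] = np.sqrt((r[..., j - 1] ** 2 + r[..., j] ** 2) / 2.0)
        k = p.conductivity
        K = np.empty(r.shape[:-1] + (3,))
        for j in range(3):
            inner = np.log(np.maximum(r[..., j] / rc[..., j], 1.0 + 1e-12)) / (
                2.0 * np.pi * k[j] * L
            )
            outer = np.log(np.maximum(rc[..., j + 1] / r[..., j], 1.0 + 1e-12)) / (
                2.0 * np.pi * k[j + 1] * L
            )
            K[..., j] = 1.0 / (inner + outer)
        return K

    def metabolic_sources(self, met_rate: np.ndarray, temperatures=None) -> np.ndarray:
        """Distribute whole-body heat production ``met_rate`` (B,) over nodes.

        The basal share follows the basal distribution factors and node
        split; anything above basal is exercise heat deposited in working
        muscle.  Rates below basal scale the basal pattern down uniformly.
        When ``temperatures`` (B,6,4) is given, the basal share carries the
        van't Hoff (Q10) temperature dependence: local heat production
        scales as ``q10^((T - 37)/10)``, so cooling tissue produces less
        heat — the slow positive feedback that drives late hypothermia.
        """
        scale = np.minimum(met_rate / np.maximum(self.basal_met, 1e-12), 1.0)
        extra = np.clip(met_rate - self.basal_met, 0.0, None)
        q = self.basal_met_node * scale[:, None, None]
        if temperatures is not None:
            q10 = self.params.raw["tissue"].get("q10", 2.0)
            q = q * q10 ** ((temperatures - 37.0) / 10.0)
        q[:, :, 1] += extra[:, None] * self.params.activity_muscle_split[None, :]
        return q

    # -- passive heat-balance rates ---------------------------------------

    def passive_rates(
        self,
        T: np.ndarray,
        T_blood: np.ndarray,
        *,
        q_source: np.ndarray,
        skin_flow_WK: np.ndarray,
        interior_flow_WK: np.ndarray,
        wettedness: np.ndarray,
        T_amb: np.ndarray,
        P_amb: np.ndarray,
        rct_total: np.ndarray,
        ret_total: np.ndarray,
        q_resp: np.ndarray,
    ):
        """Temperature derivatives of the passive network.

        Parameters are batched arrays: ``T`` (B,6,4), ``T_blood`` (B,),
        ``q_source`` (B,6,4) total heat generation per node (basal + activity
        + shivering), ``skin_flow_WK`` (B,6) skin perfusion in W/K,
        ``interior_flow_WK`` (B,6,2) core/muscle perfusion in W/K,
        ``wettedness`` (B,6), ambient temperature/vapour pressure (B,),
        per-segment total resistances (B,6) and respiratory loss (B,)
        (charged to the trunk core).

        Returns ``(dT, dT_blood, q_dry, q_evap)`` with derivatives in K/s and
        whole-body losses in W.
        """
        K = self.conductance
        # conduction fluxes between shells, positive outward
        flux = K * (T[..., :3] - T[..., 1:])  # (B,6,3)
        q_cond = np.zeros_like(T)
        q_cond[..., 0] = -flux[..., 0]
        q_cond[..., 1] = flux[..., 0] - flux[..., 1]
        q_cond[..., 2] = flux[..., 1] - flux[..., 2]
        q_cond[..., 3] = flux[..., 2]

        # blood convective exchange with the central pool
        W = np.zeros_like(T)
        W[..., 0] = interior_flow_WK[..., 0]
        W[..., 1] = interior_flow_WK[..., 1]
        W[..., 3] = skin_flow_WK
        q_blood = W * (T_blood[:, None, None] - T)
        dT_blood = -q_blood.sum(axis=(1, 2)) / self.blood_capacity

        # environmental exchange at the skin
        T_skin = T[..., 3]
        q_dry_seg = (T_skin - T_amb[:, None]) * self.area / rct_total
        p_sat = saturation_vapour_pressure(T_skin)
        q_evap_seg = (
            wettedness * np.clip(p_sat - P_amb[:, None], 0.0, None) * self.area / ret_total
        )

        q_env = np.zeros_like(T)
        q_env[..., 3] = q_dry_seg + q_evap_seg

        q_net = q_source + q_cond + q_blood - q_env
        q_net[:, 1, 0] -= q_resp  # respiratory loss from the trunk core
        dT = q_net / self.capacity
        return dT, dT_blood, q_dry_seg.sum(axis=1), q_evap_seg.sum(axis=1)

    def segment_geometry(self, b: int = 0) -> list[SegmentGeometry]:
        """Materialise :class:`SegmentGeometry` records for batch element ``b``."""
        out = []
        for i, seg in enumerate(SEGMENTS):
            out.append(
                SegmentGeometry(
                    segment=seg,
                    surface_area=float(self.area[b, i]),
                    volume=float(self.volume[b, i]),
                    length=float(self.length[b, i]),
                    outer_radius=float(self.outer_radius[b, i]),
                    compartment_radii=tuple(float(x) for x in self.radii[b, i]),
                    degenerate=bool(self.degenerate[i]),
                )
            )
        return out


def build_segments(
    anthropometry: Anthropometry,
    factors: DistributionFactors | None = None,
    params: ModelParams | None = None,
) -> SegmentSet:
    """Build the six segment cylinders for one individual.

    Segment areas and volumes are the whole-body values times the
    distribution factors, so they sum to the DuBois surface area and the
    density-derived body volume exactly; each cylinder's length and radius
    solve its area/volume pair exactly.
    """
    body = ThermalBody(
        anthropometry.height,
        anthropometry.mass,
        anthropometry.fat_fraction,
        params=params,
        factors=factors,
    )
    return SegmentSet(body.segment_geometry(0), body)


# ---------------------------------------------------------------------------
# Boundary heat-loss primitives
# ---------------------------------------------------------------------------


def dry_heat_loss(
    skin_temp: float, env: Environment, total_thermal_resistance: float, area: float
) -> float:
    """Dry (convective + radiative) heat loss through a clothed surface, W.

    ``(T_skin − T_ambient) · A / R_total``; positive when heat leaves the body.
    """
    if total_thermal_resistance <= 0:
        raise ValidationError("total_thermal_resistance must be > 0")
    return (skin_temp - env.ambient_temp) * area / total_thermal_resistance


def evaporative_heat_loss(
    skin_temp: float,
    wettedness: float,
    env: Environment,
    total_evap_resistance: float,
    area: float,
) -> float:
    """Evaporative heat loss from partially wet skin, W.

    ``w · (P_sat(T_skin) − P_ambient) · A / R_e,total``, clamped at zero when
    the ambient vapour pressure exceeds skin saturation (no condensation
    gain is modelled).
    """
    if not 0.0 <= wettedness <= 1.0:
        raise ValidationError(f"wettedness {wettedness} outside [0, 1]")
    if total_evap_resistance <= 0:
        raise ValidationError("total_evap_resistance must be > 0")
    gradient = saturation_vapour_pressure(skin_temp) - env.vapour_pressure
    return wettedness * max(gradient, 0.0) * area / total_evap_resistance


def passive_derivatives(
    state: BodyState,
    effectors,
    env: Environment,
    res,
    geom: SegmentSet,
    metabolic_rate: float | None = None,
):
    """Full passive heat-balance derivative of one individual's state.

    ``effectors`` is a :class:`~coweda.control.EffectorOutputs` (zeroed
    effectors give the pure passive system), ``res`` an
    :class:`~coweda.clothing.EnsembleResistances` with totals filled, and
    ``geom`` the :class:`SegmentSet` from :func:`build_segments`.
    ``metabolic_rate`` is the whole-body heat production in W (``None`` →
    basal; ``0`` switches all sources off, including the
    metabolism-proportional perfusion and respiratory loss).

    Returns ``(dT, dT_blood)`` in K/s with ``dT`` shaped 6x4.
    """
    body = geom.body
    p = body.params
    if res.rct_total is None or res.ret_total is None:
        raise ConfigurationError("res must have total resistances filled")
    T = state.temperatures[None, ...]
    if not np.all(np.isfinite(T)):
        raise ValidationError("non-finite temperature in state")
    Tb = np.array([state.blood_temperature])

    M = body.basal_met if metabolic_rate is None else np.array([float(metabolic_rate)])
    q_source = body.metabolic_sources(M, T)
    shiv = float(np.atleast_1d(effectors.shivering_heat)[0])
    q_source[:, :, 1] += shiv * body.muscle_share

    skin_flow = np.atleast_2d(np.asarray(effectors.skin_blood_flow, dtype=float))
    skin_flow_WK = skin_flow * body.flow_to_WK
    interior_flow_WK = (
        p.perfusion_per_watt * np.stack([q_source[..., 0], q_source[..., 1]], axis=-1)
    )
    wet = np.atleast_2d(np.asarray(effectors.wettedness, dtype=float))

    if env.medium == "water":
        q_resp_total = 0.0 * M
    else:
        r = p.respiration
        q_resp_total = M * (
            r["dry_coeff"] * max(r["ref_temp"] - env.air_temp, 0.0)
            + r["latent_coeff"] * max(r["ref_vp_kPa"] - env.vapour_pressure / 1000.0, 0.0)
        )

    dT, dTb, _, _ = body.passive_rates(
        T,
        Tb,
        q_source=q_source,
        skin_flow_WK=skin_flow_WK,
        interior_flow_WK=interior_flow_WK,
        wettedness=wet,
        T_amb=np.array([env.ambient_temp]),
        P_amb=np.array([0.0 if env.medium == "water" else env.vapour_pressure]),
        rct_total=np.asarray(res.rct_total)[None, :],
        ret_total=np.asarray(res.ret_total)[None, :],
        q_resp=q_resp_total,
    )
    return dT[0], float(dTb[0])
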