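"""Clothing biophysics: garments, ensembles and boundary-layer resistances.

A garment carries an intrinsic thermal resistance (m²·K/W) and an intrinsic
evaporative resistance (m²·Pa/W) for each body segment it covers.  An
ensemble is an ordered stack of garments; its per-segment intrinsic
resistance is the series sum over the covering layers, and its whole-body
insulation is the area-weighted mean expressed in clo (1 clo = 0.155 m²·K/W).

The resistance the body actually sees is the intrinsic resistance plus a
boundary (surface-film) resistance.  In air the film is a combined
convective/radiative layer that thins with wind; in water it is a thin
convective film two orders of magnitude smaller, and flooded clothing keeps
only a documented fraction of its dry insulation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .params import (
    CLO_TO_M2KW,
    N_SEGMENTS,
    SEGMENTS,
    ConfigurationError,
    ModelParams,
    ValidationError,
    default_params,
)

__all__ = [
    "Garment",
    "EnsembleResistances",
    "load_garment_database",
    "aggregate_ensemble",
    "boundary_layer_resistance",
    "total_resistances",
    "clo_to_si",
    "si_to_clo",
]

_SEG_INDEX = {name: i for i, name in enumerate(SEGMENTS)}

CSV_COLUMNS = ("id", "name", "layer_order", "segment", "rct_m2KW", "ret_m2PaW")


def clo_to_si(clo: float) -> float:
    """Convert clothing insulation from clo to m²·K/W."""
    return clo * CLO_TO_M2KW


def si_to_clo(rct: float) -> float:
    """Convert clothing insulation from m²·K/W to clo."""
    return rct / CLO_TO_M2KW


@dataclass(frozen=True)
class Garment:
    """A single clothing item with per-covered-segment resistances.

    ``rct`` and ``ret`` map segment name → intrinsic thermal (m²·K/W) and
    evaporative (m²·Pa/W) resistance; ``layer_order`` is 1 for the layer worn
    next to the skin.
    """

    id: str
    name: str
    layer_order: int
    rct: Mapping[str, float]
    ret: Mapping[str, float]

    def __post_init__(self):
        if not self.id:
            raise ValidationError("garment id must be non-empty")
        if int(self.layer_order) < 1:
            raise ValidationError(f"garment {self.id}: layer_order must be >= 1")
        if not self.rct:
            raise ValidationError(f"garment {self.id}: coverage must be non-empty")
        if set(self.rct) != set(self.ret):
            raise ValidationError(f"garment {self.id}: rct and ret cover different segments")
        for seg, val in self.rct.items():
            if seg not in _SEG_INDEX:
                raise ValidationError(f"garment {self.id}: unknown segment {seg!r}")
            if val < 0:
                raise ValidationError(f"garment {self.id}: rct[{seg}] must be >= 0, got {val}")
        for seg, val in self.ret.items():
            if val <= 0:
                raise ValidationError(f"garment {self.id}: ret[{seg}] must be > 0, got {val}")

    @property
    def coverage(self) -> frozenset[str]:
        return frozenset(self.rct)


@dataclass
class EnsembleResistances:
    """Per-segment resistances of a worn ensemble, in segment order.

    ``rct``/``ret`` are the intrinsic clothing resistances, ``rct_air``/
    ``ret_air`` the boundary films and ``rct_total``/``ret_total`` their
    series sums.  Boundary and total arrays are filled by
    :func:`total_resistances`; until then they are ``None``.
    """

    rct: np.ndarray
    ret: np.ndarray
    rct_air: np.ndarray | None = None
    ret_air: np.ndarray | None = None
    rct_total: np.ndarray | None = None
    ret_total: np.ndarray | None = None
    area_weights: np.ndarray = field(default_factory=lambda: default_params().area_fraction)

    @property
    def whole_body_clo(self) -> float:
        """Area-weighted whole-body intrinsic insulation, clo."""
        return si_to_clo(float(np.dot(self.area_weights, self.rct)))


# ---------------------------------------------------------------------------
# Database I/O
# ---------------------------------------------------------------------------


def load_garment_database(path: str | Path) -> list[Garment]:
    """Load a garment database from CSV or JSON.

    CSV: UTF-8, header row mandatory, one row per garment × segment, columns
    ``id,name,layer_order,segment,rct_m2KW,ret_m2PaW``.  JSON: a list of
    objects with ``id``, ``name``, ``layer_order`` and per-segment ``rct`` /
    ``ret`` maps.  Duplicate ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        garments = [
            Garment(
                id=str(rec["id"]),
                name=str(rec.get("name", rec["id"])),
                layer_order=int(rec["layer_order"]),
                rct=dict(rec["rct"]),
                ret=dict(rec["ret"]),
            )
            for rec in records
        ]
    else:
        garments = _load_csv(path)
    seen: set[str] = set()
    for g in garments:
        if g.id in seen:
            raise ConfigurationError(f"duplicate garment id {g.id!r} in {path}")
        seen.add(g.id)
    return garments


def _load_csv(path: Path) -> list[Garment]:
    rows: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(
            CSV_COLUMNS
        ):
            raise ConfigurationError(
                f"{path}: expected header {','.join(CSV_COLUMNS)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            gid = row["id"].strip()
            try:
                rct = float(row["rct_m2KW"])
                ret = float(row["ret_m2PaW"])
                order = int(row["layer_order"])
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(f"{path}:{lineno}: unparsable numeric field: {exc}")
            if rct < 0:
                raise ConfigurationError(f"{path}:{lineno}: rct_m2KW must be >= 0, got {rct}")
            if ret <= 0:
                raise ConfigurationError(f"{path}:{lineno}: ret_m2PaW must be > 0, got {ret}")
            seg = row["segment"].strip()
            if seg not in _SEG_INDEX:
                raise ConfigurationError(f"{path}:{lineno}: unknown segment {seg!r}")
            rec = rows.setdefault(
                gid, {"name": row["name"].strip(), "layer_order": order, "rct": {}, "ret": {}}
            )
            if rec["layer_order"] != order:
                raise ConfigurationError(
                    f"{path}:{lineno}: garment {gid!r} has inconsistent layer_order"
                )
            if seg in rec["rct"]:
                raise ConfigurationError(f"{path}:{lineno}: duplicate segment {seg!r} for {gid!r}")
            rec["rct"][seg] = rct
            rec["ret"][seg] = ret
    return [Garment(id=gid, **rec) for gid, rec in rows.items()]


def save_garment_database(garments: Iterable[Garment], path: str | Path) -> None:
    """Write a garment list to the documented CSV schema."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for g in garments:
            for seg in SEGMENTS:
                if seg in g.rct:
                    writer.writerow(
                        [g.id, g.name, g.layer_order, seg, repr(g.rct[seg]), repr(g.ret[seg])]
                    )


# ---------------------------------------------------------------------------
# Ensemble aggregation
# ---------------------------------------------------------------------------


def aggregate_ensemble(
    garments: Sequence[Garment], params: ModelParams | None = None
) -> EnsembleResistances:
    """Compose garments into per-segment intrinsic ensemble resistances.

    Resistances of the covering layers add in series per segment; uncovered
    segments are bare (zero intrinsic resistance).  The result depends only
    on each garment's ``layer_order``, not on list order, and two garments
    sharing a layer_order on the same segment are rejected as a conflict.
    """
    params = params or default_params()
    rct = np.zeros(N_SEGMENTS)
    ret = np.zeros(N_SEGMENTS)
    occupied: dict[tuple[str, int], str] = {}
    for g in sorted(garments, key=lambda g: (g.layer_order, g.id)):
        for seg in g.rct:
            key = (seg, g.layer_order)
            if key in occupied:
                raise ConfigurationError(
                    f"garments {occupied[key]!r} and {g.id!r} both occupy layer "
                    f"{g.layer_order} on segment {seg!r}"
                )
            occupied[key] = g.id
            i = _SEG_INDEX[seg]
            rct[i] += g.rct[seg]
            ret[i] += g.ret[seg]
    return EnsembleResistances(rct=rct, ret=ret, area_weights=params.area_fraction.copy())


# ---------------------------------------------------------------------------
# Boundary layers and totals
# ---------------------------------------------------------------------------


def boundary_layer_resistance(
    wind_speed: float, segment: str | None = None, params: ModelParams | None = None
) -> tuple[float, float]:
    """Air boundary-layer resistances ``(rct_air, ret_air)`` for one segment.

    The convective coefficient follows ``h_c = a·v^b`` (default 8.3·v^0.6,
    W/m²·K) in parallel with a constant radiative coefficient; small
    extremities carry a film-factor > 1 (thinner film).  The thermal film is
    clamped below at a configured minimum so it never vanishes at high wind,
    and the wind speed is floored at a still-air value.  ``segment=None``
    returns the area-weighted whole-body mean.
    """
    if wind_speed < 0:
        raise ValidationError("wind_speed must be >= 0")
    params = params or default_params()
    b = params.boundary
    if segment is None:
        pairs = [
            boundary_layer_resistance(wind_speed, seg, params) for seg in SEGMENTS
        ]
        w = params.area_fraction
        return (
            float(np.dot(w, [p[0] for p in pairs])),
            float(np.dot(w, [p[1] for p in pairs])),
        )
    if segment not in _SEG_INDEX:
        raise ValidationError(f"unknown segment {segment!r}")
    factor = b["segment_film_factor"][_SEG_INDEX[segment]]
    v = max(wind_speed, b["min_wind_speed"])
    h_c = b["convective_coeff"] * v ** b["convective_exponent"] * factor
    h_r = b["radiative_coeff"]
    rct_air = max(1.0 / (h_c + h_r), b["min_resistance"])
    ret_air = 1.0 / (b["lewis_ratio"] * h_c)
    return float(rct_air), float(ret_air)


def total_resistances(
    intrinsic: EnsembleResistances,
    wind_speed: float,
    medium: str = "air",
    params: ModelParams | None = None,
) -> EnsembleResistances:
    """Fill in boundary and total resistances for a given wind speed/medium.

    In air, total = intrinsic + air film per segment.  In water the film is
    replaced by a thin convective water film (1/h_water) and the flooded
    clothing retains only ``wet_insulation_factor`` of its dry thermal
    resistance; evaporation is impossible, so the evaporative path is closed
    with an effectively infinite resistance.
    """
    params = params or default_params()
    b = params.boundary
    if medium == "air":
        films = np.array(
            [boundary_layer_resistance(wind_speed, seg, params) for seg in SEGMENTS]
        )
        rct_air, ret_air = films[:, 0], films[:, 1]
        rct = intrinsic.rct.copy()
        ret = intrinsic.ret.copy()
    elif medium == "water":
        rct_air = np.full(N_SEGMENTS, 1.0 / b["water_film_coeff"])
        ret_air = np.full(N_SEGMENTS, 1e12)
        rct = intrinsic.rct * b["wet_insulation_factor"]
        ret = np.full(N_SEGMENTS, 1e12)
    else:
        raise ValidationError(f"medium must be 'air' or 'water', got {medium!r}")
    return EnsembleResistances(
        rct=rct,
        ret=ret,
        rct_air=rct_air,
        ret_air=ret_air,
        rct_total=rct + rct_air,
        ret_total=ret + ret_air,
        area_weights=intrinsic.area_weights.copy(),
    )
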