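"""Synthetic clothing database and example inputs.

The military garment measurements behind the original decision aid are not
public, so the package ships a synthetic 12-garment database with physically
plausible per-segment resistances.  The values are calibration data, chosen
so that the named ensembles land at documented whole-body insulations:

- ``moderate_cold`` — hat, balaclava, midweight shirt and drawers, fleece
  jacket, wind jacket, shell pants and intermediate cold-wet boots;
  aggregates to ~1.9 clo whole-body intrinsic insulation.
- ``acu`` — a combat-uniform-like coat+trouser garment with boots, ~0.9 clo.
- ``light`` — midweight base layer only, ~0.5 clo; also the default
  (flooded) clothing for immersion survival runs.

Three gloves of strictly increasing hand insulation support the
manual-performance comparisons (no glove / liner / insulated / arctic
mitten).  Metadata note: resistances are quoted as intrinsic values under
still-air reference conditions (0.4 m/s).
"""

from __future__ import annotations

import json
from pathlib import Path
from importlib import resources

from .clothing import Garment, aggregate_ensemble, load_garment_database, save_garment_database
from .params import ConfigurationError, default_params

__all__ = [
    "default_garments",
    "fixture_ensembles",
    "shipped_database_path",
    "load_default_database",
    "generate_fixtures",
]


def _g(gid, name, order, segs, rct, im):
    """Garment helper: evaporative resistance from a permeability index."""
    lewis = 0.0165  # K/Pa
    rct_map = dict(zip(segs, rct))
    ret_map = {s: r / (im * lewis) if r > 0 else 1.0 for s, r in rct_map.items()}
    return Garment(id=gid, name=name, layer_order=order, rct=rct_map, ret=ret_map)


def default_garments() -> list[Garment]:
    """The 12 synthetic garments (intrinsic resistances, m²·K/W)."""
    return [
        _g("balaclava", "Fleece balaclava", 1, ["head"], [0.08], 0.45),
        _g("hat", "Insulated hat", 2, ["head"], [0.10], 0.40),
        _g("shirt_mid", "Midweight cold weather shirt", 1, ["trunk", "arms"], [0.12, 0.06], 0.45),
        _g("drawers_mid", "Midweight cold weather drawers", 1, ["legs"], [0.08], 0.45),
        _g("fleece_jacket", "Fleece jacket", 2, ["trunk", "arms"], [0.22, 0.09], 0.42),
        _g("wind_jacket", "Wind jacket", 3, ["trunk", "arms"], [0.142, 0.05], 0.30),
        _g("pants_shell", "Cold weather pants", 2, ["legs"], [0.10], 0.35),
        _g("boots_icw", "Intermediate cold wet boots", 1, ["feet"], [0.35], 0.25),
        _g("acu_uniform", "Combat uniform with patrol cap", 2,
           ["trunk", "arms", "legs", "head"], [0.15, 0.12, 0.13, 0.06], 0.40),
        _g("glove_liner", "Glove liner", 1, ["hands"], [0.06], 0.45),
        _g("glove_insulated", "Insulated glove", 2, ["hands"], [0.16], 0.35),
        _g("mitten_arctic", "Arctic mitten", 3, ["hands"], [0.30], 0.30),
    ]


def fixture_ensembles() -> dict[str, list[str]]:
    """Named ensembles as ordered garment-id lists."""
    return {
        "light": ["shirt_mid", "drawers_mid"],
        "acu": ["acu_uniform", "boots_icw"],
        "moderate_cold": [
            "balaclava", "hat", "shirt_mid", "drawers_mid",
            "fleece_jacket", "wind_jacket", "pants_shell", "boots_icw",
        ],
    }


def shipped_database_path() -> Path:
    """Path of the garment CSV shipped inside the package."""
    return Path(str(resources.files("coweda.data").joinpath("garments.csv")))


def load_default_database() -> list[Garment]:
    """Load the shipped fixture database (falls back to the in-code table)."""
    path = shipped_database_path()
    if path.exists():
        return load_garment_database(path)
    return default_garments()


def resolve_ensemble(name: str, garments=None, extra_ids: list[str] | None = None):
    """Aggregate a named fixture ensemble (optionally with extra garments).

    Raises a configuration error listing the available names for unknown
    ensembles.
    """
    garments = garments if garments is not None else load_default_database()
    by_id = {g.id: g for g in garments}
    ensembles = fixture_ensembles()
    if name not in ensembles:
        raise ConfigurationError(
            f"unknown ensemble {name!r}; available: {', '.join(sorted(ensembles))}"
        )
    ids = list(ensembles[name]) + list(extra_ids or [])
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise ConfigurationError(
            f"ensemble {name!r} references unknown garments {missing}; "
            f"available ids: {', '.join(sorted(by_id))}"
        )
    return aggregate_ensemble([by_id[i] for i in ids])


def generate_fixtures(output_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the fixture database, parameter file and example scenarios.

    The fixture content is deterministic calibration data, so regeneration
    with the same seed is bit-identical; the seed is echoed into the example
    scenarios for downstream population sampling.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = out / "garments.csv"
    save_garment_database(default_garments(), db)
    par = out / "params.json"
    default_params().to_json(par)
    scen = out / "example_scenarios.json"
    scen.write_text(
        json.dumps(
            {
                "seed": int(seed),
                "endurance_grid": {
                    "air_temps_C": [2, -9, -21, -32, -43],
                    "wind_speeds_ms": [2, 11, 20],
                    "activity": "rest",
                    "ensembles": ["acu", "moderate_cold"],
                    "horizon_min": 1440,
                },
                "immersion": {
                    "water_temps_C": [0, 5, 10, 15, 20],
                    "ensemble": "light",
                    "population_n": 100,
                },
            },
            indent=2,
        )
        + "\n"
    )
    return {"garments": db, "params": par, "scenarios": scen}
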