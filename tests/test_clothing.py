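"""Garment database, ensemble aggregation and boundary layers."""

import numpy as np
import pytest

import coweda as cw
from coweda.clothing import (
    CSV_COLUMNS,
    Garment,
    aggregate_ensemble,
    boundary_layer_resistance,
    load_garment_database,
    save_garment_database,
    total_resistances,
)
from coweda.fixtures import shipped_database_path
from coweda.params import SEGMENTS, ConfigurationError, ValidationError, CLO_TO_M2KW


class TestDatabase:
    def test_shipped_database_loads_12_garments(self):
        garments = load_garment_database(shipped_database_path())
        assert len(garments) == 12
        assert all(g.coverage for g in garments)

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(",".join(CSV_COLUMNS) + "\n")
        assert load_garment_database(p) == []

    def test_negative_rct_rejected_with_field_name(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            ",".join(CSV_COLUMNS) + "\n" + "x,X,1,trunk,-0.1,15\n"
        )
        with pytest.raises(ConfigurationError, match="rct"):
            load_garment_database(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.json"
        rec = {"id": "a", "name": "A", "layer_order": 1,
               "rct": {"trunk": 0.1}, "ret": {"trunk": 15.0}}
        import json

        p.write_text(json.dumps([rec, rec]))
        with pytest.raises(ConfigurationError, match="duplicate"):
            load_garment_database(p)

    def test_unknown_segment_rejected(self, tmp_path):
        p = tmp_path / "seg.csv"
        p.write_text(",".join(CSV_COLUMNS) + "\n" + "x,X,1,tail,0.1,15\n")
        with pytest.raises(ConfigurationError, match="tail"):
            load_garment_database(p)

    def test_csv_round_trip(self, tmp_path, garments):
        p = tmp_path / "db.csv"
        save_garment_database(garments, p)
        loaded = load_garment_database(p)
        by_id = {g.id: g for g in loaded}
        assert set(by_id) == {g.id for g in garments}
        for g in garments:
            assert by_id[g.id].rct == pytest.approx(g.rct)
            assert by_id[g.id].layer_order == g.layer_order


class TestAggregation:
    def test_no_garments_all_bare(self):
        ens = aggregate_ensemble([])
        assert np.all(ens.rct == 0.0)
        assert ens.whole_body_clo == 0.0

    def test_single_garment_identity(self, garments):
        g = next(g for g in garments if g.id == "boots_icw")
        ens = aggregate_ensemble([g])
        i = SEGMENTS.index("feet")
        assert ens.rct[i] == pytest.approx(g.rct["feet"])
        assert ens.ret[i] == pytest.approx(g.ret["feet"])
        assert np.all(np.delete(ens.rct, i) == 0.0)

    def test_series_sum(self):
        a = Garment("a", "A", 1, {"trunk": 0.078}, {"trunk": 12.0})
        b = Garment("b", "B", 2, {"trunk": 0.108}, {"trunk": 18.0})
        ens = aggregate_ensemble([a, b])
        assert ens.rct[SEGMENTS.index("trunk")] == pytest.approx(0.186)

    def test_layer_conflict_rejected(self):
        a = Garment("a", "A", 1, {"trunk": 0.1}, {"trunk": 12.0})
        b = Garment("b", "B", 1, {"trunk": 0.1}, {"trunk": 12.0})
        with pytest.raises(ConfigurationError, match="layer"):
            aggregate_ensemble([a, b])

    def test_permutation_invariance(self, garments):
        import itertools

        ids = ["shirt_mid", "fleece_jacket", "wind_jacket"]
        sel = [g for g in garments if g.id in ids]
        reference = aggregate_ensemble(sel).rct
        for perm in itertools.permutations(sel):
            assert np.allclose(aggregate_ensemble(list(perm)).rct, reference)

    def test_layer_inclusion_orders_resistance(self, garments):
        by_id = {g.id: g for g in garments}
        inner = aggregate_ensemble([by_id["shirt_mid"]])
        outer = aggregate_ensemble([by_id["shirt_mid"], by_id["fleece_jacket"]])
        assert np.all(outer.rct >= inner.rct)
        assert outer.whole_body_clo > inner.whole_body_clo

    def test_clo_unit_round_trip(self):
        assert cw.si_to_clo(cw.clo_to_si(1.37)) == pytest.approx(1.37, abs=1e-12)
        assert cw.clo_to_si(1.0) == CLO_TO_M2KW


class TestBoundaryLayer:
    def test_still_air_reference(self, params):
        rct, _ = boundary_layer_resistance(0.4, None, params)
        assert rct == pytest.approx(0.104, rel=0.02)

    def test_monotone_decreasing_in_wind(self, params):
        values = [boundary_layer_resistance(v, "trunk", params)[0] for v in (0.4, 2, 5, 11, 20)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_floor_at_extreme_wind(self, params):
        rct, _ = boundary_layer_resistance(500.0, "trunk", params)
        assert rct == params.boundary["min_resistance"]

    def test_extremities_thinner_film(self, params):
        assert (
            boundary_layer_resistance(2.0, "hands", params)[0]
            < boundary_layer_resistance(2.0, "trunk", params)[0]
        )

    def test_negative_wind_rejected(self):
        with pytest.raises(ValidationError):
            boundary_layer_resistance(-1.0, "trunk")


class TestTotals:
    def test_bare_segment_total_is_boundary(self, params):
        ens = aggregate_ensemble([])
        tot = total_resistances(ens, 2.0, "air", params)
        for i, seg in enumerate(SEGMENTS):
            assert tot.rct_total[i] == pytest.approx(
                boundary_layer_resistance(2.0, seg, params)[0]
            )

    def test_adding_garment_never_decreases_total(self, garments, params):
        by_id = {g.id: g for g in garments}
        base = total_resistances(
            aggregate_ensemble([by_id["shirt_mid"]]), 2.0, "air", params
        )
        for gid in by_id:
            if gid == "shirt_mid":
                continue
            more = total_resistances(
                aggregate_ensemble([by_id["shirt_mid"], by_id[gid]]), 2.0, "air", params
            )
            assert np.all(more.rct_total >= base.rct_total - 1e-12)

    def test_moderate_fixture_whole_body_clo(self, moderate_ensemble):
        assert moderate_ensemble.whole_body_clo == pytest.approx(1.9, abs=0.05)

    def test_water_film_replaces_air_and_closes_evaporation(
        self, light_ensemble, params
    ):
        air = total_resistances(light_ensemble, 0.4, "air", params)
        water = total_resistances(light_ensemble, 0.4, "water", params)
        assert np.all(water.rct_air < air.rct_air / 5)
        assert np.all(water.ret_total > 1e9)
        assert np.all(water.rct < light_ensemble.rct + 1e-12)

    def test_glove_fixtures_strictly_ordered(self, garments):
        by_id = {g.id: g for g in garments}
        hands = [by_id[g].rct["hands"] for g in ("glove_liner", "glove_insulated", "mitten_arctic")]
        assert hands[0] < hands[1] < hands[2]
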