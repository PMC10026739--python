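"""Body geometry and passive heat-balance primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coweda as cw
from coweda.body import ThermalBody, body_density
from coweda.control import EffectorOutputs
from coweda.params import SEGMENTS, ValidationError, ConfigurationError


class TestBodySurfaceArea:
    @pytest.mark.parametrize(
        "height,mass,expected",
        [(180.0, 74.4, 1.936), (170.0, 70.0, 1.810)],
    )
    def test_dubois_values(self, height, mass, expected):
        a = cw.Anthropometry(height, mass, 0.15)
        assert cw.body_surface_area(a) == pytest.approx(expected, abs=5e-4)

    @given(
        h=st.floats(110, 220),
        m=st.floats(35, 190),
        dm=st.floats(1.0, 10.0),
        dh=st.floats(1.0, 9.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_height_and_mass(self, h, m, dm, dh):
        base = cw.body_surface_area(cw.Anthropometry(h, m, 0.2))
        assert cw.body_surface_area(cw.Anthropometry(h, m + dm, 0.2)) > base
        assert cw.body_surface_area(cw.Anthropometry(h + dh, m, 0.2)) > base

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(height=90, mass=70, fat_fraction=0.2), "height"),
            (dict(height=180, mass=20, fat_fraction=0.2), "mass"),
            (dict(height=180, mass=70, fat_fraction=0.7), "fat_fraction"),
        ],
    )
    def test_out_of_range_names_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            cw.Anthropometry(**kwargs)


class TestSegments:
    def test_geometry_closure(self, reference_adult, params):
        segs = cw.build_segments(reference_adult)
        bsa = cw.body_surface_area(reference_adult)
        vol = reference_adult.mass / body_density(reference_adult.fat_fraction)
        assert sum(s.surface_area for s in segs) == pytest.approx(bsa, rel=1e-9)
        assert sum(s.volume for s in segs) == pytest.approx(vol, rel=1e-9)

    def test_cylinder_solves_area_volume_pair(self, reference_adult):
        for s in cw.build_segments(reference_adult):
            assert np.pi * s.outer_radius**2 * s.length == pytest.approx(
                s.volume, rel=1e-9
            )
            assert 2 * np.pi * s.outer_radius * s.length == pytest.approx(
                s.surface_area, rel=1e-9
            )
            radii = np.asarray(s.compartment_radii)
            assert np.all(np.diff(radii) > 0)
            assert radii[-1] == pytest.approx(s.outer_radius)

    def test_trunk_area_fraction(self, reference_adult, params):
        segs = cw.build_segments(reference_adult)
        trunk = segs[SEGMENTS.index("trunk")]
        assert trunk.surface_area == pytest.approx(0.36 * 1.936, abs=2e-3)

    def test_single_segment_factors_flag_degenerate(self, reference_adult, params):
        f = cw.DistributionFactors(
            area=[0, 1, 0, 0, 0, 0],
            volume=[0, 1, 0, 0, 0, 0],
            basal_met=[0, 1, 0, 0, 0, 0],
            basal_skin_flow=[0, 1, 0, 0, 0, 0],
        )
        segs = cw.build_segments(reference_adult, factors=f)
        trunk = segs[1]
        assert trunk.surface_area == pytest.approx(
            cw.body_surface_area(reference_adult), rel=1e-6
        )
        assert not trunk.degenerate
        assert all(segs[i].degenerate for i in (0, 2, 3, 4, 5))

    def test_bad_factors_rejected(self):
        with pytest.raises(ConfigurationError):
            cw.DistributionFactors(
                area=[0.5, 0.5, 0.1, 0, 0, 0],
                volume=[0.07, 0.5, 0.13, 0.26, 0.01, 0.03],
                basal_met=[0.16, 0.56, 0.1, 0.15, 0.015, 0.015],
                basal_skin_flow=[0.12, 0.4, 0.13, 0.23, 0.06, 0.06],
            )


class TestBoundaryLosses:
    def test_dry_zero_gradient(self):
        env = cw.Environment(air_temp=30.0)
        assert cw.dry_heat_loss(30.0, env, 0.31, 1.0) == 0.0

    def test_dry_hand_value(self):
        env = cw.Environment(air_temp=-7.0)
        # 40 K gradient over 0.31 m2K/W on 1 m2
        assert cw.dry_heat_loss(33.0, env, 0.31, 1.0) == pytest.approx(129.0, abs=0.1)

    def test_dry_resistance_proportionality(self):
        env = cw.Environment(air_temp=0.0)
        assert cw.dry_heat_loss(33.0, env, 0.4, 1.0) == pytest.approx(
            cw.dry_heat_loss(33.0, env, 0.2, 1.0) / 2
        )

    def test_dry_bad_resistance(self):
        with pytest.raises(ValidationError):
            cw.dry_heat_loss(33.0, cw.Environment(air_temp=0.0), 0.0, 1.0)

    def test_evaporative_zero_wettedness(self):
        env = cw.Environment(air_temp=0.0, rh=50.0)
        assert cw.evaporative_heat_loss(33.0, 0.0, env, 500.0, 1.0) == 0.0

    def test_evaporative_linearity_in_wettedness(self):
        env = cw.Environment(air_temp=0.0, rh=50.0)
        half = cw.evaporative_heat_loss(33.0, 0.5, env, 500.0, 1.0)
        assert cw.evaporative_heat_loss(33.0, 1.0, env, 500.0, 1.0) == pytest.approx(
            2 * half
        )

    def test_evaporative_hand_value(self):
        # independent Magnus arithmetic: w (Psat(33) - 0.5 Psat(0)) / 500
        env = cw.Environment(air_temp=0.0, rh=50.0)
        p33 = 610.94 * np.exp(17.625 * 33 / (33 + 243.04))
        p0 = 0.5 * 610.94
        expected = 0.3 * (p33 - p0) / 500.0
        got = cw.evaporative_heat_loss(33.0, 0.3, env, 500.0, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2.84, rel=0.02)

    def test_evaporative_clamped_against_condensation(self):
        env = cw.Environment(air_temp=40.0, rh=100.0)
        assert cw.evaporative_heat_loss(20.0, 0.5, env, 500.0, 1.0) == 0.0

    def test_evaporative_bad_wettedness(self):
        with pytest.raises(ValidationError):
            cw.evaporative_heat_loss(33.0, 1.5, cw.Environment(air_temp=0.0), 500.0, 1.0)


class TestPassiveDerivatives:
    def test_equilibrium_fixed_point(self, reference_adult, light_ensemble, params):
        """Uniform body at air temperature with all sources off is a fixed point."""
        env = cw.Environment(air_temp=20.0, wind_speed=0.4, rh=50.0)
        segs = cw.build_segments(reference_adult)
        res = cw.total_resistances(light_ensemble, env.wind_speed, "air", params)
        state = cw.BodyState(np.full((6, 4), 20.0), blood_temperature=20.0)
        dT, dTb = cw.passive_derivatives(
            state, EffectorOutputs.zero(), env, res, segs, metabolic_rate=0.0
        )
        assert np.all(dT == 0.0)
        assert dTb == 0.0

    def test_warm_skin_cools_with_sources_off(self, reference_adult, light_ensemble, params):
        env = cw.Environment(air_temp=0.0, wind_speed=0.4, rh=50.0)
        segs = cw.build_segments(reference_adult)
        res = cw.total_resistances(light_ensemble, env.wind_speed, "air", params)
        state = cw.BodyState(np.full((6, 4), 30.0), blood_temperature=30.0)
        dT, _ = cw.passive_derivatives(
            state, EffectorOutputs.zero(), env, res, segs, metabolic_rate=0.0
        )
        assert np.all(dT[:, 3] < 0.0)

    def test_single_cylinder_radial_conduction_oracle(self, reference_adult, params):
        """Steady state of an isolated heated cylinder matches the closed form.

        A fixed heat input in the trunk core, no blood flow and no
        evaporation: at steady state the analytic solution is
        T_skin = T_env + Q R/A and successive shells differ by Q over the
        log-annulus conductances, evaluated here independently from the
        boundary radii.
        """
        body = ThermalBody(
            reference_adult.height, reference_adult.mass, reference_adult.fat_fraction
        )
        env_T, Q, R = 10.0, 20.0, 0.2
        B = body.B
        T = np.full((B, 6, 4), env_T)
        Tb = np.array([env_T])
        q_source = np.zeros((B, 6, 4))
        q_source[0, 1, 0] = Q
        rct = np.full((B, 6), R)
        ret = np.full((B, 6), 1e12)
        kwargs = dict(
            q_source=q_source,
            skin_flow_WK=np.zeros((B, 6)),
            interior_flow_WK=np.zeros((B, 6, 2)),
            wettedness=np.zeros((B, 6)),
            T_amb=np.array([env_T]),
            P_amb=np.array([0.0]),
            rct_total=rct,
            ret_total=ret,
            q_resp=np.zeros(B),
        )
        dt = 20.0
        for _ in range(40000):  # ~9 days of model time; well past steady state
            dT, dTb, _, _ = body.passive_rates(T, Tb, **kwargs)
            T = T + dt * dT
            Tb = Tb + dt * dTb

        # independent closed form from the boundary radii
        r1, r2, r3, r4 = body.radii[0, 1]
        L = body.length[0, 1]
        k = params.conductivity
        rc = [r1 / np.sqrt(2)]
        for a, b in [(r1, r2), (r2, r3), (r3, r4)]:
            rc.append(np.sqrt((a**2 + b**2) / 2))
        resist = []
        for j, rb in enumerate([r1, r2, r3]):
            resist.append(
                np.log(rb / rc[j]) / (2 * np.pi * k[j] * L)
                + np.log(rc[j + 1] / rb) / (2 * np.pi * k[j + 1] * L)
            )
        area = body.area[0, 1]
        expected_skin = env_T + Q * R / area
        expected = [expected_skin + Q * sum(resist[j:]) for j in range(3)]
        expected.append(expected_skin)

        assert np.allclose(T[0, 1], expected, atol=0.1)
        # unheated segments relax to the environment temperature
        others = [i for i in range(6) if i != 1]
        assert np.allclose(T[0, others], env_T, atol=0.05)
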