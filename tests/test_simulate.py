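"""Coupled simulation, crossing detection and endurance extraction."""

import numpy as np
import pytest

import coweda as cw
from coweda.params import ValidationError
from coweda.simulate import detect_crossing, endurance_grid


def _scenario(env, activity, ensemble, minutes):
    return cw.ExposureScenario(
        [cw.ExposurePhase(env, cw.Activity(activity), ensemble, minutes)]
    )


class TestDetectCrossing:
    def test_interpolated_falling(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([10.0, 8.0, 6.0, 4.0])
        assert detect_crossing(t, y, 5.0, "falling") == pytest.approx(2.5)

    def test_not_reached(self):
        t = np.array([0.0, 1.0, 2.0])
        assert detect_crossing(t, np.array([10.0, 9.0, 8.0]), 5.0, "falling") is None

    def test_boundary_rule_zero(self):
        t = np.array([0.0, 1.0])
        assert detect_crossing(t, np.array([4.0, 3.0]), 5.0, "falling") == 0.0

    def test_rising(self):
        t = np.array([0.0, 10.0])
        assert detect_crossing(t, np.array([0.0, 1.0]), 0.25, "rising") == pytest.approx(2.5)

    def test_bad_direction(self):
        with pytest.raises(ValidationError):
            detect_crossing(np.array([0.0]), np.array([1.0]), 0.5, "sideways")


class TestManualPerformance:
    @pytest.mark.parametrize("temp,expected", [(15.0, 0.80), (5.0, 0.50), (36.0, 1.00)])
    def test_anchor_points(self, temp, expected):
        assert cw.manual_performance_fraction(temp) == expected

    def test_continuous_and_nondecreasing(self):
        t = np.linspace(-5.0, 40.0, 400)
        f = cw.manual_performance_fraction(t)
        assert np.all(np.diff(f) >= 0)
        assert np.all(np.abs(np.diff(f)) < 0.02)
        assert f.min() == 0.50 and f.max() == 1.00


class TestSimulate:
    def test_thermoneutral_holds_initial_state(self, thermoneutral_run):
        """30 degC, 50 %RH, 0.4 m/s, rest, light ensemble: no drift over 2 h."""
        drift = np.abs(
            thermoneutral_run.temperatures - thermoneutral_run.temperatures[0]
        ).max()
        assert drift < 0.5

    def test_thermoneutral_reaches_nothing(self, thermoneutral_run, thresholds):
        et = cw.endurance_times(thermoneutral_run, thresholds)
        assert et.finger_frostbite_risk is None
        assert et.toe_frostbite_risk is None
        assert et.hypothermia is None
        assert et.comfort_limit is None
        assert et.manual_performance_limit is None

    def test_deep_cold_cools_fingers_monotonically(self, reference_adult, acu_ensemble):
        env = cw.Environment(air_temp=-40.0, wind_speed=2.0, rh=70.0)
        res = cw.simulate(
            _scenario(env, "rest", acu_ensemble, 60.0), reference_adult
        )
        after5 = res.hand_skin[res.time_min >= 5.0]
        assert np.all(np.diff(after5) < 0)

    def test_two_identical_phases_equal_one(self, reference_adult, acu_ensemble):
        env = cw.Environment(air_temp=-15.0, wind_speed=5.0, rh=70.0)
        one = cw.simulate(_scenario(env, "rest", acu_ensemble, 120.0), reference_adult)
        two = cw.simulate(
            cw.ExposureScenario(
                [
                    cw.ExposurePhase(env, cw.Activity("rest"), acu_ensemble, 60.0),
                    cw.ExposurePhase(env, cw.Activity("rest"), acu_ensemble, 60.0),
                ]
            ),
            reference_adult,
        )
        assert np.allclose(one.temperatures[-1], two.temperatures[-1], atol=1e-9)
        assert one.time_min[-1] == pytest.approx(two.time_min[-1])

    def test_phase_concatenation_continuous(self, reference_adult, acu_ensemble, moderate_ensemble):
        cold = cw.Environment(air_temp=-15.0, wind_speed=5.0, rh=70.0)
        scen = cw.ExposureScenario(
            [
                cw.ExposurePhase(cold, cw.Activity("rest"), acu_ensemble, 30.0),
                cw.ExposurePhase(cold, cw.Activity("light"), moderate_ensemble, 30.0),
            ]
        )
        res = cw.simulate(scen, reference_adult)
        # no state jump where the ensemble/activity switch at t = 30 min:
        # the per-step change around the boundary stays of ordinary size
        steps = np.abs(np.diff(res.temperatures, axis=0)).max(axis=(1, 2))
        t_mid = res.time_min[1:]
        window = (t_mid > 25.0) & (t_mid < 35.0)
        assert steps[window].max() < 1.5

    def test_timestep_validation(self, reference_adult, acu_ensemble):
        env = cw.Environment(air_temp=0.0)
        with pytest.raises(ValidationError):
            cw.simulate(
                _scenario(env, "rest", acu_ensemble, 30.0), reference_adult, timestep=300.0
            )

    def test_energy_balance_residual(self, cold_acu_run):
        """Stored-energy change matches integrated net heat to well under 1 %."""
        scale = max(105.0, np.abs(cold_acu_run.shivering).max())
        assert cold_acu_run.energy_residual.max() < 0.01 * scale

    def test_timestep_convergence(self, reference_adult, acu_ensemble, thresholds):
        """Halving the step moves every reported endurance time by < 1 %."""
        env = cw.Environment(air_temp=-9.0, wind_speed=2.0, rh=70.0)
        scen = _scenario(env, "rest", acu_ensemble, 330.0)
        coarse = cw.endurance_times(
            cw.simulate(scen, reference_adult, timestep=30.0), thresholds
        )
        fine = cw.endurance_times(
            cw.simulate(scen, reference_adult, timestep=15.0), thresholds
        )
        for field in (
            "finger_frostbite_risk",
            "toe_frostbite_risk",
            "hypothermia",
            "manual_performance_limit",
        ):
            a, b = getattr(coarse, field), getattr(fine, field)
            assert (a is None) == (b is None)
            if a is not None:
                assert abs(a - b) / b < 0.01

    def test_shivering_and_sweating_mutually_exclusive(self, cold_acu_run, thermoneutral_run):
        for run in (cold_acu_run, thermoneutral_run):
            both = (run.shivering > 1e-9) & (run.sweat_rate > 1e-9)
            assert not both.any()

    def test_fluid_loss_nondecreasing(self, cold_acu_run, thermoneutral_run):
        for run in (cold_acu_run, thermoneutral_run):
            assert np.all(np.diff(run.fluid_loss) >= -1e-15)


class TestEnduranceAnchors:
    def test_acu_reference_cell(self, cold_acu_run, thresholds):
        """ACU at -9 degC, 2 m/s, rest, bare hands: hand endurance near
        32 min and hypothermia near 4.2 h (calibration reference)."""
        et = cw.endurance_times(cold_acu_run, thresholds)
        assert et.finger_frostbite_risk == pytest.approx(32.0, rel=0.40)
        assert et.hypothermia == pytest.approx(4.2 * 60.0, rel=0.40)

    def test_threshold_ordering(self, cold_acu_run, thresholds):
        """The 15 degC manual-performance crossing precedes the 5 degC one."""
        et = cw.endurance_times(cold_acu_run, thresholds)
        assert et.manual_performance_limit < et.finger_frostbite_risk

    def test_moderate_outlasts_acu(self, reference_adult, acu_ensemble, moderate_ensemble, thresholds):
        env = cw.Environment(air_temp=-9.0, wind_speed=2.0, rh=70.0)
        acu = cw.endurance_times(
            cw.simulate(_scenario(env, "rest", acu_ensemble, 360.0), reference_adult),
            thresholds,
        )
        mod = cw.endurance_times(
            cw.simulate(_scenario(env, "rest", moderate_ensemble, 360.0), reference_adult),
            thresholds,
        )
        assert acu.hypothermia is not None
        assert mod.hypothermia is None or mod.hypothermia > acu.hypothermia


class TestEnduranceGrid:
    def test_grid_matches_single_runs(self, reference_adult, acu_ensemble, thresholds):
        env = cw.Environment(air_temp=-21.0, wind_speed=11.0, rh=70.0)
        single = cw.endurance_times(
            cw.simulate(_scenario(env, "rest", acu_ensemble, 120.0), reference_adult),
            thresholds,
        )
        [cell] = endurance_grid(
            [-21.0], [11.0], acu_ensemble, cw.Activity("rest"), reference_adult,
            horizon_min=120.0,
        )
        assert cell["finger_frostbite_risk_min"] == pytest.approx(
            single.finger_frostbite_risk, rel=1e-6
        )
        assert cell["hypothermia_min"] == pytest.approx(single.hypothermia, rel=1e-6)

    def test_empty_grid(self, reference_adult, acu_ensemble):
        assert endurance_grid([], [2.0], acu_ensemble, cw.Activity("rest"), reference_adult) == []
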