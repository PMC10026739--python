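import numpy as np
import pytest

import coweda as cw


@pytest.fixture(scope="session")
def params():
    return cw.default_params()


@pytest.fixture(scope="session")
def reference_adult():
    """180 cm / 74.4 kg / 15 % fat adult used throughout the examples."""
    return cw.Anthropometry(height=180.0, mass=74.4, fat_fraction=0.15)


@pytest.fixture(scope="session")
def garments():
    return cw.default_garments()


@pytest.fixture(scope="session")
def light_ensemble():
    return cw.resolve_ensemble("light")


@pytest.fixture(scope="session")
def acu_ensemble():
    return cw.resolve_ensemble("acu")


@pytest.fixture(scope="session")
def moderate_ensemble():
    return cw.resolve_ensemble("moderate_cold")


@pytest.fixture(scope="session")
def thresholds():
    return cw.Thresholds()


def _one_phase(env, activity, ensemble, minutes):
    return cw.ExposureScenario(
        [cw.ExposurePhase(env, cw.Activity(activity), ensemble, minutes)]
    )


@pytest.fixture(scope="session")
def cold_acu_run(reference_adult, acu_ensemble):
    """ACU-like ensemble at -9 degC, 2 m/s, rest, bare hands (5 h horizon)."""
    env = cw.Environment(air_temp=-9.0, wind_speed=2.0, rh=70.0)
    return cw.simulate(_one_phase(env, "rest", acu_ensemble, 330.0), reference_adult)


@pytest.fixture(scope="session")
def thermoneutral_run(reference_adult, light_ensemble):
    env = cw.Environment(air_temp=30.0, wind_speed=0.4, rh=50.0)
    return cw.simulate(_one_phase(env, "rest", light_ensemble, 120.0), reference_adult)


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("ci", derandomize=True)
_hyp_settings.load_profile("ci")
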