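import pytest

from xylodeb import default_parameters, derive_compound


@pytest.fixture(scope="session")
def params():
    """Shipped Xylonora atlantica parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def compound(params):
    return derive_compound(params)


@pytest.fixture(scope="session")
def baseline_deep_sea(params):
    """One full life cycle at satiety under deep-sea conditions (4 degC),
    shared across tests that only read from it."""
    from xylodeb.traits import simulate_scenario

    return simulate_scenario(params, 1.0, 4.0, 821.0)
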