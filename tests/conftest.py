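import pytest

from acidflux.engine import SimulationConfig, run
from acidflux.kinetics import KineticParameters
from acidflux.network import make_toy_network


@pytest.fixture()
def toy_net():
    return make_toy_network()


@pytest.fixture()
def params():
    return KineticParameters()


@pytest.fixture(scope="session")
def session_params():
    return KineticParameters()


@pytest.fixture(scope="session")
def ph2_long_run(session_params):
    """192 h batch at initial pH 2, minute resolution (the headline run)."""
    net = make_toy_network()
    config = SimulationConfig(duration=192.0, dt=1.0 / 60.0)
    return run(net, session_params, config), config


@pytest.fixture(scope="session")
def ph7_knockout_runs(session_params):
    """Control / oah / gox / double-knockout runs at initial pH 7."""
    net = make_toy_network()
    out = {}
    for name, knockouts in {
        "control": frozenset(),
        "oah": frozenset({"oah"}),
        "gox": frozenset({"gox"}),
        "oah_gox": frozenset({"oah", "gox"}),
    }.items():
        config = SimulationConfig(
            duration=96.0, dt=1.0 / 60.0, initial_ph=7.0, knockouts=knockouts
        )
        out[name] = run(net, session_params, config)
    return out
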