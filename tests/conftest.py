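import numpy as np
import pytest

from pyloricnet import CircuitParams, NetworkState, SimulationConfig
from pyloricnet.fixtures import fixture_sim_config, generate_fixtures, zero_weight_circuit


@pytest.fixture(scope="session")
def zero_circuit():
    return zero_weight_circuit()


@pytest.fixture(scope="session")
def ring_oscillator():
    """Center-crossing inhibitory ring: a reliable hand-built oscillator."""
    weights = {(s, t): 0.0 for s in ("LP", "PY", "PD") for t in ("LP", "PY", "PD")}
    for n in ("LP", "PY", "PD"):
        weights[(n, n)] = 5.0
    for s, t in (("LP", "PY"), ("PY", "PD"), ("PD", "LP")):
        weights[(s, t)] = -8.0
    theta = {n: 1.5 for n in ("LP", "PY", "PD")}  # center-crossing: -(5-8)/2
    return CircuitParams(
        time_constants={"LP": 1.0, "PY": 1.0, "PD": 1.0},
        biases=theta,
        weights=weights,
    )


@pytest.fixture(scope="session")
def nudge_state():
    # symmetric rings need an asymmetric kick to leave the diagonal
    return NetworkState(states={"LP": 0.5, "PY": 0.0, "PD": -0.5})


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def fast_config():
    """Coarse-step config valid for the slow-tau archetype fixtures."""
    return fixture_sim_config()


@pytest.fixture(scope="session")
def suite():
    """Uncertified fixture suite (certification is itself under test)."""
    return generate_fixtures(certify=False)


@pytest.fixture(scope="session")
def separable_circuit(suite):
    return suite.circuit("separable")


@pytest.fixture(scope="session")
def inseparable_circuit(suite):
    return suite.circuit("inseparable_2d")


@pytest.fixture(scope="session")
def unstable_circuit(suite):
    return suite.circuit("unstable")


@pytest.fixture(scope="session")
def separable_scan(separable_circuit, fast_config):
    from pyloricnet.prediction import scan_subspace

    return scan_subspace(separable_circuit, ("LP", "PD"), step=0.5, config=fast_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reliable_target(separable_scan):
    """First exclusive-bin target whose endpoint prediction is an unflagged
    'reliable' on the separable fixture."""
    from pyloricnet.prediction import reliable_targets

    for targets, _ in reliable_targets(separable_scan, max_candidates=1):
        return targets
    raise RuntimeError("separable fixture has no reliable-predicted target")
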