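import numpy as np
import pytest

from measync import ElectrodeGeometry, SimParams, SpikeTrain, constant_protocol, simulate_well


@pytest.fixture(scope="session")
def geometry():
    return ElectrodeGeometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_train(times, t_start=0.0, t_stop=10.0, eid="E01"):
    return SpikeTrain(eid, np.asarray(times, dtype=float), t_start, t_stop)


@pytest.fixture(scope="session")
def default_well():
    """600 s default-parameter well (sporadic 5 Hz + 0.06 Hz SBFs)."""
    well, truth = simulate_well(constant_protocol(600.0), SimParams(), seed=7)
    return well, truth


@pytest.fixture(scope="session")
def poisson_well():
    """900 s burst-free Poisson well for null-calibration tests."""
    well, _ = simulate_well(
        constant_protocol(900.0), SimParams(sbf_rate=0.0), seed=42
    )
    return well
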