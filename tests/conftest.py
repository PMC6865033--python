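import numpy as np
import pytest

from netaging import (
    LifespanDataset,
    MechanisticNetworkSpec,
    NetworkAgingParams,
    load_wild_isolates,
    sample_closed_form,
)


@pytest.fixture(scope="session")
def by4742_params():
    """Network-model point estimates for the reference laboratory strain."""
    return NetworkAgingParams(R=0.0047, t0=56.2, n=7.9)


@pytest.fixture(scope="session")
def wild_isolates():
    return load_wild_isolates()


@pytest.fixture(scope="session")
def mech_spec():
    return MechanisticNetworkSpec(m=500, n=7, p=0.7, lam=0.005)


@pytest.fixture(scope="session")
def network_sample():
    """1000 closed-form lifespans at (R=0.005, t0=50, n=7), fixed seed."""
    truth = NetworkAgingParams(R=0.005, t0=50.0, n=7.0)
    return truth, sample_closed_form(truth, 1000, seed=42)


@pytest.fixture
def toy_dataset():
    return LifespanDataset("toy", np.array([10.0, 20.0, 30.0]))
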