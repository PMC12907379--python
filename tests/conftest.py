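import numpy as np
import pytest

from neurocosim.connectome import SyntheticConnectomeSpec, generate_synthetic
from neurocosim.ion_neuron import IonNeuronParams, resting_state


@pytest.fixture(scope="session")
def default_params() -> IonNeuronParams:
    return IonNeuronParams()


@pytest.fixture(scope="session")
def rest(default_params):
    return resting_state(default_params)


@pytest.fixture(scope="session")
def quiescent():
    """Fully adapted silent cell at a low bath (2.5 mM): params, state."""
    from neurocosim.ion_neuron import IonNeuronState, integrate

    p = IonNeuronParams(K_bath=2.5)
    tr = integrate(p, resting_state(p), 30_000.0, dt=0.05,
                   sample_every=600_000)
    state = IonNeuronState(V=float(tr.V[-1, 0]), n=float(tr.n[-1, 0]),
                           DeltaK_i=float(tr.DeltaK_i[-1, 0]),
                           K_g=float(tr.K_g[-1, 0]))
    return p, state


@pytest.fixture(scope="session")
def small_connectome():
    """Deterministic 10-region synthetic connectome with a proxy seed."""
    return generate_synthetic(
        SyntheticConnectomeSpec(n_regions=10, density=1.0, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
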