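import numpy as np
import pytest

from parbcond.polymer_core import ForceField, init_wlc_chain, run_steps


@pytest.fixture(scope="session")
def ff():
    return ForceField()


@pytest.fixture(scope="session")
def thermal_chain(ff):
    """A 100-bead chain thermalized for ~40 tau_B; shared across tests."""
    state = init_wlc_chain(100, ff, seed=1234)
    run_steps(state, ff, 20000, seed=99)
    return state


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
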