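import numpy as np
import pytest

import porecall as pc


@pytest.fixture(scope="session")
def pore_model():
    return pc.build_default_pore_model(seed=1)


@pytest.fixture(scope="session")
def sim_params():
    return pc.SimParams(seed=7)


@pytest.fixture(scope="session")
def small_run(pore_model):
    """A tiny simulated run shared across tests: 12 reads off a 6 kb genome,
    half-methylated sites."""
    params = pc.SimParams(seed=3)
    ref = pc.random_reference(6000, seed=2)
    reads, truths = pc.simulate_run(
        ref, 12, pore_model, params, read_len_range=(400, 800),
        per_site_meth_prob=0.5,
    )
    return ref, reads, truths, params


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
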