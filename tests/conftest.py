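import numpy as np
import pytest

import protoflux as pf


@pytest.fixture(scope="session")
def toys():
    return pf.toy_models()


@pytest.fixture(scope="session")
def segment(toys):
    return toys["segment"]


@pytest.fixture(scope="session")
def branch(toys):
    return toys["branch"]


@pytest.fixture(scope="session")
def diamond(toys):
    return toys["diamond"]


@pytest.fixture(scope="session")
def central(toys):
    return toys["toy_central_carbon"]


@pytest.fixture(scope="session")
def segment_posterior(segment):
    return pf.ep_fit(segment)


@pytest.fixture(scope="session")
def branch_posterior(branch):
    return pf.ep_fit(branch)


@pytest.fixture(scope="session")
def central_posterior(central):
    return pf.ep_fit(central)


def random_model_specs(n, start_seed=100, rng_seed=0):
    """Shapes for random synthetic models: 10-25 metabolites, 15-40 reactions."""
    rng = np.random.default_rng(rng_seed)
    specs = []
    for i in range(n):
        nm = int(rng.integers(10, 26))
        nr = int(rng.integers(max(15, nm + 3), 41))
        npath = int(rng.integers(2, 5))
        nex = int(rng.integers(npath + 1, npath + 3))
        nsinks = min(npath, nex - 1)
        nm = min(nm, nr - npath - nex + 1 + nsinks)
        specs.append(pf.SyntheticSpec(nm, nr, npath, nex, 0.25, 1.0,
                                      seed=start_seed + i))
    return specs
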