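import numpy as np
import pytest

from cctte import (
    Scenario,
    TrialDesign,
    generate_replicate,
    make_fixture,
)


@pytest.fixture
def tiny():
    """Six-subject one-covariate dataset with an interior partial-likelihood MLE."""
    return make_fixture("tiny")


@pytest.fixture
def worked():
    """2g=4 randomized trial with a plain-Python permutation-test sidecar."""
    return make_fixture("worked", seed=3)


@pytest.fixture(scope="session")
def medium_trial():
    """A moderate randomized trial (g=4, n=40) for fitter cross-checks."""
    sc = Scenario(
        design=TrialDesign(g=4, n=40, delta=0.7, beta=0.3),
        q=1.0,
        n_sim=1,
        seed=1701,
    )
    dataset, space, allocation = generate_replicate(sc, 0)
    return dataset, space, allocation


@pytest.fixture(scope="session")
def frailty_trial():
    """A trial with strong gamma frailty for mixed-model checks."""
    sc = Scenario(
        design=TrialDesign(g=6, n=40, delta=1.0, beta=0.0, frailty_var=0.6),
        q=1.0,
        n_sim=1,
        seed=2041,
    )
    dataset, space, allocation = generate_replicate(sc, 0)
    return dataset


def rng_for(name: str) -> np.random.Generator:
    """Deterministic per-test generator keyed on a label."""
    import zlib

    return np.random.default_rng(zlib.crc32(name.encode()))
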