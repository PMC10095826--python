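import numpy as np
import pytest

from ffmatch.synthetic import (GhostSpec, ghost_reference_dataset,
                               make_diatomic, make_toy_host)


@pytest.fixture(scope="session")
def toy_host():
    """(topology, ghost params, meta) for the stiff 8-unit ring."""
    return make_toy_host(n_units=8, stiffness="stiff")


@pytest.fixture(scope="session")
def diatomic():
    return make_diatomic(k=300.0, r_eq=1.5)


@pytest.fixture(scope="session")
def small_ghost_dataset(toy_host):
    """400 noiseless frames of the stiff toy host at 600 K (shared)."""
    top, params, meta = toy_host
    spec = GhostSpec(temperature=600.0, n_frames=400, stride=10, seed=42)
    return ghost_reference_dataset(top, params, spec, x0=meta["coords"])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
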