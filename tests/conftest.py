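import numpy as np
import pytest

from glomnet import build_random_network, synth_gc_lattice

from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_network():
    """One random connection model at the study's native scale."""
    return build_random_network(3000, 1000, 4, seed=42)


@pytest.fixture(scope="session")
def toy_network():
    """Small network (10 GCs, 5 glomeruli, 2 dendrites) for brute-force oracles."""
    return build_random_network(10, 5, 2, seed=7)


@pytest.fixture(scope="session")
def small_lattice():
    """Hard-core soma lattice small enough for fast G/F/K computation."""
    return synth_gc_lattice(800, field_um=110.0, min_spacing_um=2.5, seed=11)
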