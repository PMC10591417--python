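import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from senesim.genome import LocusLayout
from senesim.lattice import Lattice

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_layout():
    """L_f = 2, L_a = 2 with a fixed interleaved order (f a f a)."""
    return LocusLayout(np.array([0, 1, 0, 1], dtype=np.int8))


@pytest.fixture
def lattice_builder():
    """Build a lattice from {site: (alleles, age[, tag])} occupant specs."""

    def build(N, layout, occupants, target=None):
        lat = Lattice.empty(N, layout)
        for site, spec in occupants.items():
            alleles = np.asarray(spec[0], dtype=np.uint8)
            age = spec[1]
            tag = spec[2] if len(spec) > 2 else 0
            lat.occupied[site] = 1
            lat.age[site] = age
            lat.genomes[site] = alleles
            lat.tag[site] = tag
        lat.refresh_caches(target)
        return lat

    return build
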