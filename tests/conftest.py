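import pytest

from vegsynth import (
    NeighborhoodGeometry,
    VectorPattern,
    Element,
    gen_cluster,
    gen_poisson,
    gen_regular,
    gen_two_type,
)


@pytest.fixture(scope="session")
def lattice():
    """64-per-unit square lattice sample on the unit region (spacing 0.125)."""
    return gen_regular(64)


@pytest.fixture(scope="session")
def poisson_sample():
    return gen_poisson(25, seed=0)


@pytest.fixture(scope="session")
def cluster_sample():
    return gen_cluster(25, 6.6, 0.08, seed=0)


@pytest.fixture(scope="session")
def two_type_sample():
    return gen_two_type(seed=0, attributes=True)


@pytest.fixture
def geom():
    return NeighborhoodGeometry(r0=0.125)


def random_pattern(rng, n=40, n_types=1, size=1.0):
    """Uniform-random multi-type test pattern on a size x size region."""
    xy = rng.uniform(0, size, (n, 2))
    elements = [
        Element(id=i, x=float(xy[i, 0]), y=float(xy[i, 1]),
                type_id=int(rng.integers(n_types)))
        for i in range(n)
    ]
    return VectorPattern(elements, (0, 0, size, size))
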