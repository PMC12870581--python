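import numpy as np
import pytest

from mtlmorph.containers import TriMesh


@pytest.fixture(scope="session")
def sphere_pair():
    """Concentric icospheres r=10, R=12.5 at subdivision 2 (fast fixture)."""
    return TriMesh.icosphere(2, 10.0), TriMesh.icosphere(2, 12.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _random_blob_mesh(rng, subdivisions=1, radius=5.0, bump=0.3):
    """Randomly bumped sphere: generic closed oriented test surface."""
    m = TriMesh.icosphere(subdivisions, radius)
    r = 1.0 + bump * rng.uniform(-1, 1, size=len(m.vertices))
    return m.with_vertices(m.vertices * r[:, None])


@pytest.fixture
def blob_mesh():
    return _random_blob_mesh
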