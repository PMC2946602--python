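import numpy as np
import pytest

from surfatlas import KernelSpec, TriMesh, default_tau, make_icosphere


@pytest.fixture
def tetrahedron() -> TriMesh:
    """Smallest closed triangulation: 4 vertices, 4 outward-oriented faces."""
    v = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(v, f)


@pytest.fixture
def ico12() -> TriMesh:
    return make_icosphere(0)


@pytest.fixture
def ico42() -> TriMesh:
    return make_icosphere(1)


@pytest.fixture
def spec12(ico12) -> KernelSpec:
    return KernelSpec(tau=default_tau(ico12))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
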