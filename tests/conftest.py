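import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tmmkit import FrequencyGrid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the five head tissues of the recipe table with their printed
#: Kraszewski compositions (TX-100 vol%, NaCl g/L) and 1 GHz properties
HEAD_TABLE = {
    "brain": dict(tx=34.0, nacl=6.8, eps_r=41.0, sigma=1.0),
    "csf": dict(tx=5.0, nacl=13.9, eps_r=68.0, sigma=2.5),
    "muscle": dict(tx=21.0, nacl=5.5, eps_r=54.0, sigma=1.0),
    "bone_cortical": dict(tx=80.0, nacl=1.0, eps_r=12.0, sigma=0.2),
    "blood": dict(tx=14.0, nacl=9.2, eps_r=60.0, sigma=1.6),
}

ALL_TISSUES = [
    "blood", "bone_cortical", "brain", "brain_grey_matter",
    "brain_white_matter", "csf", "fat", "muscle", "nerve", "skin_dry",
]


@pytest.fixture(scope="session")
def band_grid() -> FrequencyGrid:
    """Default design band: 26 linear points on 0.5-3 GHz."""
    return FrequencyGrid()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


# --- tiny synthetic STL geometry -------------------------------------------

def tetrahedron_triangles() -> np.ndarray:
    """Closed tetrahedron, coordinates in mm (synthetic test geometry)."""
    v = np.array(
        [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [0.0, 0.0, 10.0]]
    )
    faces = [(0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3)]
    return np.array([[v[i] for i in face] for face in faces])


@pytest.fixture()
def tetra_ascii(tmp_path):
    from tmmkit.phantom_manifest import write_ascii_stl

    path = tmp_path / "tetra_ascii.stl"
    write_ascii_stl(path, tetrahedron_triangles())
    return path


@pytest.fixture()
def tetra_binary(tmp_path):
    from tmmkit.phantom_manifest import write_binary_stl

    path = tmp_path / "tetra_binary.stl"
    write_binary_stl(path, tetrahedron_triangles())
    return path
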