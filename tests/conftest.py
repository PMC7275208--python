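import numpy as np
import pytest

from aortamark import GridSpec, LandmarkSet


@pytest.fixture
def unit_grid():
    """128^3 grid at 1 mm isotropic spacing, identity orientation."""
    return GridSpec((128, 128, 128))


@pytest.fixture
def small_grid():
    """32^3 grid at 1 mm for brute-force-oracle comparisons."""
    return GridSpec((32, 32, 32))


@pytest.fixture
def landmarks():
    """Five well-separated landmarks near the middle of a 128^3 / 1 mm grid."""
    return LandmarkSet(
        {
            "LCC": [60.0, 70.0, 58.0],
            "NCC": [52.0, 58.0, 60.0],
            "RCC": [68.0, 57.0, 61.0],
            "LCO": [58.0, 66.0, 74.0],
            "RCO": [66.0, 60.0, 76.0],
        }
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
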