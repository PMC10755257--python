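import numpy as np
import pytest

from hemensd.mode_basis import default_mode_basis
from hemensd.reference_geometry import build_reference_porphine


@pytest.fixture(scope="session")
def ref():
    return build_reference_porphine()


@pytest.fixture(scope="session")
def basis():
    # Hessian build + eigen-solve + classification, cached for the session.
    return default_mode_basis()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
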