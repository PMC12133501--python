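import numpy as np
import pytest

from exotremor.dynamics import AnatomicalMatrices, ArmGeometry, load_matrices
from exotremor.actuation import load_layout
from exotremor.config import load_joint_ranges, load_torque_scale
from exotremor.motion import generate_synthetic_movement


@pytest.fixture(scope="session")
def matrices() -> AnatomicalMatrices:
    return load_matrices()


@pytest.fixture(scope="session")
def geometry() -> ArmGeometry:
    return ArmGeometry()


@pytest.fixture(scope="session")
def layout():
    return load_layout()


@pytest.fixture(scope="session")
def torque_scale():
    return load_torque_scale()


@pytest.fixture(scope="session")
def joint_ranges():
    return load_joint_ranges()


@pytest.fixture(scope="session")
def elbow_trajectory():
    return generate_synthetic_movement(
        "elbow_flexion_extension", duration_s=4.0, dt=1 / 30, seed=1
    )


@pytest.fixture(scope="session")
def short_trajectory():
    return generate_synthetic_movement(
        "elbow_flexion_extension", duration_s=2.0, dt=1 / 30, seed=1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def diagonal_matrices(matrices) -> AnatomicalMatrices:
    """Decoupled variant: same diagonals, zero off-diagonal coupling."""
    return AnatomicalMatrices(
        np.diag(np.diag(matrices.I)),
        np.diag(np.diag(matrices.D)),
        np.diag(np.diag(matrices.K)),
    )
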