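import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from otonav import LabeledPointSet, RigidTransform


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def random_rigid(rng: np.random.Generator, t_scale: float = 100.0) -> RigidTransform:
    return RigidTransform(random_rotation(rng), rng.uniform(-t_scale, t_scale, 3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261002)


@pytest.fixture
def tetrahedron() -> LabeledPointSet:
    """A generic (scalene) tetrahedron: all pairwise distances distinct."""
    pts = np.array(
        [
            [0.0, 0.0, 0.0],
            [13.0, 1.0, -2.0],
            [3.0, 11.0, 4.0],
            [-5.0, 4.0, 9.0],
        ]
    )
    return LabeledPointSet(["F1", "F2", "F3", "F4"], pts, frame="image")
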