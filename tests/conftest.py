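import numpy as np
import pytest

from retimosaic.camera import Camera, Intrinsics


def rot_y(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_x(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def random_rotation(rng, max_angle):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(axis * rng.uniform(0, max_angle)).as_matrix()


def homography_from_cameras(cam_i: Camera, cam_j: Camera) -> np.ndarray:
    H = cam_j.K.K @ cam_j.R.T @ cam_i.R @ cam_i.K.K_inv
    return H / H[2, 2]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def centered_camera():
    """f=700 camera with principal point at the origin (centred coords)."""
    return Camera(Intrinsics(700.0, 700.0, 0.0, 0.0), np.eye(3))
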