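import numpy as np
import pytest

from gaze3d.camera_geometry import CameraIntrinsics, StereoRig


def simple_intrinsics(f=800.0, cx=400.0, cy=300.0, w=800, h=600) -> CameraIntrinsics:
    K = np.array([[f, 0.0, cx], [0.0, f, cy], [0.0, 0.0, 1.0]])
    return CameraIntrinsics(K=K, image_width=w, image_height=h)


def rotation_y(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def make_test_rig(baseline=20.0, yaw_deg=30.0, f=800.0) -> StereoRig:
    """Small verging stereo rig looking at an eye ~30-40 mm down +z."""
    intr = simple_intrinsics(f=f)
    R = rotation_y(yaw_deg)
    C_rgb = np.array([baseline, 0.0, 0.0])
    return StereoRig(ir=intr, rgb=intr, R=R, T=-R @ C_rgb)


def random_rig(rng: np.random.Generator) -> StereoRig:
    """Random verging rig with the eye region in view of both cameras."""
    f = rng.uniform(300, 1200)
    intr = simple_intrinsics(f=f, cx=rng.uniform(300, 500), cy=rng.uniform(200, 400))
    baseline = rng.uniform(10, 40)
    yaw = rng.uniform(5, 45)
    R = rotation_y(yaw)
    C_rgb = np.array([baseline, rng.uniform(-3, 3), rng.uniform(-3, 3)])
    return StereoRig(ir=intr, rgb=intr, R=R, T=-R @ C_rgb)


@pytest.fixture
def rig() -> StereoRig:
    return make_test_rig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
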