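import numpy as np
import pytest

from neuroreach.gd_planner import GDConfig
from neuroreach.kinematics import ArmGeometry, JointAngles, Point3D, forward_kinematics


@pytest.fixture
def geometry() -> ArmGeometry:
    return ArmGeometry()


@pytest.fixture
def gd_config() -> GDConfig:
    return GDConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def sample_workspace_target(
    rng: np.random.Generator,
    g: ArmGeometry,
    r_range=(12.0, 30.0),
    z: float = 0.0,
) -> Point3D:
    """A random tabletop target in the utilized work annulus (arm frame)."""
    azimuth = rng.uniform(0.0, np.pi / 2)
    radius = rng.uniform(*r_range)
    return Point3D(radius * np.cos(azimuth), radius * np.sin(azimuth), z)


def sample_joint_pose(rng: np.random.Generator, g: ArmGeometry) -> JointAngles:
    """A random pose uniform within the joint limits."""
    vals = [rng.uniform(lo, hi) for lo, hi in g.joint_limits]
    return JointAngles(*vals)


def sample_reachable_point(rng: np.random.Generator, g: ArmGeometry) -> Point3D:
    """A random reachable EE point away from the degenerate base axis."""
    while True:
        q = sample_joint_pose(rng, g)
        p = forward_kinematics(q, g)
        if np.hypot(p.x, p.y) > 1.0:
            return p
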