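import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from equilimb.geometry import (
    HIP,
    PATELLOFEMORAL,
    STIFLE,
    Actuator,
    Joint,
    LimbGeometry,
    Segment,
)


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


@pytest.fixture
def rot():
    return random_rotation(42)


@pytest.fixture
def toy_geometry():
    """Three-joint chain with three hand-checkable actuators.

    Actuator coordinates are chosen so every moment coefficient can be
    verified by a hand cross product.
    """
    joints = [
        Joint(HIP, [0.0, 0.0, 1.0]),
        Joint(STIFLE, [0.0, 0.0, 0.6]),
        Joint(PATELLOFEMORAL, [0.1, 0.0, 0.65]),
    ]
    actuators = [
        Actuator(
            name="hip_extensor",
            kind="muscle",
            origin=[0.0, 0.1, 1.2],
            insertion=[0.1, 0.0, 1.0],  # lever (0.1, 0, 0) about the hip
            pcsa=2e-3,
            f_max=600.0,
            spans={HIP},
            attaches_femur=True,
            area_label="greater_trochanter",
        ),
        Actuator(
            name="biarticular",
            kind="muscle",
            origin=[0.0, -0.1, 1.1],
            insertion=[0.0, -0.05, 0.6],
            pcsa=4e-3,
            f_max=1200.0,
            spans={HIP, STIFLE},
            attaches_femur=False,
        ),
        Actuator(
            name="patellar_lig",
            kind="ligament",
            origin=[0.12, 0.0, 0.7],
            insertion=[0.12, 0.02, 0.55],
            pcsa=1e-3,
            f_max=3000.0,
            spans={PATELLOFEMORAL},
        ),
    ]
    segments = [
        Segment("thigh", 0.0335, [0.02, 0.0, 0.8]),
        Segment("crus", 0.0145, [0.03, 0.0, 0.45]),
        Segment("metatarsus", 0.0055, [0.04, 0.0, 0.2]),
        Segment("hind pastern", 0.0035, [0.05, 0.0, 0.08]),
        Segment("hind hoof", 0.0025, [0.05, 0.0, 0.03]),
    ]
    return LimbGeometry(
        joints=joints,
        actuators=actuators,
        segments=segments,
        body_mass=514.0,
        hoof_contact=[0.05, 0.0, 0.0],
    )
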