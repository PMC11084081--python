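"""External loads and net joint moments for the square-standing hindlimb.

In quiet standing the only external loads are gravity on the limb segments
and the ground reaction force (GRF) under the hoof; each hindlimb carries
about 20% of body weight.  The net joint moment at a joint is the moment
about its center of rotation produced by all external forces applied
distal to that joint in the serial chain.  For static equilibrium the
muscles and ligaments must produce the opposite moment.

The femoropatellar net moment is defined as zero: the patella itself has
negligible gravitational influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .geometry import HIP, PATELLOFEMORAL, STIFLE, LimbGeometry, as_point

GRAVITY = 9.81  # m/s^2, default; configurable everywhere it is used

#: Editable default mass fractions (share of body mass) for the five
#: hindlimb subunits, after the segmentation of Nauwelaerts and colleagues.
NAUWELAERTS_DEFAULTS = {
    "thigh": 0.0335,
    "crus": 0.0145,
    "metatarsus": 0.0055,
    "hind pastern": 0.0035,
    "hind hoof": 0.0025,
}

#: Default fraction of body weight borne by one hindlimb in square standing.
HINDLIMB_WEIGHT_FRACTION = 0.20


@dataclass(frozen=True)
class PointLoad:
    """An external force (N) applied at a point, tagged with the joints it
    lies distal to (i.e. the joints whose net moment it contributes to)."""

    name: str
    point: np.ndarray
    force: np.ndarray
    distal_to: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "point", as_point(self.point, f"load {self.name!r} point"))
        object.__setattr__(self, "force", as_point(self.force, f"load {self.name!r} force"))
        object.__setattr__(self, "distal_to", frozenset(self.distal_to))


@dataclass
class ExternalLoads:
    """GRF plus per-segment gravity loads."""

    loads: list = field(default_factory=list)

    @property
    def grf(self) -> np.ndarray:
        total = np.zeros(3)
        for l in self.loads:
            if l.name == "grf":
                total = total + l.force
        return total

    def total_force(self) -> np.ndarray:
        return np.sum([l.force for l in self.loads], axis=0) if self.loads else np.zeros(3)

    def translated(self, t) -> "ExternalLoads":
        t = as_point(t, "translation")
        return ExternalLoads([PointLoad(l.name, l.point + t, l.force, l.distal_to) for l in self.loads])

    def rotated(self, R) -> "ExternalLoads":
        R = np.asarray(R, dtype=float)
        return ExternalLoads([PointLoad(l.name, R @ l.point, R @ l.force, l.distal_to) for l in self.loads])


@dataclass
class NetJointMoments:
    """Per-joint 3-vector net moments (N·m) from external loading."""

    moments: dict  # joint name -> 3-vector

    def magnitude(self, joint: str) -> float:
        return float(np.linalg.norm(self.moments[joint]))

    def magnitudes(self) -> dict:
        return {j: self.magnitude(j) for j in self.moments}

    def stacked(self, joint_order) -> np.ndarray:
        return np.concatenate([np.asarray(self.moments[j], dtype=float) for j in joint_order])

    def negated(self) -> "NetJointMoments":
        """Moments the actuators must produce to cancel the external loading."""
        return NetJointMoments({j: -np.asarray(m) for j, m in self.moments.items()})


def ground_reaction(body_mass: float, fraction: float = HINDLIMB_WEIGHT_FRACTION,
                    g: float = GRAVITY) -> np.ndarray:
    """Vertical GRF (N) under one hoof: ``(0, 0, +fraction * body_mass * g)``."""
    if body_mass < 0:
        raise GeometryError(f"body_mass must be >= 0, got {body_mass}")
    if not 0.0 <= fraction <= 1.0:
        raise GeometryError(f"hindlimb fraction must be in [0, 1], got {fraction}")
    return np.array([0.0, 0.0, fraction * body_mass * g])


def segment_loads(body_mass: float, segments, g: float = GRAVITY) -> list:
    """Gravity load ``(0, 0, -mass_fraction * body_mass * g)`` at each segment COM."""
    import warnings

    if body_mass < 0:
        raise GeometryError(f"body_mass must be >= 0, got {body_mass}")
    total = sum(s.mass_fraction for s in segments)
    if total > 1.0:
        warnings.warn(f"segment mass fractions sum to {total:.3f} > 1")
    return [
        PointLoad(
            name=f"gravity:{s.name}",
            point=s.com,
            force=np.array([0.0, 0.0, -s.mass_fraction * body_mass * g]),
        )
        for s in segments
    ]


#: Which joints each standing load lies distal to.  The GRF and the gravity
#: of every segment below the stifle contribute to both hip and stifle
#: moments; the thigh's own weight loads only the hip.  The patellofemoral
#: moment is zero by definition, so nothing maps to it.
_DISTAL_SEGMENTS = {
    "thigh": frozenset({HIP}),
    "crus": frozenset({HIP, STIFLE}),
    "metatarsus": frozenset({HIP, STIFLE}),
    "hind pastern": frozenset({HIP, STIFLE}),
    "hind hoof": frozenset({HIP, STIFLE}),
}


def standing_loads(geometry: LimbGeometry, fraction: float = HINDLIMB_WEIGHT_FRACTION,
                   g: float = GRAVITY) -> ExternalLoads:
    """Assemble the standing load set: GRF at the hoof contact plus segment gravity."""
    loads = [
        PointLoad(
            name="grf",
            point=geometry.hoof_contact,
            force=ground_reaction(geometry.body_mass, fraction, g),
            distal_to=frozenset({HIP, STIFLE}),
        )
    ]
    for sl in segment_loads(geometry.body_mass, geometry.segments, g):
        seg_name = sl.name.split(":", 1)[1]
        distal = _DISTAL_SEGMENTS.get(seg_name, frozenset({HIP, STIFLE}))
        loads.append(PointLoad(sl.name, sl.point, sl.force, distal))
    return ExternalLoads(loads)


def net_joint_moments(geometry: LimbGeometry, loads: ExternalLoads,
                      zero_joints=(PATELLOFEMORAL,)) -> NetJointMoments:
    """Net external moment about each joint center.

    ``M_j = sum over loads distal to j of (p - c_j) x F``.  Joints listed in
    ``zero_joints`` are forced to exactly zero (the femoropatellar joint by
    default).
    """
    moments = {}
    for joint in geometry.joints:
        if joint.name in zero_joints:
            moments[joint.name] = np.zeros(3)
            continue
        m = np.zeros(3)
        for load in loads.loads:
            if joint.name in load.distal_to:
                m = m + np.cross(load.point - joint.center, load.force)
        moments[joint.name] = m
    return NetJointMoments(moments)
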