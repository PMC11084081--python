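"""Assembly of the moment-balance linear system.

Each actuator ``i`` exerts a force of unknown magnitude ``F_i`` along its
unit line of action ``r_i``.  About a joint with center ``c`` and weighted
attachment points ``p_k`` (lever arms ``tau_k = p_k - c``), the moment per
newton is ``sum_k w_k (tau_k x r_i)``.  Stacking the three moment rows of
every joint gives the ``(3J) x N`` coefficient matrix ``A`` with
``A @ F = M`` the balance condition against the target joint moments.

The moment of a unit force along ``r`` applied at lever ``tau`` is
``tau x r``; that order is used consistently here and in the net-moment
computation, so the balance system is internally sign-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .geometry import Actuator, Joint, LimbGeometry, STANDARD_JOINTS, effective_direction


def lever_arm(attachment, joint_center) -> np.ndarray:
    """Lever vector from the joint center of rotation to the attachment point."""
    return np.asarray(attachment, dtype=float) - np.asarray(joint_center, dtype=float)


def moment_coefficient(actuator: Actuator, joint: Joint) -> np.ndarray:
    """Moment (N·m) about ``joint`` per newton of force in ``actuator``.

    Zero for actuators that do not span the joint.  Multi-point attachments
    contribute their weighted sum of ``tau x r`` terms.
    """
    if joint.name not in actuator.spans:
        return np.zeros(3)
    r_hat = effective_direction(actuator)
    coeff = np.zeros(3)
    for point, weight in actuator.attachment_for(joint.name):
        coeff = coeff + weight * np.cross(lever_arm(point, joint.center), r_hat)
    return coeff


@dataclass
class SystemMatrix:
    """The stacked moment-balance coefficients.

    ``coefficients`` has one 3-row block per joint (in ``joint_order``) and
    one column per actuator (in ``actuator_order``), units N·m per N.
    """

    coefficients: np.ndarray
    joint_order: list
    actuator_order: list

    @property
    def n_actuators(self) -> int:
        return self.coefficients.shape[1]

    def block(self, joint_name: str) -> np.ndarray:
        i = self.joint_order.index(joint_name)
        return self.coefficients[3 * i : 3 * i + 3, :]

    def column(self, actuator_name: str) -> np.ndarray:
        return self.coefficients[:, self.actuator_order.index(actuator_name)]


def assemble_system(geometry: LimbGeometry, joint_order=None) -> SystemMatrix:
    """Build the ``(3J) x N`` system for the given joints (default: the hip,
    stifle and patellofemoral joints present in the geometry, in that order)."""
    if joint_order is None:
        joint_order = [j for j in STANDARD_JOINTS if j in geometry.joint_names]
        if not joint_order:
            joint_order = geometry.joint_names
    joints = [geometry.joint(name) for name in joint_order]
    known = set(geometry.joint_names)
    for a in geometry.actuators:
        unknown = a.spans - known
        if unknown:
            raise GeometryError(f"actuator {a.name!r} spans unknown joint(s) {sorted(unknown)}")
    cols = []
    for a in geometry.actuators:
        cols.append(np.concatenate([moment_coefficient(a, j) for j in joints]))
    A = np.column_stack(cols) if cols else np.zeros((3 * len(joints), 0))
    return SystemMatrix(
        coefficients=A,
        joint_order=list(joint_order),
        actuator_order=[a.name for a in geometry.actuators],
    )
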