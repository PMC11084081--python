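"""Joint contact forces.

The contact force at a joint is the vector sum of the intersegmental force
transmitted through the joint by the external loads and the forces of all
actuators crossing it:

    F_contact = sum F_segmental + sum F_muscles

Reported as the force acting on the proximal bone from the distal side;
the magnitude is what is usually compared across studies.  Because
antagonistic co-contraction is cancelled by the static optimization, these
magnitudes tend to be underestimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .geometry import LimbGeometry, effective_direction
from .optimize import ForceSolution
from .statics import ExternalLoads


@dataclass
class ContactForces:
    """Per-joint contact force vectors (N) and magnitudes."""

    vectors: dict  # joint name -> 3-vector

    def magnitude(self, joint: str) -> float:
        return float(np.linalg.norm(self.vectors[joint]))

    def magnitudes(self) -> dict:
        return {j: self.magnitude(j) for j in self.vectors}


def intersegmental_force(joint_name: str, loads: ExternalLoads) -> np.ndarray:
    """Resultant of the external forces applied distal to the joint."""
    total = np.zeros(3)
    for load in loads.loads:
        if joint_name in load.distal_to:
            total = total + load.force
    return total


def contact_force(joint_name: str, geometry: LimbGeometry, solution: ForceSolution,
                  loads: ExternalLoads = None) -> np.ndarray:
    """Contact force vector at one joint (intersegmental + crossing muscles)."""
    if joint_name not in geometry.joint_names:
        raise GeometryError(f"no joint named {joint_name!r}")
    total = intersegmental_force(joint_name, loads) if loads is not None else np.zeros(3)
    for actuator in geometry.actuators:
        if joint_name in actuator.spans:
            total = total + solution.force(actuator.name) * effective_direction(actuator)
    return total


def contact_forces(geometry: LimbGeometry, solution: ForceSolution,
                   loads: ExternalLoads = None) -> ContactForces:
    """Contact forces at every joint in the geometry."""
    return ContactForces(
        {j: contact_force(j, geometry, solution, loads) for j in geometry.joint_names}
    )
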