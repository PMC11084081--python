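"""Model/Results facade over the standing-limb pipeline.

:class:`StandingLimbModel` bundles a :class:`~equilimb.geometry.LimbGeometry`
with the standing load configuration; :meth:`StandingLimbModel.fit` runs the
inverse statics and static optimization and returns a
:class:`StandingLimbResults` carrying the per-actuator forces, bound
activity, convergence diagnostics, joint contact forces and the FEA load
case, with a ``summary()`` table.

Example
-------
>>> from equilimb import synthetic, StandingLimbModel
>>> inst = synthetic.generate(seed=7, n_actuators=20)
>>> res = StandingLimbModel.from_instance(inst).fit()
>>> res.forces.head()  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import contact as _contact
from . import loadcase as _loadcase
from . import optimize as _optimize
from . import report as _report
from .geometry import LimbGeometry, read_geometry
from .statics import (
    GRAVITY,
    HINDLIMB_WEIGHT_FRACTION,
    ExternalLoads,
    NetJointMoments,
    net_joint_moments,
    standing_loads,
)
from .system import SystemMatrix, assemble_system


class StandingLimbModel:
    """Static musculoskeletal model of one standing hindlimb.

    Parameters
    ----------
    geometry : LimbGeometry
        Joints, segments and actuators in one frame.
    hindlimb_fraction : float
        Share of body weight borne by the limb (default 0.20 in square
        standing).
    g : float
        Gravitational acceleration, m/s^2.
    target_moments : NetJointMoments, optional
        Directly prescribe the moments the actuators must produce,
        bypassing the gravity/GRF statics (used for synthetic instances).
    bounds : BoundSpec, optional
        Override the rule-based physiological bounds.
    """

    def __init__(self, geometry: LimbGeometry, hindlimb_fraction: float = HINDLIMB_WEIGHT_FRACTION,
                 g: float = GRAVITY, target_moments: Optional[NetJointMoments] = None,
                 bounds: Optional[_optimize.BoundSpec] = None,
                 sigma0: float = _optimize.SIGMA0):
        self.geometry = geometry
        self.hindlimb_fraction = hindlimb_fraction
        self.g = g
        self._target_moments = target_moments
        self._bounds = bounds
        self.sigma0 = sigma0
        self.system: SystemMatrix = assemble_system(geometry)
        self.pcsa = np.array([a.pcsa for a in geometry.actuators])

    @classmethod
    def from_file(cls, geometry_path, **kwargs) -> "StandingLimbModel":
        return cls(read_geometry(geometry_path), **kwargs)

    @classmethod
    def from_instance(cls, instance, **kwargs) -> "StandingLimbModel":
        """Build from a :class:`~equilimb.synthetic.SyntheticInstance`."""
        return cls(
            instance.geometry,
            target_moments=instance.target_moments,
            bounds=instance.bounds,
            **kwargs,
        )

    def external_loads(self) -> ExternalLoads:
        return standing_loads(self.geometry, self.hindlimb_fraction, self.g)

    def net_moments(self) -> NetJointMoments:
        """Net external joint moments from gravity and the GRF."""
        return net_joint_moments(self.geometry, self.external_loads())

    def target_moments(self) -> NetJointMoments:
        """Moments the actuators must produce (external moments negated)."""
        if self._target_moments is not None:
            return self._target_moments
        return self.net_moments().negated()

    def bounds(self) -> _optimize.BoundSpec:
        if self._bounds is not None:
            return self._bounds
        grf_mag = float(np.linalg.norm(self.external_loads().grf))
        return _optimize.default_bounds(self.geometry.actuators, grf_mag)

    def fit(self, **solver_kwargs) -> "StandingLimbResults":
        """Solve the static optimization and package the results."""
        bounds = self.bounds()
        solution = _optimize.solve_forces(
            self.system, self.target_moments(), self.pcsa, bounds,
            sigma0=self.sigma0, **solver_kwargs,
        )
        return StandingLimbResults(model=self, solution=solution)


@dataclass
class StandingLimbResults:
    """Fitted forces plus derived quantities for one standing limb."""

    model: StandingLimbModel
    solution: _optimize.ForceSolution
    _loads: ExternalLoads = field(default=None, repr=False)

    def __post_init__(self):
        if self._loads is None and self.model._target_moments is None:
            self._loads = self.model.external_loads()

    # -- estimates -----------------------------------------------------
    @property
    def forces(self) -> pd.Series:
        return pd.Series(self.solution.forces, index=self.solution.names, name="force_N")

    @property
    def objective(self) -> float:
        return self.solution.objective

    @property
    def converged(self) -> bool:
        return self.solution.converged

    def to_frame(self) -> pd.DataFrame:
        s = self.solution
        b = s.bounds
        return pd.DataFrame(
            {
                "force_N": s.forces,
                "lower_N": b.lower,
                "upper_N": b.upper,
                "at_lower": s.active_lower,
                "at_upper": s.active_upper,
                "bound_rule": b.provenance,
            },
            index=pd.Index(s.names, name="actuator"),
        )

    # -- diagnostics ---------------------------------------------------
    @property
    def moment_residual_norm(self) -> float:
        return self.solution.residual_norm

    @property
    def kkt_residual(self) -> float:
        return self.solution.kkt

    # -- derived quantities --------------------------------------------
    def contact_forces(self) -> pd.DataFrame:
        cf = _contact.contact_forces(self.model.geometry, self.solution, self._loads)
        rows = {
            j: list(v) + [float(np.linalg.norm(v))] for j, v in cf.vectors.items()
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["Fx_N", "Fy_N", "Fz_N", "magnitude_N"]
        ).rename_axis("joint")

    def load_case(self, threshold: float = _loadcase.DEFAULT_THRESHOLD_N) -> _loadcase.LoadCase:
        return _loadcase.build_loadcase(self.solution, self.model.geometry, threshold)

    def group_sum(self, member_names) -> float:
        return _report.group_sum(self.solution, member_names)

    def summary(self) -> str:
        s = self.solution
        lines = [
            "Standing hindlimb static optimization",
            "=" * 53,
            f"actuators: {len(s.names)}   joints: {len(self.model.system.joint_order)}",
            f"converged: {s.converged}   method: {s.method}   iterations: {s.n_iter}",
            f"objective U = sum (F/PCSA)^3: {s.objective:.6e}",
            f"moment residual |A F - M|: {s.residual_norm:.3e} N·m",
            f"KKT (projected gradient, relative): {s.kkt:.3e}",
            "-" * 53,
            f"{'actuator':<30}{'force (N)':>12}{'bound':>10}",
        ]
        for name, f, lo, hi in zip(s.names, s.forces, s.active_lower, s.active_upper):
            tag = "lower" if lo else ("upper" if hi else "")
            lines.append(f"{name:<30}{f:>12.1f}{tag:>10}")
        if self._loads is not None:
            lines.append("-" * 53)
            lines.append("joint contact force magnitudes (N):")
            for j, mag in self.contact_forces()["magnitude_N"].items():
                lines.append(f"  {j:<25}{mag:>12.0f}")
        return "\n".join(lines)
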