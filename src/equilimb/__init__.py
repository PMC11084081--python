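"""equilimb — static musculoskeletal analysis of the standing equine hindlimb.

Inverse-statics net joint moments, cubic PCSA-normalized static
optimization of the redundant muscle forces, joint contact forces, and
FEA-ready femoral load-case export.
"""

from importlib import resources as _resources

from . import contact, geometry, loadcase, optimize, report, statics, synthetic, system
from .errors import ConvergenceError, EquilimbError, GeometryError, InfeasibleError, SchemaError
from .geometry import (
    Actuator,
    Joint,
    LimbGeometry,
    Segment,
    derive_joint_centers,
    effective_direction,
    fit_sphere,
    read_geometry,
    write_geometry,
)
from .model import StandingLimbModel, StandingLimbResults
from .optimize import BoundSpec, ForceSolution, default_bounds, kkt_residual, solve_forces
from .statics import ground_reaction, net_joint_moments, segment_loads, standing_loads
from .system import assemble_system

__version__ = "0.1.0"


def packaged_data(name: str):
    """Path-like handle to a data file shipped with the package."""
    return _resources.files("equilimb.data").joinpath(name)


def standing_forces_table():
    """The reported standing-limb force table (inputs for derived reports)."""
    import pandas as pd

    with _resources.as_file(packaged_data("standing_forces.csv")) as p:
        df = pd.read_csv(p)
    df["attaches_femur"] = df["attaches_femur"].astype(bool)
    df["muscle_group"] = df["muscle_group"].fillna("")
    return df


def material_cards():
    """Shipped implant/bone material cards (MPa)."""
    with _resources.as_file(packaged_data("materials.yaml")) as p:
        return report.load_material_cards(p)


def peak_stresses():
    """Shipped worst-case FEA peak stresses (MPa) used for safety factors."""
    import yaml

    with _resources.as_file(packaged_data("materials.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)["peak_stresses_MPa"]
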