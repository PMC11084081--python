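"""FEA load-case export for the femur.

The downstream finite-element analysis loads the femur with every muscular
force that (a) attaches to the femur and (b) strictly exceeds a cutoff
(100 N by default — forces of roughly a kilogram-force or less have no
relevant effect on stress distribution or osteosynthesis stability).  Each
force is distributed uniformly over a named attachment area; the femoral
condyles are modeled as bearings rather than loads: the medial condyle
contact area is a fixed support and the lateral condyle is constrained in
the proximal-distal and anterior-posterior directions, leaving
medial-lateral strain free to avoid static overdetermination.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .geometry import LimbGeometry, effective_direction
from .optimize import ForceSolution

SCHEMA_VERSION = 1

DEFAULT_THRESHOLD_N = 100.0

DEFAULT_BOUNDARY_CONDITIONS = {
    "medial_condyle": {"type": "fixed_support"},
    "lateral_condyle": {
        "type": "constrained",
        "constrained_directions": ["proximal-distal", "anterior-posterior"],
    },
}


@dataclass(frozen=True)
class LoadCaseEntry:
    name: str
    force: tuple  # (Fx, Fy, Fz) N
    area_label: str
    distribution: str = "uniform"

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.force))


@dataclass
class LoadCase:
    """Femoral force set plus boundary-condition metadata for FEA handoff."""

    entries: list = field(default_factory=list)
    boundary_conditions: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDARY_CONDITIONS))
    include_contact_loads: bool = False
    contact_loads: list = field(default_factory=list)  # optional hip/patellofemoral contact entries

    @property
    def names(self):
        return [e.name for e in self.entries]


def select_femoral_loads(solution: ForceSolution, geometry: LimbGeometry,
                         threshold: float = DEFAULT_THRESHOLD_N) -> list:
    """Load-case entries for femur-attached actuators with force > threshold.

    'Exceed' is read strictly: a force of exactly ``threshold`` is excluded.
    """
    entries = []
    for actuator in geometry.actuators:
        if not actuator.attaches_femur:
            continue
        f = solution.force(actuator.name)
        if f > threshold:
            vec = f * effective_direction(actuator)
            entries.append(
                LoadCaseEntry(
                    name=actuator.name,
                    force=tuple(float(x) for x in vec),
                    area_label=actuator.area_label or actuator.name,
                )
            )
    return entries


def filter_force_table(names, forces, attaches_femur,
                       threshold: float = DEFAULT_THRESHOLD_N) -> list:
    """Names passing the femur-attachment + strict-threshold filter, applied
    to a plain force table (no geometry needed)."""
    return [
        n
        for n, f, femur in zip(names, forces, attaches_femur)
        if femur and f > threshold
    ]


def build_loadcase(solution: ForceSolution, geometry: LimbGeometry,
                   threshold: float = DEFAULT_THRESHOLD_N,
                   boundary_conditions: dict = None,
                   contact_loads: list = None) -> LoadCase:
    return LoadCase(
        entries=select_femoral_loads(solution, geometry, threshold),
        boundary_conditions=dict(boundary_conditions or DEFAULT_BOUNDARY_CONDITIONS),
        include_contact_loads=bool(contact_loads),
        contact_loads=list(contact_loads or []),
    )


def export_loadcase(loadcase: LoadCase, json_path, csv_path=None) -> None:
    """Write the schema-versioned JSON (and optional flat CSV) load case.

    Output is deterministic: identical input produces byte-identical files.
    """
    doc = {
        "schema": "equilimb-loadcase",
        "version": SCHEMA_VERSION,
        "units": {"force": "N"},
        "entries": [asdict(e) | {"force": list(e.force)} for e in loadcase.entries],
        "boundary_conditions": loadcase.boundary_conditions,
        "include_contact_loads": loadcase.include_contact_loads,
        "contact_loads": [asdict(e) | {"force": list(e.force)} for e in loadcase.contact_loads],
    }
    with open(json_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if csv_path is not None:
        with open(csv_path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "Fx_N", "Fy_N", "Fz_N", "area_label"])
            for e in loadcase.entries:
                writer.writerow([e.name, repr(e.force[0]), repr(e.force[1]), repr(e.force[2]), e.area_label])


def read_loadcase(json_path) -> LoadCase:
    """Round-trip reader for :func:`export_loadcase` JSON output."""
    with open(json_path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema") != "equilimb-loadcase":
        raise ValueError(f"{json_path}: not an equilimb load-case document")
    mk = lambda e: LoadCaseEntry(
        name=e["name"], force=tuple(e["force"]), area_label=e["area_label"],
        distribution=e.get("distribution", "uniform"),
    )
    return LoadCase(
        entries=[mk(e) for e in doc["entries"]],
        boundary_conditions=doc["boundary_conditions"],
        include_contact_loads=doc.get("include_contact_loads", False),
        contact_loads=[mk(e) for e in doc.get("contact_loads", [])],
    )
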