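"""Limb geometry: coordinate conventions, data model, joint-center construction, file I/O.

Coordinate convention
---------------------
One right-handed Cartesian frame for the whole limb, lengths in meters,
``+z`` vertically up.  Gravity acts along ``-z``.  All attachment points,
joint centers and centers of mass live in this single frame.

The three joints of interest in the standing hindlimb are the coxofemoral
(hip), femorotibial (stifle) and femoropatellar (patella-femur) joints.
Their centers of rotation are constructed from bony landmarks:

* coxofemoral — center of a least-squares sphere fitted to points sampled
  on the femoral-head surface;
* femorotibial — midpoint of the lateral and medial femoral epicondyles;
* femoropatellar — the patella-femur contact point, supplied directly
  (in square standing the complex joint reduces to a contact point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
import yaml

from .errors import GeometryError, SchemaError

HIP = "coxofemoral"
STIFLE = "femorotibial"
PATELLOFEMORAL = "femoropatellar"
STANDARD_JOINTS = (HIP, STIFLE, PATELLOFEMORAL)

SEGMENT_NAMES = ("thigh", "crus", "metatarsus", "hind pastern", "hind hoof")

_WEIGHT_TOL = 1e-9


def as_point(value, what: str = "point") -> np.ndarray:
    """Coerce to a finite float64 3-vector."""
    p = np.asarray(value, dtype=float).reshape(-1)
    if p.shape != (3,):
        raise GeometryError(f"{what} must have 3 components, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise GeometryError(f"{what} has non-finite components: {p}")
    return p


@dataclass(frozen=True)
class Joint:
    """A center of rotation."""

    name: str
    center: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", as_point(self.center, f"joint {self.name!r} center"))


@dataclass(frozen=True)
class Segment:
    """A limb subunit carrying a share of body mass at its center of mass."""

    name: str
    mass_fraction: float
    com: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "com", as_point(self.com, f"segment {self.name!r} com"))
        if not (0.0 <= self.mass_fraction < 1.0):
            raise GeometryError(
                f"segment {self.name!r}: mass_fraction must be in [0, 1), got {self.mass_fraction}"
            )


@dataclass(frozen=True)
class Actuator:
    """A muscle or ligament modeled as a line actuator.

    A single force magnitude acts along :func:`effective_direction`.  The
    moment about a joint is produced at ``attachment_points`` (1-3 points
    with weights summing to 1; default a single point at the insertion).
    ``attachment_overrides`` may pin a specific point per joint, for
    actuators whose relevant attachment differs between spanned joints.
    """

    name: str
    kind: str  # "muscle" | "ligament"
    origin: np.ndarray
    insertion: np.ndarray
    pcsa: float  # m^2; effective area for ligaments
    f_max: float  # N, maximum (isometric) force
    f_min: float = 0.0  # N, explicit floor; rule-based floors in optimize.default_bounds
    direction_override: Optional[np.ndarray] = None
    attachment_points: Optional[tuple] = None  # ((point, weight), ...)
    attachment_overrides: Optional[dict] = None  # joint name -> point
    spans: frozenset = frozenset()
    attaches_femur: bool = False
    area_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "origin", as_point(self.origin, f"{self.name!r} origin"))
        object.__setattr__(self, "insertion", as_point(self.insertion, f"{self.name!r} insertion"))
        if self.kind not in ("muscle", "ligament"):
            raise GeometryError(f"{self.name!r}: kind must be 'muscle' or 'ligament', got {self.kind!r}")
        if self.direction_override is not None:
            d = as_point(self.direction_override, f"{self.name!r} direction_override")
            n = np.linalg.norm(d)
            if n == 0.0:
                raise GeometryError(f"{self.name!r}: direction_override is the zero vector")
            object.__setattr__(self, "direction_override", d / n)
        if self.attachment_points is None:
            object.__setattr__(self, "attachment_points", ((self.insertion, 1.0),))
        else:
            pts = tuple(
                (as_point(p, f"{self.name!r} attachment point"), float(w))
                for p, w in self.attachment_points
            )
            if not 1 <= len(pts) <= 3:
                raise GeometryError(f"{self.name!r}: 1-3 attachment points required, got {len(pts)}")
            wsum = sum(w for _, w in pts)
            if abs(wsum - 1.0) > _WEIGHT_TOL:
                raise GeometryError(
                    f"{self.name!r}: attachment weights must sum to 1 (got {wsum!r})"
                )
            object.__setattr__(self, "attachment_points", pts)
        if self.attachment_overrides is not None:
            object.__setattr__(
                self,
                "attachment_overrides",
                {j: as_point(p, f"{self.name!r} override for {j!r}") for j, p in self.attachment_overrides.items()},
            )
        if self.f_min < 0:
            raise GeometryError(f"{self.name!r}: f_min must be >= 0, got {self.f_min}")
        if self.f_min > self.f_max:
            raise GeometryError(f"{self.name!r}: f_min {self.f_min} exceeds f_max {self.f_max}")
        if self.kind == "muscle" and not self.pcsa > 0:
            raise GeometryError(f"{self.name!r}: muscle pcsa must be > 0, got {self.pcsa}")
        if self.kind == "ligament" and self.pcsa < 0:
            raise GeometryError(f"{self.name!r}: pcsa must be >= 0, got {self.pcsa}")
        object.__setattr__(self, "spans", frozenset(self.spans))

    def attachment_for(self, joint_name: str):
        """Weighted attachment points used for the moment about ``joint_name``."""
        if self.attachment_overrides and joint_name in self.attachment_overrides:
            return ((self.attachment_overrides[joint_name], 1.0),)
        return self.attachment_points


@dataclass
class LimbGeometry:
    """Joints, segments and actuators of one hindlimb in a common frame."""

    joints: list
    actuators: list
    segments: list = field(default_factory=list)
    body_mass: float = 0.0
    hoof_contact: np.ndarray = None

    def __post_init__(self):
        if self.hoof_contact is None:
            self.hoof_contact = np.zeros(3)
        self.hoof_contact = as_point(self.hoof_contact, "hoof_contact")
        names = [j.name for j in self.joints]
        if len(set(names)) != len(names):
            raise GeometryError(f"duplicate joint names: {sorted(names)}")
        if self.body_mass < 0:
            raise GeometryError(f"body_mass must be >= 0, got {self.body_mass}")
        joint_set = set(names)
        for a in self.actuators:
            missing = a.spans - joint_set
            if missing:
                raise GeometryError(
                    f"actuator {a.name!r} spans unknown joint(s) {sorted(missing)}"
                )

    def joint(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise GeometryError(f"no joint named {name!r}")

    def actuator(self, name: str) -> Actuator:
        for a in self.actuators:
            if a.name == name:
                return a
        raise GeometryError(f"no actuator named {name!r}")

    @property
    def joint_names(self):
        return [j.name for j in self.joints]

    def translated(self, t) -> "LimbGeometry":
        """A copy with every point shifted by ``t`` (frame change)."""
        t = as_point(t, "translation")
        return self._transformed(lambda p: p + t)

    def rotated(self, R) -> "LimbGeometry":
        """A copy with every point and direction rotated by the 3x3 matrix ``R``."""
        R = np.asarray(R, dtype=float)
        return self._transformed(lambda p: R @ p, lambda d: R @ d)

    def _transformed(self, f, fdir=None):
        if fdir is None:
            fdir = lambda d: d  # translations leave directions alone
        acts = []
        for a in self.actuators:
            acts.append(
                replace(
                    a,
                    origin=f(a.origin),
                    insertion=f(a.insertion),
                    direction_override=None if a.direction_override is None else fdir(a.direction_override),
                    attachment_points=tuple((f(p), w) for p, w in a.attachment_points),
                    attachment_overrides=None
                    if a.attachment_overrides is None
                    else {j: f(p) for j, p in a.attachment_overrides.items()},
                )
            )
        return LimbGeometry(
            joints=[Joint(j.name, f(j.center)) for j in self.joints],
            actuators=acts,
            segments=[Segment(s.name, s.mass_fraction, f(s.com)) for s in self.segments],
            body_mass=self.body_mass,
            hoof_contact=f(self.hoof_contact),
        )


class SphereFit(NamedTuple):
    center: np.ndarray
    radius: float
    residual: float  # RMS orthogonal distance of the points from the fitted sphere


def fit_sphere(points: Sequence, refine: bool = True, tol: float = 1e-10) -> SphereFit:
    """Least-squares sphere through >= 4 non-coplanar points.

    Algebraic (linear) fit minimizing ``| |p-c|^2 - r^2 |``, optionally
    polished by geometric least squares on the orthogonal distances.
    Exact sphere data is recovered to solver tolerance.
    """
    P = np.asarray([as_point(p, "sphere point") for p in points], dtype=float)
    if P.shape[0] < 4:
        raise GeometryError(f"sphere fit needs >= 4 points, got {P.shape[0]}")
    # |p|^2 = 2 p.c + (r^2 - |c|^2): linear in (c, r^2 - |c|^2)
    A = np.hstack([2.0 * P, np.ones((P.shape[0], 1))])
    b = np.einsum("ij,ij->i", P, P)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise GeometryError("sphere fit is degenerate: points are coplanar or coincident")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise GeometryError("sphere fit is degenerate: non-positive squared radius")
    radius = math.sqrt(r2)

    if refine:
        from scipy.optimize import least_squares

        def resid(x):
            return np.linalg.norm(P - x[:3], axis=1) - x[3]

        out = least_squares(resid, np.append(center, radius), xtol=tol, ftol=tol, gtol=tol)
        center, radius = out.x[:3], float(out.x[3])

    residual = float(np.sqrt(np.mean((np.linalg.norm(P - center, axis=1) - radius) ** 2)))
    return SphereFit(center=center, radius=float(radius), residual=residual)


def derive_joint_centers(landmarks: dict) -> list:
    """Construct the three standard joint centers from a landmark table.

    ``landmarks`` keys:

    * ``"femoral_head_points"`` — points on the femoral-head surface
      (sphere-fitted for the coxofemoral center);
    * ``"lateral_epicondyle"``, ``"medial_epicondyle"`` — femorotibial
      center is their midpoint;
    * ``"patellar_contact_point"`` — the femoropatellar center directly.
    """
    import warnings

    required = ("femoral_head_points", "lateral_epicondyle", "medial_epicondyle", "patellar_contact_point")
    for key in required:
        if key not in landmarks:
            raise GeometryError(f"missing landmark {key!r}")
    hip_center = fit_sphere(landmarks["femoral_head_points"]).center
    lat = as_point(landmarks["lateral_epicondyle"], "lateral_epicondyle")
    med = as_point(landmarks["medial_epicondyle"], "medial_epicondyle")
    if np.array_equal(lat, med):
        warnings.warn("lateral and medial epicondyles coincide; femorotibial center degenerate")
    stifle_center = 0.5 * (lat + med)
    pf = as_point(landmarks["patellar_contact_point"], "patellar_contact_point")
    return [Joint(HIP, hip_center), Joint(STIFLE, stifle_center), Joint(PATELLOFEMORAL, pf)]


def effective_direction(actuator: Actuator) -> np.ndarray:
    """Unit line of action: origin->insertion, or the near-insertion override.

    The override models curved muscles (biceps femoris, semitendinosus,
    semimembranosus) whose resulting force direction near the insertion
    differs from the straight origin-insertion chord.
    """
    if actuator.direction_override is not None:
        return actuator.direction_override  # normalized at construction
    v = actuator.insertion - actuator.origin
    n = np.linalg.norm(v)
    if n == 0.0:
        raise GeometryError(
            f"actuator {actuator.name!r}: origin equals insertion and no direction_override given"
        )
    return v / n


# ---------------------------------------------------------------------------
# File I/O — structured YAML document, units meters / newtons.

_SCHEMA_VERSION = 1


def _point_to_list(p):
    return [float(x) for x in p]


def write_geometry(geometry: LimbGeometry, path) -> None:
    """Serialize to the package's YAML geometry schema (meters / newtons)."""
    doc = {
        "schema": "equilimb-geometry",
        "version": _SCHEMA_VERSION,
        "units": {"length": "m", "force": "N", "area": "m^2"},
        "body_mass_kg": float(geometry.body_mass),
        "hoof_contact": _point_to_list(geometry.hoof_contact),
        "joints": [{"name": j.name, "center": _point_to_list(j.center)} for j in geometry.joints],
        "segments": [
            {"name": s.name, "mass_fraction": float(s.mass_fraction), "com": _point_to_list(s.com)}
            for s in geometry.segments
        ],
        "actuators": [],
    }
    for a in geometry.actuators:
        entry = {
            "name": a.name,
            "kind": a.kind,
            "origin": _point_to_list(a.origin),
            "insertion": _point_to_list(a.insertion),
            "pcsa_m2": float(a.pcsa),
            "fmax_N": float(a.f_max),
            "fmin_N": float(a.f_min),
            "spans": sorted(a.spans),
            "attaches_femur": bool(a.attaches_femur),
            "area_label": a.area_label,
        }
        if a.direction_override is not None:
            entry["direction"] = _point_to_list(a.direction_override)
        default_attach = len(a.attachment_points) == 1 and np.array_equal(
            a.attachment_points[0][0], a.insertion
        )
        if not default_attach:
            entry["attachment_points"] = [
                {"point": _point_to_list(p), "weight": float(w)} for p, w in a.attachment_points
            ]
        if a.attachment_overrides:
            entry["attachment_overrides"] = {
                j: _point_to_list(p) for j, p in a.attachment_overrides.items()
            }
        doc["actuators"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _require(mapping, key, where):
    if key not in mapping:
        raise SchemaError(f"{where}: missing field {key!r}")
    return mapping[key]


def read_geometry(path) -> LimbGeometry:
    """Parse and validate a geometry file written by :func:`write_geometry`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != "equilimb-geometry":
        raise SchemaError(f"{path}: not an equilimb geometry document")
    try:
        joints = [
            Joint(_require(j, "name", f"joints[{i}]"), _require(j, "center", f"joints[{i}]"))
            for i, j in enumerate(doc.get("joints", []))
        ]
        segments = [
            Segment(
                _require(s, "name", f"segments[{i}]"),
                float(_require(s, "mass_fraction", f"segments[{i}]")),
                _require(s, "com", f"segments[{i}]"),
            )
            for i, s in enumerate(doc.get("segments", []))
        ]
        actuators = []
        for i, a in enumerate(doc.get("actuators", [])):
            where = f"actuators[{i}]"
            kwargs = dict(
                name=_require(a, "name", where),
                kind=_require(a, "kind", where),
                origin=_require(a, "origin", where),
                insertion=_require(a, "insertion", where),
                pcsa=float(_require(a, "pcsa_m2", where)),
                f_max=float(_require(a, "fmax_N", where)),
                f_min=float(a.get("fmin_N", 0.0)),
                spans=frozenset(a.get("spans", [])),
                attaches_femur=bool(a.get("attaches_femur", False)),
                area_label=a.get("area_label", ""),
            )
            if "direction" in a:
                kwargs["direction_override"] = a["direction"]
            if "attachment_points" in a:
                kwargs["attachment_points"] = tuple(
                    (p["point"], p["weight"]) for p in a["attachment_points"]
                )
            if "attachment_overrides" in a:
                kwargs["attachment_overrides"] = dict(a["attachment_overrides"])
            actuators.append(Actuator(**kwargs))
        return LimbGeometry(
            joints=joints,
            actuators=actuators,
            segments=segments,
            body_mass=float(doc.get("body_mass_kg", 0.0)),
            hoof_contact=doc.get("hoof_contact", [0.0, 0.0, 0.0]),
        )
    except GeometryError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
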