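"""Synthetic hindlimb instances for testing the whole pipeline.

Real geometry for the standing model comes from a segmented 3D skeleton;
this module generates stand-in limbs with the same structure: a three-joint
chain (hip, stifle, patellofemoral) crossed by ~20 line actuators with
anatomically plausible lever arms (0.02-0.15 m), PCSA-scaled force bounds
and forces on the 10^2-10^3 N scale.  No anatomical realism is claimed
beyond those orders of magnitude.

Two scenario modes:

* ``"reference"`` (default) — a reference force vector ``F_ref`` is drawn
  strictly inside the bounds and the target moments are set to
  ``A @ F_ref``, so every instance is feasible by construction (targets
  derived from gravity can be unreachable under the tonus floors);
* ``"gravity"`` — segments, body mass and a hoof contact are generated and
  the target moments follow from the standing external loads; used to
  exercise the statics path.

All randomness flows through ``numpy.random.default_rng(seed)``: the same
seed reproduces the same instance on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    HIP,
    PATELLOFEMORAL,
    STIFLE,
    Actuator,
    Joint,
    LimbGeometry,
    Segment,
)
from .optimize import BoundSpec, default_bounds
from .statics import ExternalLoads, NetJointMoments, net_joint_moments, standing_loads
from .system import SystemMatrix, assemble_system

DEFAULT_CONFIG = {
    "lever_range_m": (0.02, 0.15),
    "pcsa_range_m2": (1e-3, 2e-2),
    "sigma_max_Pa": 0.3e6,  # f_max = sigma_max * pcsa -> 300-6000 N
    "tonus_fraction": 0.01,
    "ref_margin": 0.1,  # F_ref kept this fraction of the span away from both bounds
    "span_mode": "random",  # or "single": all actuators span the hip only
    "body_mass_kg": 514.0,
    "hindlimb_fraction": 0.2,
    "g": 9.81,
}

_JOINT_CENTERS = {
    HIP: np.array([0.00, 0.00, 1.00]),
    STIFLE: np.array([0.06, 0.02, 0.62]),
    PATELLOFEMORAL: np.array([0.11, 0.01, 0.66]),
}

_SPAN_CHOICES = (
    frozenset({HIP}),
    frozenset({STIFLE}),
    frozenset({PATELLOFEMORAL}),
    frozenset({HIP, STIFLE}),
    frozenset({STIFLE, PATELLOFEMORAL}),
)


@dataclass
class SyntheticInstance:
    """One generated limb with its solve target and reference solution."""

    geometry: LimbGeometry
    loads: ExternalLoads
    target_moments: NetJointMoments
    reference_forces: np.ndarray
    bounds: BoundSpec
    system: SystemMatrix = None
    pcsa: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.system is None:
            self.system = assemble_system(self.geometry)
        if self.pcsa is None:
            self.pcsa = np.array([a.pcsa for a in self.geometry.actuators])


def _unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _random_actuator(rng, index: int, config: dict, spans: frozenset) -> Actuator:
    lo, hi = config["lever_range_m"]
    if not (hi > lo > 0):
        raise ValueError(f"empty lever range {config['lever_range_m']}")
    plo, phi = config["pcsa_range_m2"]
    if not (phi > plo > 0):
        raise ValueError(f"empty pcsa range {config['pcsa_range_m2']}")
    # insertion placed at a plausible lever distance from a primary joint
    primary = sorted(spans)[rng.integers(len(spans))]
    insertion = _JOINT_CENTERS[primary] + rng.uniform(lo, hi) * _unit(rng)
    origin = insertion + rng.uniform(0.1, 0.4) * _unit(rng)
    pcsa = float(rng.uniform(plo, phi))
    f_max = pcsa * config["sigma_max_Pa"]
    overrides = {}
    for j in spans:
        if j != primary:
            overrides[j] = _JOINT_CENTERS[j] + rng.uniform(lo, hi) * _unit(rng)
    return Actuator(
        name=f"actuator_{index:02d}",
        kind="muscle",
        origin=origin,
        insertion=insertion,
        pcsa=pcsa,
        f_max=f_max,
        spans=spans,
        attaches_femur=bool(rng.integers(2)),
        area_label=f"area_{index:02d}",
        attachment_overrides=overrides or None,
    )


def _segments(rng) -> list:
    fractions = {"thigh": 0.0335, "crus": 0.0145, "metatarsus": 0.0055,
                 "hind pastern": 0.0035, "hind hoof": 0.0025}
    heights = {"thigh": 0.80, "crus": 0.45, "metatarsus": 0.20,
               "hind pastern": 0.08, "hind hoof": 0.03}
    return [
        Segment(name, frac, np.array([rng.uniform(-0.03, 0.06), rng.uniform(-0.02, 0.02), heights[name]]))
        for name, frac in fractions.items()
    ]


def generate(seed: int, n_actuators: int = 20, config: dict = None,
             mode: str = "reference") -> SyntheticInstance:
    """Generate one reproducible synthetic limb instance.

    ``n_actuators`` should comfortably exceed the number of independent
    constraint rows (9 for three joints) for the redundancy the analysis
    assumes; smaller counts are useful for exact-recovery tests.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    rng = np.random.default_rng(seed)

    joints = [Joint(name, center.copy()) for name, center in _JOINT_CENTERS.items()]
    actuators = []
    for i in range(n_actuators):
        if cfg["span_mode"] == "single":
            spans = frozenset({HIP})
        else:
            spans = _SPAN_CHOICES[rng.integers(len(_SPAN_CHOICES))]
        actuators.append(_random_actuator(rng, i, cfg, spans))

    geometry = LimbGeometry(
        joints=joints,
        actuators=actuators,
        segments=_segments(rng),
        body_mass=cfg["body_mass_kg"],
        hoof_contact=np.array([rng.uniform(0.0, 0.08), rng.uniform(-0.02, 0.02), 0.0]),
    )
    system = assemble_system(geometry)
    loads = standing_loads(geometry, cfg["hindlimb_fraction"], cfg["g"])
    grf_mag = float(np.linalg.norm(loads.grf))
    bounds = default_bounds(actuators, grf_mag, tonus_fraction=cfg["tonus_fraction"])

    margin = cfg["ref_margin"] * (bounds.upper - bounds.lower)
    f_ref = rng.uniform(bounds.lower + margin, bounds.upper - margin)

    if mode == "reference":
        stacked = system.coefficients @ f_ref
        moments = NetJointMoments(
            {j: stacked[3 * i : 3 * i + 3] for i, j in enumerate(system.joint_order)}
        )
    elif mode == "gravity":
        moments = net_joint_moments(geometry, loads).negated()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return SyntheticInstance(
        geometry=geometry,
        loads=loads,
        target_moments=moments,
        reference_forces=f_ref,
        bounds=bounds,
        system=system,
    )
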