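"""Derived reports: muscle-group force sums and implant safety factors."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import yaml

from .errors import EquilimbError


@dataclass(frozen=True)
class MaterialCard:
    """Yield and ultimate strengths (MPa, signed magnitudes) of an implant
    or bone material, as used for safety-factor assessment."""

    name: str
    yield_compressive: float
    yield_tensile: float
    ultimate_compressive: float = None
    ultimate_tensile: float = None

    def __post_init__(self):
        for attr in ("yield_compressive", "yield_tensile"):
            v = getattr(self, attr)
            if not v or abs(v) <= 0:
                raise EquilimbError(f"{self.name}: {attr} must be a positive magnitude")


def load_material_cards(path) -> dict:
    """Read material cards from a YAML file (``materials:`` mapping, MPa)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cards = {}
    for name, vals in doc.get("materials", {}).items():
        cards[name] = MaterialCard(
            name=name,
            yield_compressive=abs(vals["yield_compressive_MPa"]),
            yield_tensile=abs(vals["yield_tensile_MPa"]),
            ultimate_compressive=abs(vals.get("ultimate_compressive_MPa", 0)) or None,
            ultimate_tensile=abs(vals.get("ultimate_tensile_MPa", 0)) or None,
        )
    return cards


def group_sum(forces, member_names) -> float:
    """Arithmetic sum of named member forces.

    ``forces`` is a mapping name -> force (N) or a ForceSolution.
    Permutation-invariant and additive over disjoint groups.
    """
    if hasattr(forces, "as_dict"):
        forces = forces.as_dict()
    missing = [n for n in member_names if n not in forces]
    if missing:
        raise EquilimbError(f"unknown member name(s): {missing}")
    return float(sum(forces[n] for n in member_names))


def safety_factor(yield_MPa: float, peak_stress_MPa: float) -> float:
    """|yield| / |peak stress|, rounded half-up to one decimal.

    A value above 1 indicates no plastic deformation is expected at the
    computed peak stress.
    """
    y, p = abs(yield_MPa), abs(peak_stress_MPa)
    if p == 0:
        raise EquilimbError("peak stress must be nonzero")
    if y == 0:
        raise EquilimbError("yield strength must be nonzero")
    ratio = Decimal(repr(y)) / Decimal(repr(p))
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
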