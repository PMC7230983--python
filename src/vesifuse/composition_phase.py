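"""Ternary DOPC/EggSM/Chol composition arithmetic and phase-region lookup.

Compositions are stored as non-negative "parts" (e.g. 1:1:3) with derived
mole fractions. Two mixing rules are provided for the composition of a
fused vesicle:

``mix_amounts``
    Componentwise summation of ratio parts with the given weights. For
    equal-sized vesicles this reproduces the conventional bench
    arithmetic: 1:1:0 combined with 1:1:3 gives 2:2:3. Note that if the
    parts are read as mole fractions this rule is not mole-conserving;
    it is nonetheless the rule practitioners quote, so it is the default.

``mix_fractions``
    Area-weighted averaging of mole fractions (equal area per molecule),
    which *is* conserving: the same pair at equal areas gives 7:7:6.

The discrepancy between the two is documented rather than resolved; the
underlying convention for ratio notation is ambiguous in common usage.

Phase lookup classifies a composition against labelled polygonal regions
on the ternary simplex. The shipped default diagram is schematic — it is
constructed so that the canonical compositions land in the phases observed
experimentally (1:1:0 gel/liquid, 1:1:3 uniform liquid, 2:2:3 and 1:1:1
Lo/Ld coexistence) — and is NOT an empirical phase diagram; supply a
measured one for real work.

Barycentric convention: (DOPC, EggSM, Chol) map to the bottom-left,
bottom-right and top vertices of a unit-edge triangle, with Cartesian
embedding x = EggSM + Chol/2, y = (sqrt(3)/2) * Chol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import List, Optional, Sequence, Tuple

from shapely.geometry import Point, Polygon

__all__ = [
    "TernaryComposition",
    "PhaseRegion",
    "PhaseDiagram",
    "PHASE_LABELS",
    "mix_amounts",
    "mix_fractions",
    "to_integer_ratio",
    "phase_lookup",
    "barycentric_to_cartesian",
    "cartesian_to_barycentric",
    "load_phase_diagram",
    "default_phase_diagram",
]

LIPIDS = ("DOPC", "EggSM", "Chol")

PHASE_LABELS = (
    "gel_liquid_coexistence",
    "uniform_liquid",
    "Lo_Ld_coexistence",
    "other",
)

UNASSIGNED = "unassigned"

_SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class TernaryComposition:
    """A DOPC/EggSM/Chol composition held as non-negative ratio parts."""

    dopc: float
    eggsm: float
    chol: float
    probe_mol_percent: float = 0.0  # fluorescent probe, metadata only

    def __post_init__(self) -> None:
        parts = (self.dopc, self.eggsm, self.chol)
        if any(p < 0 for p in parts):
            raise ValueError(f"composition parts cannot be negative: {parts}")
        if sum(parts) <= 0:
            raise ValueError("at least one lipid amount must be positive")

    @classmethod
    def from_ratio(cls, text: str) -> "TernaryComposition":
        """Parse ``"2:2:3"`` into a composition."""
        parts = [float(p) for p in text.split(":")]
        if len(parts) != 3:
            raise ValueError(f"expected three ':'-separated parts, got {text!r}")
        return cls(*parts)

    @property
    def amounts(self) -> Tuple[float, float, float]:
        return (self.dopc, self.eggsm, self.chol)

    @property
    def fractions(self) -> Tuple[float, float, float]:
        """Mole fractions, normalised to sum to 1."""
        total = self.dopc + self.eggsm + self.chol
        return (self.dopc / total, self.eggsm / total, self.chol / total)

    def ratio_string(self, tolerance: float = 1e-6) -> str:
        return ":".join(str(n) for n in to_integer_ratio(self, tolerance))

    def __repr__(self) -> str:
        return f"TernaryComposition({self.dopc:g}:{self.eggsm:g}:{self.chol:g})"


def mix_amounts(
    c1: TernaryComposition,
    w1: float,
    c2: TernaryComposition,
    w2: float,
) -> TernaryComposition:
    """Mix by weighted componentwise summation of ratio parts.

    Equal weights on 1:1:0 and 1:1:3 give 2:2:3, the bench arithmetic for
    fusing two identical vesicles. Commutative and scale-invariant in the
    weights up to overall normalisation of parts.
    """
    if w1 <= 0 or w2 <= 0:
        raise ValueError("mixing weights must be positive")
    return TernaryComposition(
        w1 * c1.dopc + w2 * c2.dopc,
        w1 * c1.eggsm + w2 * c2.eggsm,
        w1 * c1.chol + w2 * c2.chol,
    )


def mix_fractions(
    c1: TernaryComposition,
    area1_um2: float,
    c2: TernaryComposition,
    area2_um2: float,
) -> TernaryComposition:
    """Mix by area-weighted averaging of mole fractions.

    Assumes equal area per molecule so that membrane area is proportional
    to mole number; this rule conserves moles of each species.
    """
    if area1_um2 <= 0 or area2_um2 <= 0:
        raise ValueError("membrane areas must be positive")
    f1, f2 = c1.fractions, c2.fractions
    total = area1_um2 + area2_um2
    mixed = tuple((area1_um2 * a + area2_um2 * b) / total for a, b in zip(f1, f2))
    return TernaryComposition(*mixed)


def to_integer_ratio(
    c: TernaryComposition, tolerance: float = 1e-6, max_denominator: int = 1000
) -> Tuple[int, int, int]:
    """Smallest integer triple proportional to the composition's parts.

    Each mole fraction is rationalised with denominator at most
    ``max_denominator``; if the resulting triple reproduces the fractions
    to the requested relative tolerance it is reduced and returned,
    otherwise the fractions are scaled by ``max_denominator`` and rounded.
    """
    fracs = c.fractions
    rationals = [Fraction(f).limit_denominator(max_denominator) for f in fracs]
    lcm = 1
    for r in rationals:
        lcm = lcm * r.denominator // math.gcd(lcm, r.denominator)
    ints = [int(r * lcm) for r in rationals]
    g = math.gcd(math.gcd(ints[0], ints[1]), ints[2])
    if g > 0:
        ints = [i // g for i in ints]
    total = sum(ints)
    if total > 0:
        ok = all(
            abs(i / total - f) <= tolerance * max(f, 1e-30) + 1e-15
            for i, f in zip(ints, fracs)
        )
        if ok:
            return tuple(ints)  # type: ignore[return-value]
    scaled = [round(f * max_denominator) for f in fracs]
    g = math.gcd(math.gcd(scaled[0], scaled[1]), scaled[2])
    if g > 0:
        scaled = [s // g for s in scaled]
    return tuple(scaled)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Ternary simplex embedding


def barycentric_to_cartesian(fractions: Sequence[float]) -> Tuple[float, float]:
    """Map (DOPC, EggSM, Chol) fractions to the unit-edge triangle plane."""
    _, eggsm, chol = fractions
    return (eggsm + 0.5 * chol, _SQRT3_2 * chol)


def cartesian_to_barycentric(x: float, y: float) -> Tuple[float, float, float]:
    """Inverse of :func:`barycentric_to_cartesian`."""
    chol = y / _SQRT3_2
    eggsm = x - 0.5 * chol
    return (1.0 - eggsm - chol, eggsm, chol)


# ---------------------------------------------------------------------------
# Phase diagram


@dataclass(frozen=True)
class PhaseRegion:
    """One labelled polygonal region in barycentric composition space."""

    label: str
    vertices: Tuple[Tuple[float, float, float], ...]
    polygon: Polygon = field(compare=False, repr=False, default=None)  # type: ignore

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {self.label!r}; expected one of {PHASE_LABELS}")
        if len(self.vertices) < 3:
            raise ValueError("a phase region needs at least three vertices")
        poly = Polygon([barycentric_to_cartesian(v) for v in self.vertices])
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"degenerate polygon for region {self.label!r}")
        object.__setattr__(self, "polygon", poly)


@dataclass(frozen=True)
class PhaseDiagram:
    """Labelled regions tiling (part of) the ternary simplex.

    Regions may not overlap in their interiors; a query point on a shared
    boundary is assigned to the region listed first (deterministic rule).
    """

    regions: Tuple[PhaseRegion, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                inter = a.polygon.intersection(b.polygon)
                if inter.area > 1e-9:
                    raise ValueError(
                        f"regions {a.label!r} and {b.label!r} overlap (area {inter.area:g})"
                    )

    def classify(self, c: TernaryComposition) -> str:
        return phase_lookup(c, self)


def phase_lookup(c: TernaryComposition, diagram: PhaseDiagram) -> str:
    """Phase label at a composition; ``"unassigned"`` outside all regions.

    Boundary points are assigned to the first region (file order) whose
    closed polygon covers them; never a silent default.
    """
    pt = Point(barycentric_to_cartesian(c.fractions))
    for region in diagram.regions:
        if region.polygon.covers(pt) or region.polygon.distance(pt) < 1e-12:
            return region.label
    return UNASSIGNED


def _diagram_from_dict(payload: dict) -> PhaseDiagram:
    regions = tuple(
        PhaseRegion(r["label"], tuple(tuple(v) for v in r["vertices"]))
        for r in payload["regions"]
    )
    return PhaseDiagram(regions=regions, provenance=payload.get("provenance", ""))


def load_phase_diagram(path: str) -> PhaseDiagram:
    """Load a phase diagram from a JSON file.

    Expected schema: ``{"provenance": str, "regions": [{"label": str,
    "vertices": [[dopc, eggsm, chol], ...]}, ...]}`` with barycentric
    vertex triples summing to 1.
    """
    with open(path, "r", encoding="utf-8") as fh:
        return _diagram_from_dict(json.load(fh))


def default_phase_diagram() -> PhaseDiagram:
    """The shipped schematic DOPC/EggSM/Chol diagram.

    Schematic and illustrative only — region boundaries are simple
    cholesterol-fraction cuts chosen to place the canonical compositions
    in their experimentally observed phases, not fitted to measurements.
    """
    payload = json.loads(
        resources.files("vesifuse")
        .joinpath("data/schematic_phase_diagram.json")
        .read_text(encoding="utf-8")
    )
    return _diagram_from_dict(payload)
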