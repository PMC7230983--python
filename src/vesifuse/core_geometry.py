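"""Adhesion geometry of two identical giant unilamellar vesicles.

When two equal-sized vesicles adhere they each deform into a truncated
sphere that shares a flat circular contact patch. Because the enclosed
volume is conserved during adhesion, the truncation forces the membrane
area of each vesicle to grow relative to the free sphere. The fractional
area increase depends only on the contact angle ``theta``, defined as the
arcsine of the adhesion-patch diameter normalised by the vesicle diameter:

    f(theta) = (3 - cos theta)
               / (2**(2/3) * (1 + cos theta)**(1/3) * (2 - cos theta)**(2/3))
               - 1

The flat patch disc is counted as part of each vesicle's membrane area;
with that convention the closed form above is exactly the truncated-sphere
area ratio at conserved volume. A stretched membrane develops extra
tension; in the linear-elastic regime the increase is the area-expansion
modulus times the area strain.

Angles are radians internally. Contact angles beyond 90 degrees would put
the patch past the equator, outside the truncated-sphere model, and are
rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Vesicle",
    "AdhesionPair",
    "MembraneMechanics",
    "area_increase_fraction",
    "contact_angle_from_patch",
    "patch_diameter_from_angle",
    "tension_increase",
]

#: Default area-expansion modulus for a fluid phospholipid bilayer, mJ/m^2.
DEFAULT_AREA_EXPANSION_MODULUS = 200.0

_HALF_PI = math.pi / 2.0
_ANGLE_TOL = 1e-12


@dataclass
class Vesicle:
    """A giant unilamellar vesicle.

    Parameters
    ----------
    radius_um:
        Vesicle radius in micrometres; must be positive.
    composition:
        Ternary lipid composition (``composition_phase.TernaryComposition``)
        or ``None`` when composition is not tracked.
    internal_solution, external_solution:
        Solute mixtures (``fusion_model.SoluteMixture``) or ``None``.
    tension_un_per_m:
        Membrane tension in uN/m, optional; non-negative when present.
    has_excess_area:
        True for flaccid vesicles with visible tubules / excess membrane.
    aunp_labelled:
        True when the membrane carries gold nanoparticles.
    """

    radius_um: float
    composition: Optional[object] = None
    internal_solution: Optional[object] = None
    external_solution: Optional[object] = None
    tension_un_per_m: Optional[float] = None
    has_excess_area: bool = False
    aunp_labelled: bool = False

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError(f"vesicle radius must be positive, got {self.radius_um}")
        if self.tension_un_per_m is not None and self.tension_un_per_m < 0:
            raise ValueError("membrane tension cannot be negative")

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um

    @property
    def area_um2(self) -> float:
        """Membrane area of the undeformed sphere, um^2."""
        return 4.0 * math.pi * self.radius_um**2

    @property
    def volume_um3(self) -> float:
        """Enclosed volume, um^3."""
        return (4.0 / 3.0) * math.pi * self.radius_um**3


@dataclass
class AdhesionPair:
    """Two identical adhered vesicles characterised by a contact angle.

    The truncated-sphere model is derived for identical vesicles only;
    constructing a pair from vesicles of different radii raises
    ``ValueError`` rather than silently approximating.
    """

    vesicle_a: Vesicle
    vesicle_b: Vesicle
    contact_angle_rad: float
    patch_diameter_um: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ra, rb = self.vesicle_a.radius_um, self.vesicle_b.radius_um
        if not math.isclose(ra, rb, rel_tol=1e-9):
            raise ValueError(
                "adhesion geometry is modelled for identical vesicles only; "
                f"got radii {ra} and {rb} um"
            )
        _check_angle(self.contact_angle_rad)
        expected = patch_diameter_from_angle(
            self.contact_angle_rad, self.vesicle_a.diameter_um
        )
        if self.patch_diameter_um is None:
            self.patch_diameter_um = expected
        elif not math.isclose(self.patch_diameter_um, expected, rel_tol=1e-6, abs_tol=1e-9):
            raise ValueError(
                f"patch diameter {self.patch_diameter_um} um inconsistent with "
                f"contact angle (expected {expected:.6g} um)"
            )

    @property
    def area_increase_fraction(self) -> float:
        return area_increase_fraction(self.contact_angle_rad)


@dataclass(frozen=True)
class MembraneMechanics:
    """Linear-elastic membrane stretching parameters.

    ``area_expansion_modulus_mj_m2`` is K_A in mJ/m^2 (equivalently mN/m);
    the default 200 is typical of fluid phosphatidylcholine bilayers.
    """

    area_expansion_modulus_mj_m2: float = DEFAULT_AREA_EXPANSION_MODULUS

    def __post_init__(self) -> None:
        if not self.area_expansion_modulus_mj_m2 > 0:
            raise ValueError("area expansion modulus must be positive")


def _check_angle(theta_rad: float) -> None:
    if not (-_ANGLE_TOL <= theta_rad <= _HALF_PI + _ANGLE_TOL):
        raise ValueError(
            f"contact angle {theta_rad} rad outside [0, pi/2]; the truncated-"
            "sphere model holds only for patches at or below the equator"
        )


def area_increase_fraction(contact_angle_rad: float) -> float:
    """Fractional membrane-area increase of an adhered vesicle, f(theta).

    Closed-form area ratio of a volume-conserving truncated sphere (flat
    patch included) relative to the free sphere, minus one. Zero at
    theta = 0 and strictly increasing up to theta = pi/2.

    Parameters
    ----------
    contact_angle_rad:
        Contact angle in radians, in [0, pi/2].

    Returns
    -------
    float
        Dimensionless area-increase fraction, >= 0.
    """
    _check_angle(contact_angle_rad)
    c = math.cos(contact_angle_rad)
    ratio = (3.0 - c) / (2.0 ** (2.0 / 3.0) * (1.0 + c) ** (1.0 / 3.0) * (2.0 - c) ** (2.0 / 3.0))
    return max(ratio - 1.0, 0.0)


def contact_angle_from_patch(patch_diameter_um: float, vesicle_diameter_um: float) -> float:
    """Contact angle (radians) from patch and vesicle diameters.

    Defined as ``arcsin(patch_diameter / vesicle_diameter)``.
    """
    if vesicle_diameter_um <= 0:
        raise ValueError("vesicle diameter must be positive")
    if patch_diameter_um < 0:
        raise ValueError("patch diameter cannot be negative")
    x = patch_diameter_um / vesicle_diameter_um
    if x > 1.0 + 1e-12:
        raise ValueError(
            f"patch diameter {patch_diameter_um} exceeds vesicle diameter "
            f"{vesicle_diameter_um}"
        )
    return math.asin(min(x, 1.0))


def patch_diameter_from_angle(contact_angle_rad: float, vesicle_diameter_um: float) -> float:
    """Inverse of :func:`contact_angle_from_patch`."""
    _check_angle(contact_angle_rad)
    if vesicle_diameter_um <= 0:
        raise ValueError("vesicle diameter must be positive")
    return vesicle_diameter_um * math.sin(contact_angle_rad)


def tension_increase(mechanics: MembraneMechanics, area_fraction: float) -> float:
    """Membrane-tension increase in uN/m for a given area strain.

    Linear elastic law: delta_tau = K_A * (delta_A / A0). K_A in mJ/m^2
    equals mN/m, so the result in uN/m is ``1000 * K_A * area_fraction``.
    """
    if area_fraction < 0:
        raise ValueError("area fraction cannot be negative")
    return 1000.0 * mechanics.area_expansion_modulus_mj_m2 * area_fraction
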