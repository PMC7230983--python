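"""Steady-state temperature field around a laser-heated gold nanoparticle.

A membrane-bound plasmonic nanoparticle absorbing power P in a medium of
thermal conductivity k reaches a steady surface temperature rise

    dT_s = P / (4 pi k a)

(point-absorber solution; the metal is treated as isothermal, so the rise
is flat inside the particle). Outside, heat conduction gives the 1/r
field dT(r) = dT_s * a / r — the elevation is confined to a zone of
roughly the particle size, which is why a >100 degC surface rise can
coexist with sub-degree heating a vesicle radius away.

Absorbed power is an input, not derived from laser power: converting one
to the other needs an absorption cross-section that is outside this
model. Likewise the few-degree bulk warming of the sample at the laser
focus (default 5 degC, typical estimates 4-6 degC) is a configured
constant, not computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "NanoparticleHeatSource",
    "surface_temperature_rise",
    "temperature_at",
    "hot_zone_extent",
]

#: Thermal conductivity of water at room temperature, W/(m K).
WATER_CONDUCTIVITY_W_M_K = 0.6

#: Default particle radius, nm (150 nm diameter AuNPs).
DEFAULT_NP_RADIUS_NM = 75.0

#: Default bulk temperature rise at the laser focus, degC.
DEFAULT_AMBIENT_RISE_C = 5.0


@dataclass(frozen=True)
class NanoparticleHeatSource:
    """A heated nanoparticle: radius, absorbed power, medium conductivity."""

    np_radius_nm: float = DEFAULT_NP_RADIUS_NM
    absorbed_power_uw: float = 0.0
    conductivity_w_m_k: float = WATER_CONDUCTIVITY_W_M_K
    ambient_rise_c: float = DEFAULT_AMBIENT_RISE_C

    def __post_init__(self) -> None:
        if not self.np_radius_nm > 0:
            raise ValueError("nanoparticle radius must be positive")
        if not self.conductivity_w_m_k > 0:
            raise ValueError("thermal conductivity must be positive")
        if self.absorbed_power_uw < 0:
            raise ValueError("absorbed power cannot be negative")


def surface_temperature_rise(source: NanoparticleHeatSource) -> float:
    """Steady-state temperature rise at the particle surface, degC.

    dT_s = P_abs / (4 pi k a); linear in absorbed power, inverse in
    particle radius and medium conductivity.
    """
    p_w = source.absorbed_power_uw * 1e-6
    a_m = source.np_radius_nm * 1e-9
    return p_w / (4.0 * math.pi * source.conductivity_w_m_k * a_m)


def temperature_at(
    source: NanoparticleHeatSource,
    r_nm: Union[float, np.ndarray],
    include_ambient: bool = False,
) -> Union[float, np.ndarray]:
    """Temperature rise (degC) at radial distance ``r_nm`` from the centre.

    Flat at dT_s inside the particle, decaying as 1/r outside; continuous
    at the surface. With ``include_ambient`` the configured bulk rise is
    added on top.
    """
    r = np.asarray(r_nm, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance cannot be negative")
    dts = surface_temperature_rise(source)
    a = source.np_radius_nm
    with np.errstate(divide="ignore"):
        field = np.where(r <= a, dts, dts * a / np.where(r > 0, r, np.inf))
    if include_ambient:
        field = field + source.ambient_rise_c
    return float(field) if np.isscalar(r_nm) else field


def hot_zone_extent(source: NanoparticleHeatSource, threshold_c: float) -> Optional[float]:
    """Radius (nm) at which the rise first falls to ``threshold_c``.

    Closed-form inversion of the 1/r field: r* = a * dT_s / threshold.
    Returns the particle radius when the threshold equals the surface
    rise, and ``None`` (no hot zone) when the threshold exceeds it. A
    threshold of zero is never reached by a 1/r field and is rejected.
    """
    if threshold_c <= 0:
        raise ValueError("threshold must be positive (the 1/r field never reaches 0)")
    dts = surface_temperature_rise(source)
    if threshold_c > dts:
        return None
    return source.np_radius_nm * dts / threshold_c
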