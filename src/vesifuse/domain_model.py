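"""Spherical-cap model of coexisting membrane domains and their coalescence.

A lipid domain on a vesicle of radius R is modelled as an in-plane
spherical cap of half-angle alpha, related to its area by
A = 2 pi R^2 (1 - cos alpha) and bounded by a circle of length
L = 2 pi R sin alpha. The phase boundary carries a line tension gamma
(pN), so a configuration of domains has line energy gamma * sum(L).

Merging two caps of the same phase conserves area and shortens the total
boundary (L is subadditive in area for caps up to a hemisphere), so every
merge releases line energy. Experimentally, bulged domains repel each
other and sit kinetically trapped — they do not coalesce spontaneously;
here that is a flag on the configuration, and merges happen only when
commanded, mimicking domains dragged together with an optical trap. The
scheduler replays a user-specified order of pairwise merges; n domains
always collapse in exactly n - 1 events whatever the order.

Line tension drops as temperature approaches the miscibility temperature
T_c; with no measured curve to fit, a linear ramp vanishing at T_c is
used: gamma(T) = gamma_ref * max(0, (T_c - T) / (T_c - T_ref)).

Caps larger than a hemisphere are outside the model and rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple, Union

__all__ = [
    "Domain",
    "DomainConfiguration",
    "MergeEvent",
    "boundary_length",
    "line_energy",
    "line_tension_at",
    "merge_pair",
    "sequential_merge",
]

PHASES = ("Ld", "Lo")


@dataclass(frozen=True)
class Domain:
    """A spherical-cap membrane domain on a host vesicle."""

    phase: str
    area_um2: float
    host_vesicle_radius_um: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.host_vesicle_radius_um <= 0:
            raise ValueError("host vesicle radius must be positive")
        hemisphere = 2.0 * math.pi * self.host_vesicle_radius_um**2
        if not 0 <= self.area_um2 <= hemisphere * (1 + 1e-12):
            raise ValueError(
                f"cap area {self.area_um2} um^2 outside [0, hemisphere "
                f"{hemisphere:.6g} um^2]; larger caps are outside the model"
            )

    @property
    def cap_half_angle_rad(self) -> float:
        """alpha from A = 2 pi R^2 (1 - cos alpha); in [0, pi/2]."""
        r = self.host_vesicle_radius_um
        cos_a = 1.0 - self.area_um2 / (2.0 * math.pi * r**2)
        return math.acos(min(1.0, max(-1.0, cos_a)))

    @property
    def boundary_length_um(self) -> float:
        return boundary_length(self)


def boundary_length(d: Domain) -> float:
    """In-plane boundary circle length, L = 2 pi R sin alpha (um).

    Tends to the flat-disc circumference 2 sqrt(pi A) as A/R^2 -> 0.
    """
    return 2.0 * math.pi * d.host_vesicle_radius_um * math.sin(d.cap_half_angle_rad)


@dataclass
class DomainConfiguration:
    """A vesicle with a set of cap domains, line tension and temperature."""

    vesicle_radius_um: float
    domains: List[Domain]
    line_tension_pn: float = 1.0
    temperature_c: float = 21.0
    kinetically_trapped: bool = True  # no spontaneous merging; merges on command

    def __post_init__(self) -> None:
        if self.vesicle_radius_um <= 0:
            raise ValueError("vesicle radius must be positive")
        if self.line_tension_pn < 0:
            raise ValueError("line tension cannot be negative")
        total = sum(d.area_um2 for d in self.domains)
        sphere = 4.0 * math.pi * self.vesicle_radius_um**2
        if total > sphere * (1 + 1e-12):
            raise ValueError(
                f"total domain area {total:.6g} exceeds vesicle area {sphere:.6g} um^2"
            )
        for d in self.domains:
            if not math.isclose(d.host_vesicle_radius_um, self.vesicle_radius_um, rel_tol=1e-12):
                raise ValueError("all domains must live on the configuration's vesicle")

    @property
    def total_area_um2(self) -> float:
        return sum(d.area_um2 for d in self.domains)

    @property
    def total_boundary_um(self) -> float:
        return sum(boundary_length(d) for d in self.domains)


def line_energy(config: DomainConfiguration) -> float:
    """Total line energy gamma * sum of boundary lengths, in pN um (= 1e-18 J)."""
    return config.line_tension_pn * config.total_boundary_um


def line_tension_at(gamma_ref_pn: float, t_ref_c: float, t_c: float, t_crit_c: float) -> float:
    """Line tension at temperature ``t_c`` on a linear ramp to zero at T_c.

    gamma(T) = gamma_ref * max(0, (T_crit - T) / (T_crit - T_ref));
    equals gamma_ref at the reference temperature and vanishes at and
    above the miscibility temperature.
    """
    if gamma_ref_pn < 0:
        raise ValueError("reference line tension cannot be negative")
    if t_ref_c >= t_crit_c:
        raise ValueError("reference temperature must lie below the miscibility temperature")
    return gamma_ref_pn * max(0.0, (t_crit_c - t_c) / (t_crit_c - t_ref_c))


@dataclass(frozen=True)
class MergeEvent:
    """Audit record of one commanded pairwise domain merge."""

    index_a: int
    index_b: int
    pre_boundary_um: float
    post_boundary_um: float
    line_energy_change_pn_um: float

    def __post_init__(self) -> None:
        if self.line_energy_change_pn_um > 1e-9:
            raise ValueError("a merge cannot increase line energy")


def merge_pair(
    config: DomainConfiguration, i: int, j: int
) -> Tuple[DomainConfiguration, MergeEvent]:
    """Merge domains ``i`` and ``j`` into one cap of the summed area.

    The merged domain takes the place of ``min(i, j)``; the other slot is
    removed. Same-phase pairs only, and the merged cap must stay within a
    hemisphere. Area is conserved exactly; line energy cannot increase.
    """
    if i == j:
        raise ValueError("cannot merge a domain with itself")
    n = len(config.domains)
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"domain indices ({i}, {j}) out of range for {n} domains")
    a, b = config.domains[i], config.domains[j]
    if a.phase != b.phase:
        raise ValueError(
            f"cannot merge domains of different phases ({a.phase} vs {b.phase})"
        )
    merged_area = a.area_um2 + b.area_um2
    hemisphere = 2.0 * math.pi * config.vesicle_radius_um**2
    if merged_area > hemisphere * (1 + 1e-12):
        raise ValueError(
            f"merged cap area {merged_area:.6g} um^2 exceeds the hemisphere bound"
        )
    merged = Domain(a.phase, merged_area, config.vesicle_radius_um)

    lo, hi = sorted((i, j))
    new_domains = list(config.domains)
    new_domains[lo] = merged
    del new_domains[hi]

    pre = boundary_length(a) + boundary_length(b)
    post = boundary_length(merged)
    event = MergeEvent(
        index_a=i,
        index_b=j,
        pre_boundary_um=pre,
        post_boundary_um=post,
        line_energy_change_pn_um=config.line_tension_pn * (post - pre),
    )
    new_config = replace(config, domains=new_domains)
    return new_config, event


def sequential_merge(
    config: DomainConfiguration,
    order: Union[str, Sequence[Tuple[int, int]]] = "left-to-right",
) -> Tuple[DomainConfiguration, List[MergeEvent]]:
    """Apply pairwise merges until a single domain remains.

    ``order`` is either the string ``"left-to-right"`` (repeatedly merge
    the first two domains, emulating a trap dragging each next domain
    into the growing one) or an explicit list of ``(i, j)`` index pairs,
    interpreted against the shrinking domain list. Always produces
    exactly ``n - 1`` events for ``n`` starting domains, and the final
    area equals the summed initial areas regardless of order.
    """
    if len(config.domains) == 0:
        raise ValueError("configuration has no domains to merge")
    events: List[MergeEvent] = []
    current = config
    if isinstance(order, str):
        if order != "left-to-right":
            raise ValueError(f"unknown merge order {order!r}")
        while len(current.domains) > 1:
            current, ev = merge_pair(current, 0, 1)
            events.append(ev)
    else:
        for i, j in order:
            current, ev = merge_pair(current, i, j)
            events.append(ev)
        if len(current.domains) != 1:
            raise ValueError(
                f"explicit merge order left {len(current.domains)} domains; "
                "a complete order reduces to one"
            )
    return current, events
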