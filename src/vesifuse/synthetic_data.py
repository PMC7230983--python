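"""Seeded synthetic vesicle populations, fusion campaigns and domain sets.

The generators emulate the experimental material this package models:
electroformed GUV suspensions of about 5 um diameter (log-normal sizes),
DOPC/EggSM/Chol compositions at the canonical ratios, 0.75 M sucrose
inside against glucose/NaCl buffers outside, a fraction of vesicles with
excess membrane area, optional gold-nanoparticle labelling, and fusion
campaigns whose clean/disorderly outcomes follow the Bernoulli model of
``fusion_model.classify_fusion`` (clean probability 0.82 under
iso-osmotic conditions). Domain configurations partition a requested
liquid-disordered area fraction over n caps with a flat Dirichlet draw.

Everything is bit-reproducible under a fixed seed; one
``numpy.random.Generator`` drives each call and the seed is recorded in
the output so any table can be regenerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fusion_model
from .composition_phase import TernaryComposition
from .domain_model import Domain, DomainConfiguration
from .fusion_model import (
    DEFAULT_CLEAN_PROBABILITY,
    ISO_OSMOTIC_EXTERNAL,
    STANDARD_INTERNAL,
    SoluteMixture,
    classify_fusion,
    osmolarity,
)

__all__ = [
    "PopulationSpec",
    "FusionConditions",
    "generate_population",
    "simulate_fusion_campaign",
    "generate_domain_configuration",
]

VESICLE_COLUMNS = [
    "id",
    "diameter_um",
    "dopc",
    "eggsm",
    "chol",
    "internal_osm",
    "external_osm",
    "aunp",
    "excess_area",
    "rng_seed",
]


@dataclass
class PopulationSpec:
    """Recipe for a synthetic vesicle population.

    Diameters are log-normal around ``median_diameter_um`` with log-scale
    ``diameter_shape`` (0 gives a monodisperse population). Compositions
    are drawn from ``composition_choices``, a list of
    ``(TernaryComposition, probability)`` pairs.
    """

    n_vesicles: int = 50
    median_diameter_um: float = 5.0
    diameter_shape: float = 0.25
    composition_choices: Sequence[Tuple[TernaryComposition, float]] = field(
        default_factory=lambda: [(TernaryComposition(1, 1, 1), 1.0)]
    )
    internal_solution: SoluteMixture = field(default_factory=lambda: STANDARD_INTERNAL)
    external_solution: SoluteMixture = field(default_factory=lambda: ISO_OSMOTIC_EXTERNAL)
    excess_area_fraction: float = 0.2
    aunp_label_fraction: float = 0.5
    clean_fusion_probability: float = DEFAULT_CLEAN_PROBABILITY
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vesicles < 1:
            raise ValueError("population needs at least one vesicle")
        if self.median_diameter_um <= 0:
            raise ValueError("median diameter must be positive")
        if self.diameter_shape < 0:
            raise ValueError("diameter shape parameter cannot be negative")
        probs = [p for _, p in self.composition_choices]
        if not probs or not np.isclose(sum(probs), 1.0):
            raise ValueError("composition probabilities must sum to 1")
        for frac in (self.excess_area_fraction, self.aunp_label_fraction,
                     self.clean_fusion_probability):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions and probabilities must lie in [0, 1]")


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Sample a vesicle table from a population spec.

    Returns a DataFrame with one row per vesicle: id, diameter (um),
    composition parts, internal/external osmolarities (Osm/L), AuNP and
    excess-area flags, and the seed used.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_vesicles

    # log-normal with median = exp(mu): mu = log(median), sigma = shape
    diameters = spec.median_diameter_um * np.exp(
        rng.normal(0.0, 1.0, size=n) * spec.diameter_shape
    )

    comps = [c for c, _ in spec.composition_choices]
    probs = np.array([p for _, p in spec.composition_choices])
    comp_idx = rng.choice(len(comps), size=n, p=probs / probs.sum())

    aunp = rng.random(n) < spec.aunp_label_fraction
    excess = rng.random(n) < spec.excess_area_fraction

    rows = {
        "id": np.arange(n),
        "diameter_um": diameters,
        "dopc": [comps[k].dopc for k in comp_idx],
        "eggsm": [comps[k].eggsm for k in comp_idx],
        "chol": [comps[k].chol for k in comp_idx],
        "internal_osm": osmolarity(spec.internal_solution),
        "external_osm": osmolarity(spec.external_solution),
        "aunp": aunp,
        "excess_area": excess,
        "rng_seed": spec.rng_seed,
    }
    return pd.DataFrame(rows, columns=VESICLE_COLUMNS)


@dataclass(frozen=True)
class FusionConditions:
    """Laser and outcome parameters for a fusion campaign."""

    laser_power_mw: float = 200.0
    clean_probability: float = DEFAULT_CLEAN_PROBABILITY
    fusion_threshold_mw: float = fusion_model.DEFAULT_FUSION_THRESHOLD_MW


def simulate_fusion_campaign(
    population: pd.DataFrame,
    n_events: int,
    conditions: Optional[FusionConditions] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pair vesicles from a population table and classify each fusion.

    Vesicles are paired without replacement in shuffled order, so the
    population must contain at least ``2 * n_events`` rows. Each pair is
    run through the outcome classifier at the campaign's laser power and
    the pair's own osmotic ratio. The returned event table carries a
    volume audit (summed input vs output volume) per event.
    """
    if conditions is None:
        conditions = FusionConditions()
    if n_events < 1:
        raise ValueError("a campaign needs at least one event")
    if len(population) < 2 * n_events:
        raise ValueError(
            f"{n_events} events need {2 * n_events} vesicles; "
            f"population has {len(population)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(population))

    records = []
    for k in range(n_events):
        row_a = population.iloc[order[2 * k]]
        row_b = population.iloc[order[2 * k + 1]]
        r1 = row_a["diameter_um"] / 2.0
        r2 = row_b["diameter_um"] / 2.0
        ratio = row_a["internal_osm"] / row_a["external_osm"]
        event = classify_fusion(
            (r1, r2),
            laser_power_mw=conditions.laser_power_mw,
            osmotic_ratio=ratio,
            clean_probability=conditions.clean_probability,
            rng=rng,
            fusion_threshold_mw=conditions.fusion_threshold_mw,
        )
        if event is None:  # sub-threshold power: no fusion to record
            continue
        v_in = (4.0 / 3.0) * np.pi * (r1**3 + r2**3)
        records.append(
            {
                "event": k,
                "vesicle_a": int(row_a["id"]),
                "vesicle_b": int(row_b["id"]),
                "radius_a_um": r1,
                "radius_b_um": r2,
                "laser_power_mw": conditions.laser_power_mw,
                "osmotic_ratio": ratio,
                "outcome": event.outcome,
                "post_radius_um": event.post_fusion_vesicle.radius_um,
                "area_deficit": event.area_deficit,
                "volume_in_um3": v_in,
                "volume_out_um3": event.post_fusion_vesicle.volume_um3,
                "rng_seed": seed,
            }
        )
    return pd.DataFrame.from_records(records)


def generate_domain_configuration(
    n_domains: int,
    total_ld_area_fraction: float,
    vesicle_radius_um: float,
    seed: int = 0,
    line_tension_pn: float = 1.0,
    temperature_c: float = 21.0,
) -> DomainConfiguration:
    """Random Ld cap domains covering a set fraction of the vesicle.

    Areas are a flat Dirichlet partition of
    ``total_ld_area_fraction * 4 pi R^2``; the fraction may not exceed
    0.5 so every cap (and any merged cap) stays within a hemisphere.
    Reproducible under seed.
    """
    if n_domains < 1:
        raise ValueError("need at least one domain")
    if not 0.0 < total_ld_area_fraction <= 0.5:
        raise ValueError("total Ld area fraction must lie in (0, 0.5]")
    if vesicle_radius_um <= 0:
        raise ValueError("vesicle radius must be positive")
    rng = np.random.default_rng(seed)
    total_area = total_ld_area_fraction * 4.0 * np.pi * vesicle_radius_um**2
    weights = rng.dirichlet(np.ones(n_domains))
    # force exact conservation of the requested total against rounding
    areas = weights * total_area
    areas[-1] = total_area - areas[:-1].sum()
    domains = [Domain("Ld", float(a), vesicle_radius_um) for a in areas]
    return DomainConfiguration(
        vesicle_radius_um=vesicle_radius_um,
        domains=domains,
        line_tension_pn=line_tension_pn,
        temperature_c=temperature_c,
    )
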