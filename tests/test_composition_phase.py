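"""Ternary composition mixing, rationalisation and phase-region lookup."""

import json
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesifuse import (
    PhaseDiagram,
    PhaseRegion,
    TernaryComposition,
    default_phase_diagram,
    load_phase_diagram,
    mix_amounts,
    mix_fractions,
    phase_lookup,
    to_integer_ratio,
)
from vesifuse.composition_phase import (
    UNASSIGNED,
    barycentric_to_cartesian,
    cartesian_to_barycentric,
)

parts = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)
weights = st.floats(min_value=0.01, max_value=100.0, allow_nan=False)


def compositions():
    return st.tuples(parts, parts, parts).filter(lambda t: sum(t) > 1e-6).map(
        lambda t: TernaryComposition(*t)
    )


class TestTernaryComposition:
    def test_fractions_normalise(self):
        c = TernaryComposition(2, 2, 3)
        assert sum(c.fractions) == pytest.approx(1.0, abs=1e-12)
        assert c.fractions == pytest.approx((2 / 7, 2 / 7, 3 / 7))

    def test_ratio_parsing(self):
        assert TernaryComposition.from_ratio("1:1:3").amounts == (1, 1, 3)
        with pytest.raises(ValueError):
            TernaryComposition.from_ratio("1:1")

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            TernaryComposition(0, 0, 0)
        with pytest.raises(ValueError):
            TernaryComposition(-1, 1, 1)


class TestMixing:
    def test_bench_arithmetic_reproduces_two_two_three(self):
        mixed = mix_amounts(TernaryComposition(1, 1, 0), 1.0,
                            TernaryComposition(1, 1, 3), 1.0)
        assert to_integer_ratio(mixed) == (2, 2, 3)

    def test_mix_amounts_is_mass_balanced(self):
        c1, c2 = TernaryComposition(1, 2, 3), TernaryComposition(4, 0, 1)
        mixed = mix_amounts(c1, 2.0, c2, 3.0)
        assert mixed.amounts == (2 * 1 + 3 * 4, 2 * 2, 2 * 3 + 3 * 1)

    def test_weighted_pure_components(self):
        mixed = mix_amounts(TernaryComposition(1, 0, 0), 2.0,
                            TernaryComposition(0, 1, 0), 1.0)
        assert to_integer_ratio(mixed) == (2, 1, 0)

    def test_fraction_rule_on_canonical_pair(self):
        mixed = mix_fractions(TernaryComposition(1, 1, 0), 1.0,
                              TernaryComposition(1, 1, 3), 1.0)
        assert mixed.fractions == pytest.approx((0.35, 0.35, 0.30))
        assert to_integer_ratio(mixed) == (7, 7, 6)

    @given(compositions(), compositions(), weights, weights)
    @settings(derandomize=True, max_examples=50)
    def test_both_rules_commute(self, c1, c2, w1, w2):
        a = mix_amounts(c1, w1, c2, w2)
        b = mix_amounts(c2, w2, c1, w1)
        assert a.fractions == pytest.approx(b.fractions, abs=1e-12)
        fa = mix_fractions(c1, w1, c2, w2)
        fb = mix_fractions(c2, w2, c1, w1)
        assert fa.fractions == pytest.approx(fb.fractions, abs=1e-12)

    @given(compositions(), compositions(), weights, st.floats(0.5, 5.0))
    @settings(derandomize=True, max_examples=50)
    def test_mixing_is_scale_invariant_in_weights(self, c1, c2, w, scale):
        a = mix_amounts(c1, w, c2, 2 * w)
        b = mix_amounts(c1, scale * w, c2, scale * 2 * w)
        assert a.fractions == pytest.approx(b.fractions, abs=1e-12)

    @given(compositions(), weights, weights)
    @settings(derandomize=True, max_examples=50)
    def test_mixing_identical_compositions_is_idempotent(self, c, w1, w2):
        assert mix_amounts(c, w1, c, w2).fractions == pytest.approx(c.fractions, abs=1e-12)
        assert mix_fractions(c, w1, c, w2).fractions == pytest.approx(c.fractions, abs=1e-12)

    def test_fraction_rule_continuity_in_vanishing_area(self):
        c1, c2 = TernaryComposition(1, 1, 0), TernaryComposition(1, 1, 3)
        mixed = mix_fractions(c1, 1.0, c2, 1e-12)
        assert mixed.fractions == pytest.approx(c1.fractions, abs=1e-9)

    def test_invalid_weights_rejected(self):
        c = TernaryComposition(1, 1, 1)
        with pytest.raises(ValueError):
            mix_amounts(c, 0.0, c, 1.0)
        with pytest.raises(ValueError):
            mix_fractions(c, -1.0, c, 1.0)


class TestIntegerRatio:
    @pytest.mark.parametrize(
        "amounts, expected",
        [
            ((2 / 7, 2 / 7, 3 / 7), (2, 2, 3)),
            ((0.5, 0.5, 0.0), (1, 1, 0)),
            ((0.35, 0.35, 0.30), (7, 7, 6)),
            ((1, 1, 1), (1, 1, 1)),
        ],
    )
    def test_rationalisation(self, amounts, expected):
        assert to_integer_ratio(TernaryComposition(*amounts)) == expected


class TestSimplexEmbedding:
    @given(compositions())
    @settings(derandomize=True, max_examples=100)
    def test_barycentric_cartesian_round_trip(self, c):
        x, y = barycentric_to_cartesian(c.fractions)
        back = cartesian_to_barycentric(x, y)
        assert back == pytest.approx(c.fractions, abs=1e-12)

    def test_vertices_map_to_triangle_corners(self):
        assert barycentric_to_cartesian((1, 0, 0)) == pytest.approx((0.0, 0.0))
        assert barycentric_to_cartesian((0, 1, 0)) == pytest.approx((1.0, 0.0))
        assert barycentric_to_cartesian((0, 0, 1)) == pytest.approx(
            (0.5, math.sqrt(3) / 2)
        )


class TestPhaseLookup:
    @pytest.mark.parametrize(
        "ratio, phase",
        [
            ("1:1:0", "gel_liquid_coexistence"),
            ("1:1:3", "uniform_liquid"),
            ("2:2:3", "Lo_Ld_coexistence"),
            ("1:1:1", "Lo_Ld_coexistence"),
        ],
    )
    def test_canonical_compositions_land_in_observed_phases(self, ratio, phase):
        diagram = default_phase_diagram()
        c = TernaryComposition.from_ratio(ratio)
        assert phase_lookup(c, diagram) == phase

    def test_boundary_assigned_to_first_listed_region(self):
        diagram = default_phase_diagram()
        # 15 mol% Chol sits on the gel/Lo-Ld boundary; gel is listed first
        c = TernaryComposition(0.425, 0.425, 0.15)
        assert phase_lookup(c, diagram) == "gel_liquid_coexistence"

    def test_point_outside_all_regions_is_flagged_unassigned(self):
        partial = PhaseDiagram(
            regions=(
                PhaseRegion(
                    "gel_liquid_coexistence",
                    ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.85, 0.15), (0.85, 0.0, 0.15)),
                ),
            )
        )
        chol_rich = TernaryComposition(1, 1, 3)
        assert phase_lookup(chol_rich, partial) == UNASSIGNED

    def test_overlapping_regions_rejected(self):
        tri = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
        with pytest.raises(ValueError, match="overlap"):
            PhaseDiagram(regions=(
                PhaseRegion("gel_liquid_coexistence", tri),
                PhaseRegion("uniform_liquid", tri),
            ))

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            PhaseRegion("other", ((1, 0, 0), (0, 1, 0), (0.5, 0.5, 0)))

    def test_diagram_file_round_trip(self, tmp_path):
        diagram = default_phase_diagram()
        payload = {
            "provenance": diagram.provenance,
            "regions": [
                {"label": r.label, "vertices": [list(v) for v in r.vertices]}
                for r in diagram.regions
            ],
        }
        path = tmp_path / "diagram.json"
        path.write_text(json.dumps(payload))
        reloaded = load_phase_diagram(str(path))
        assert [r.label for r in reloaded.regions] == [r.label for r in diagram.regions]
        c = TernaryComposition(2, 2, 3)
        assert phase_lookup(c, reloaded) == phase_lookup(c, diagram)

    def test_shipped_diagram_declares_itself_schematic(self):
        assert "schematic" in default_phase_diagram().provenance.lower()
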