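"""Diagram classification, Venn/Euler arrangements, scaling rules and
label placement, cross-checked against the Monte-Carlo region oracle."""

import math

import pytest

from conftest import all_patterns, card_from_pattern
from vennforge.errors import UnsupportedScalingError, WrongClassError
from vennforge.geometry import Circle, region_areas_and_centroids
from vennforge.layout import (
    SCALABLE_EULER,
    DiagramClass,
    attach_labels,
    build_layout,
    check_three_set_scaling,
    classify_diagram,
    layout_euler,
    layout_scaled_two_set,
    layout_venn,
    point_region,
)
from vennforge.sets import all_region_keys, parse_region_counts
from vennforge.style import StyleConfig

SAMPLES = 300_000
DEGENERATE = 1e-3  # canvas-area fraction treated as an empty region


def oracle(layout, seed=11, samples=SAMPLES):
    return region_areas_and_centroids(layout.shapes, n_samples=samples, seed=seed)


class TestClassifier:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"A": 1, "B": 1, "A&B": 1}, DiagramClass.VENN_2),
            ({"A": 5, "A&B": 3}, DiagramClass.EULER_2_INCLUSION),
            ({"A": 5, "B": 3}, DiagramClass.EULER_2_DISJOINT),
            ({"A&C": 4, "B&C": 5}, DiagramClass.FALLBACK_VENN_3),  # C = A ⊎ B
            ({"A&B&C": 2, "B&C": 3, "C": 4}, DiagramClass.EULER_3_CHAIN),
            ({"A": 1, "B": 1, "C": 1}, DiagramClass.EULER_3_DISJOINT),
        ],
    )
    def test_known_cases(self, counts, expected):
        assert classify_diagram(parse_region_counts(counts)) is expected

    def test_euler_off_forces_venn(self):
        card = parse_region_counts({"A": 5, "A&B": 3})
        assert classify_diagram(card, euler_enabled=False) is DiagramClass.VENN_2

    @pytest.mark.parametrize("n", [2, 3])
    def test_totality_over_all_zero_patterns(self, n):
        include_empty = n == 3
        seen = 0
        for pattern in all_patterns(n, include_empty=include_empty):
            card = card_from_pattern(n, pattern)
            cls = classify_diagram(card, euler_enabled=True)
            assert isinstance(cls, DiagramClass)
            off = classify_diagram(card, euler_enabled=False)
            assert off is DiagramClass[f"VENN_{n}"]
            seen += 1
        assert seen == (7 if n == 2 else 128)

    def test_four_sets_never_euler(self):
        card = card_from_pattern(4, [(0, 1, 2, 3), (3,)])
        assert classify_diagram(card, euler_enabled=True) is DiagramClass.VENN_4


class TestVennLayouts:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_all_regions_nondegenerate(self, n):
        card = card_from_pattern(n, all_region_keys(n))
        layout = layout_venn(card)
        areas = oracle(layout)
        positive = [k for k, (a, _) in areas.items() if a > DEGENERATE]
        assert len(positive) == 2**n - 1

    def test_single_set_centered(self):
        card = parse_region_counts({"A": 3})
        layout = layout_venn(card)
        assert layout.shapes[0].center == pytest.approx((0.5, 0.5))

    def test_zero_regions_still_labeled(self):
        card = parse_region_counts({"A": 5, "B": 0, "A&B": 0})
        layout = build_layout(card, StyleConfig(euler=False),
                              n_samples=SAMPLES, seed=11)
        assert sorted(layout.region_labels.values()) == ["0", "0", "5"]


class TestScaledTwoSet:
    def test_symmetric_counts_give_equal_radii(self):
        card = parse_region_counts({"A": 35, "B": 35, "A&B": 30})
        layout = layout_scaled_two_set(card)
        r0, r1 = (s.radius for s in layout.shapes)
        assert r0 == pytest.approx(r1)
        assert layout.shapes[0].center[1] == layout.shapes[1].center[1]

    def test_equal_sets_concentric(self):
        card = parse_region_counts({"A": 0, "B": 0, "A&B": 12})
        layout = layout_scaled_two_set(card)
        c0, c1 = layout.shapes
        assert c0.center == pytest.approx(c1.center)
        assert c0.radius == pytest.approx(c1.radius)

    @pytest.mark.parametrize(
        "counts",
        [
            {"A": 100, "B": 70, "A&B": 30},
            {"A": 20, "B": 80, "A&B": 15},
            {"A": 55, "B": 25, "A&B": 25},
        ],
    )
    def test_region_areas_proportional_to_counts(self, counts):
        card = parse_region_counts(counts)
        layout = layout_scaled_two_set(card)
        areas = oracle(layout, samples=1_000_000)
        total_area = sum(a for a, _ in areas.values())
        total_count = card.union_total()
        for key in all_region_keys(2):
            if card[key] == 0:
                continue
            got = areas[key][0] / total_area
            want = card[key] / total_count
            assert abs(got - want) / want < 0.02

    def test_disjoint_tangency_keeps_visible_gap(self):
        card = parse_region_counts({"A": 50, "B": 30, "A&B": 0})
        layout = layout_scaled_two_set(card)
        c0, c1 = layout.shapes
        d = math.hypot(c1.center[0] - c0.center[0], c1.center[1] - c0.center[1])
        assert d > c0.radius + c1.radius  # gap, not touching

    def test_inclusion_tangency_nests_inner_circle(self):
        card = parse_region_counts({"A": 50, "B": 0, "A&B": 30})
        layout = layout_scaled_two_set(card)
        c0, c1 = layout.shapes  # B nested in A
        d = math.hypot(c1.center[0] - c0.center[0], c1.center[1] - c0.center[1])
        assert d + c1.radius < c0.radius  # strictly inside


class TestThreeSetScalingGuard:
    def test_full_venn3_scaled_refused(self):
        card = card_from_pattern(3, all_region_keys(3))
        with pytest.raises(UnsupportedScalingError):
            check_three_set_scaling(card, scaled=True)

    def test_unscaled_passes(self):
        card = card_from_pattern(3, all_region_keys(3))
        check_three_set_scaling(card, scaled=False)

    def test_two_set_not_this_guards_concern(self):
        card = parse_region_counts({"A": 100, "B": 70, "A&B": 30})
        check_three_set_scaling(card, scaled=True)

    def test_scalable_euler_case_passes_when_euler_on(self):
        card = parse_region_counts({"A&B&C": 2, "B&C": 3, "C": 4})
        check_three_set_scaling(card, scaled=True, euler_enabled=True)
        with pytest.raises(UnsupportedScalingError):
            check_three_set_scaling(card, scaled=True, euler_enabled=False)


class TestEulerLayouts:
    def euler_cases(self):
        # one representative counts table per Euler class
        return [
            ({"A": 5, "A&B": 3}, DiagramClass.EULER_2_INCLUSION),
            ({"A&B": 3}, DiagramClass.EULER_2_INCLUSION),
            ({"A": 5, "B": 3}, DiagramClass.EULER_2_DISJOINT),
            ({"A": 2, "B": 3, "C": 4}, DiagramClass.EULER_3_DISJOINT),
            ({"A&B&C": 2, "B&C": 3, "C": 4}, DiagramClass.EULER_3_CHAIN),
            ({"A&B": 2, "B": 3, "C": 4}, DiagramClass.EULER_3_NESTED_PAIR_DISJOINT),
            ({"A&C": 2, "B&C": 3, "C": 4}, DiagramClass.EULER_3_TWO_DISJOINT_IN_ONE),
            ({"A&C": 2, "B&C": 3, "A&B&C": 1, "C": 4},
             DiagramClass.EULER_3_TWO_OVERLAP_IN_ONE),
            ({"A": 2, "B": 3, "A&B": 1, "C": 4},
             DiagramClass.EULER_3_OVERLAP_PAIR_DISJOINT),
            ({"A&B&C": 2, "B&C": 3, "B": 4, "C": 5}, DiagramClass.EULER_3_IN_LENS),
            ({"A&B": 2, "B": 3, "B&C": 1, "C": 4}, DiagramClass.EULER_3_IN_ONE_OF_PAIR),
            ({"A&B": 2, "A&B&C": 1, "B": 3, "B&C": 1, "C": 4},
             DiagramClass.EULER_3_IN_ONE_CROSS),
            ({"A&B": 1, "A&C": 1, "A&B&C": 1, "B": 2, "C": 2, "B&C": 1},
             DiagramClass.EULER_3_COVERED_BY_UNION),
            ({"A": 1, "B": 1, "C": 1, "A&B": 1, "A&C": 1, "B&C": 1},
             DiagramClass.EULER_3_RING),
        ]

    def test_every_euler_class_realizes_its_pattern(self):
        for counts, expected in self.euler_cases():
            card = parse_region_counts(counts)
            cls = classify_diagram(card)
            assert cls is expected, counts
            layout = layout_euler(card, cls)
            areas = oracle(layout)
            pattern = card.nonzero_pattern()
            for key, (area, _) in areas.items():
                if key in pattern:
                    assert area > DEGENERATE, (counts, key)
                else:
                    assert area <= DEGENERATE, (counts, key)

    def test_scaled_disjoint_two_set_radius_ratio(self):
        card = parse_region_counts({"A": 100, "B": 25})
        layout = layout_euler(card, DiagramClass.EULER_2_DISJOINT, scaled=True)
        r0, r1 = (s.radius for s in layout.shapes)
        assert r0 / r1 == pytest.approx(2.0, rel=1e-9)
        c0, c1 = layout.shapes
        d = math.hypot(c1.center[0] - c0.center[0], c1.center[1] - c0.center[1])
        assert d > r0 + r1

    def test_scaled_chain_is_nested_with_exact_areas(self):
        card = parse_region_counts({"A&B&C": 5, "B&C": 11, "C": 20})
        layout = layout_euler(card, DiagramClass.EULER_3_CHAIN, scaled=True)
        assert layout.scaled
        rA, rB, rC = (s.radius for s in layout.shapes)
        # drawn areas proportional to totals 5, 16, 36
        assert (rB / rA) ** 2 == pytest.approx(16 / 5, rel=1e-9)
        assert (rC / rA) ** 2 == pytest.approx(36 / 5, rel=1e-9)
        areas = oracle(layout)
        assert areas[(0, 1, 2)][0] > DEGENERATE
        assert areas[(0, 1)][0] <= DEGENERATE

    def test_unscalable_case_warns_and_uses_template(self, caplog):
        card = parse_region_counts({"A": 2, "B": 3, "A&B": 1, "C": 4})
        cls = classify_diagram(card)
        assert cls not in SCALABLE_EULER
        with caplog.at_level("WARNING", logger="vennforge"):
            layout = layout_euler(card, cls, scaled=True)
        assert not layout.scaled
        assert any("template proportions" in r.message for r in caplog.records)

    def test_wrong_class_rejected(self):
        card = parse_region_counts({"A": 5, "B": 3})
        with pytest.raises(WrongClassError):
            layout_euler(card, DiagramClass.VENN_2)
        with pytest.raises(WrongClassError):
            layout_euler(card, DiagramClass.EULER_2_INCLUSION)

    def test_fallback_always_renders(self):
        # the circle-unrealizable pattern still produces a drawable layout
        card = parse_region_counts({"A&C": 4, "B&C": 5})
        layout = build_layout(card, n_samples=SAMPLES, seed=11)
        assert layout.diagram_class is DiagramClass.FALLBACK_VENN_3
        assert len(layout.shapes) == 3
        assert layout.region_labels  # labeled, no dead-end


class TestLabels:
    def anchors_inside(self, counts, style=None):
        card = parse_region_counts(counts)
        layout = build_layout(card, style, n_samples=SAMPLES, seed=11)
        for key, count in card.counts.items():
            if count == 0:
                continue
            x, y = layout.region_anchors[key]
            assert point_region(layout.shapes, x, y) == key, (counts, key)

    @pytest.mark.parametrize(
        "counts",
        [
            {"A": 3},
            {"A": 2, "B": 1, "A&B": 1},
            {"A": 5, "A&B": 3},
            {"A&B&C": 2, "B&C": 3, "C": 4},
            {"A": 1, "B": 1, "C": 1, "A&B": 1, "A&C": 1, "B&C": 1, "A&B&C": 1},
        ],
    )
    def test_positive_regions_have_interior_anchors(self, counts):
        self.anchors_inside(counts)

    def test_small_lens_gets_leader_line(self):
        card = parse_region_counts({"A": 1000, "B": 800, "A&B": 4})
        layout = build_layout(card, StyleConfig(scaled=True),
                              n_samples=SAMPLES, seed=11)
        assert len(layout.leader_lines) == 1
        inner, outer = layout.leader_lines[0]
        # the line starts inside the lens and ends at the external label
        assert point_region(layout.shapes, *inner) == (0, 1)
        assert outer == layout.region_anchors[(0, 1)]
        top = max(s.center[1] + s.radius for s in layout.shapes)
        assert outer[1] > top

    def test_large_lens_needs_no_leader_line(self, venn2_counts):
        layout = build_layout(venn2_counts, StyleConfig(scaled=True),
                              n_samples=SAMPLES, seed=11)
        assert layout.leader_lines == []

    def test_text_caption_mode_attaches_to_exclusive_label(self):
        style = StyleConfig(caption_mode="text", caption_distance=0.04)
        card = parse_region_counts({"A": 2, "B": 1, "A&B": 1})
        layout = build_layout(card, style, n_samples=SAMPLES, seed=11)
        for i, label in enumerate(layout.set_labels):
            cx, cy, _ = layout.caption_anchors[label]
            rx, ry = layout.region_anchors[(i,)]
            assert math.hypot(cx - rx, cy - ry) <= 0.04 + 1e-9

    def test_explicit_caption_positions(self):
        style = StyleConfig(
            caption_mode="explicit",
            caption_positions={"A": (0.1, 0.9), "B": (0.9, 0.9)},
            caption_justification="left",
        )
        card = parse_region_counts({"A": 2, "B": 1, "A&B": 1})
        layout = build_layout(card, style, n_samples=SAMPLES, seed=11)
        assert layout.caption_anchors["A"] == (0.1, 0.9, "left")


class TestTransformedLayouts:
    def test_rotation_preserves_labels_and_areas(self, venn2_counts):
        base = build_layout(venn2_counts, StyleConfig(scaled=True),
                            n_samples=SAMPLES, seed=11)
        rotated = base.transformed(90.0, False)
        assert rotated.region_labels == base.region_labels
        a0 = oracle(base, seed=21)
        a1 = oracle(rotated, seed=22)
        for key in a0:
            assert a1[key][0] == pytest.approx(a0[key][0], abs=5e-3)

    def test_inversion_mirrors_anchor_x(self, venn2_counts):
        base = build_layout(venn2_counts, n_samples=SAMPLES, seed=11)
        mirrored = base.transformed(0.0, True)
        for key, (x, y) in base.region_anchors.items():
            mx, my = mirrored.region_anchors[key]
            assert mx == pytest.approx(1.0 - x, abs=1e-12)
            assert my == pytest.approx(y, abs=1e-12)
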