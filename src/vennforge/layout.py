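"""Diagram classification and shape placement.

A validated region-cardinality table is classified into a Venn or an Euler
case; the case determines an arrangement of circles/ellipses on the unit
canvas.  Euler recognition works by matching the zero/nonzero pattern of
the region counts, up to set permutation, against a catalogue of
circle-realizable configurations; patterns with no circle/ellipse
realization (e.g. two disjoint sets exactly comprising the third) fall
back to a standard Venn diagram.

Area-proportional scaling is available for two-set diagrams and for the
Euler cases whose geometry is fully determined by the set totals plus
inclusion/disjointness alone.  Scaling a three-set Venn diagram is refused:
with circles, the three pairwise distances already fix the drawing, so the
triple-intersection count could not alter it — the drawing would silently
misrepresent it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import EmptyDiagramError, UnsupportedScalingError, WrongClassError
from .geometry import (
    DEFAULT_SAMPLES,
    DEFAULT_SEED,
    Circle,
    Ellipse,
    Shape,
    radius_from_area,
    region_areas_and_centroids,
    solve_distance,
    transform_point,
    transform_shape,
)
from .sets import RegionCardinalities, RegionKey, all_region_keys
from .style import StyleConfig

logger = logging.getLogger("vennforge")

#: radius used to park an empty set in an Euler layout; its area stays below
#: the 1e-3 canvas-fraction threshold treated as degenerate
TINY_RADIUS = 0.015


class DiagramClass(Enum):
    VENN_1 = "VENN_1"
    VENN_2 = "VENN_2"
    VENN_3 = "VENN_3"
    VENN_4 = "VENN_4"
    EULER_2_INCLUSION = "EULER_2_INCLUSION"
    EULER_2_DISJOINT = "EULER_2_DISJOINT"
    EULER_3_DISJOINT = "EULER_3_DISJOINT"
    EULER_3_CHAIN = "EULER_3_CHAIN"
    EULER_3_NESTED_PAIR_DISJOINT = "EULER_3_NESTED_PAIR_DISJOINT"
    EULER_3_TWO_DISJOINT_IN_ONE = "EULER_3_TWO_DISJOINT_IN_ONE"
    EULER_3_TWO_OVERLAP_IN_ONE = "EULER_3_TWO_OVERLAP_IN_ONE"
    EULER_3_OVERLAP_PAIR_DISJOINT = "EULER_3_OVERLAP_PAIR_DISJOINT"
    EULER_3_IN_LENS = "EULER_3_IN_LENS"
    EULER_3_IN_ONE_OF_PAIR = "EULER_3_IN_ONE_OF_PAIR"
    EULER_3_IN_ONE_CROSS = "EULER_3_IN_ONE_CROSS"
    EULER_3_RING = "EULER_3_RING"
    EULER_3_COVERED_BY_UNION = "EULER_3_COVERED_BY_UNION"
    FALLBACK_VENN_3 = "FALLBACK_VENN_3"

    @property
    def is_euler(self) -> bool:
        return self.value.startswith("EULER")


#: Euler classes whose scaled geometry is fully determined by set totals and
#: inclusion/disjointness relations (no partial two-way overlap anywhere)
SCALABLE_EULER = frozenset({
    DiagramClass.EULER_2_INCLUSION,
    DiagramClass.EULER_2_DISJOINT,
    DiagramClass.EULER_3_DISJOINT,
    DiagramClass.EULER_3_CHAIN,
    DiagramClass.EULER_3_NESTED_PAIR_DISJOINT,
    DiagramClass.EULER_3_TWO_DISJOINT_IN_ONE,
})


@dataclass
class Layout:
    """Positioned shapes plus label anchors on the [0,1]x[0,1] canvas."""

    shapes: list[Shape]
    diagram_class: DiagramClass
    set_labels: tuple[str, ...]
    scaled: bool = False
    region_anchors: dict[RegionKey, tuple[float, float]] = field(default_factory=dict)
    region_labels: dict[RegionKey, str] = field(default_factory=dict)
    caption_anchors: dict[str, tuple[float, float, str]] = field(default_factory=dict)
    leader_lines: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )

    @property
    def n(self) -> int:
        return len(self.shapes)

    def transformed(self, rotation_deg: float, invert: bool) -> "Layout":
        """Rigidly rotate (CCW about the canvas center) and/or mirror the
        whole layout; label texts are untouched."""
        if rotation_deg == 0 and not invert:
            return self

        def tp(p):
            return transform_point(p, rotation_deg, invert)

        return replace(
            self,
            shapes=[transform_shape(s, rotation_deg, invert) for s in self.shapes],
            region_anchors={k: tp(p) for k, p in self.region_anchors.items()},
            caption_anchors={
                k: (*tp((x, y)), ha) for k, (x, y, ha) in self.caption_anchors.items()
            },
            leader_lines=[(tp(a), tp(b)) for a, b in self.leader_lines],
        )


def point_region(shapes: Sequence[Shape], x: float, y: float) -> RegionKey:
    """The region key of the point (x, y): which shapes contain it."""
    ax = np.asarray([x])
    ay = np.asarray([y])
    return tuple(i for i, s in enumerate(shapes) if bool(s.contains(ax, ay)[0]))


# ---------------------------------------------------------------------------
# Euler pattern catalogue
# ---------------------------------------------------------------------------

def _fs(*keys: RegionKey) -> frozenset:
    return frozenset(keys)


# configuration name -> accepted zero/nonzero patterns in role space
# (role 0 = "a", role 1 = "b", role 2 = "c"); exact match required
_CONFIGS_3 = {
    "disjoint3": [_fs((0,), (1,), (2,))],
    # a ⊆ b ⊆ c, with coincident circles realizing the equalities
    "chain": [
        _fs((0, 1, 2), (1, 2), (2,)),
        _fs((0, 1, 2), (2,)),
        _fs((0, 1, 2), (1, 2)),
        _fs((0, 1, 2),),
    ],
    # a ⊆ b, c disjoint from both
    "nested_pair_disjoint": [
        _fs((0, 1), (1,), (2,)),
        _fs((0, 1), (2,)),
    ],
    # a, b strictly inside c, mutually disjoint; c keeps discrete elements
    "two_disjoint_in_one": [_fs((0, 2), (1, 2), (2,))],
    # a, b inside c and overlapping each other
    "two_overlap_in_one": [_fs((0, 2), (1, 2), (0, 1, 2), (2,))],
    # a and b overlap, c disjoint from both
    "overlap_pair_disjoint": [_fs((0,), (1,), (0, 1), (2,))],
    # a inside the lens of b and c
    "in_lens": [_fs((0, 1, 2), (1, 2), (1,), (2,))],
    # a inside b, clear of c; b and c overlap
    "in_one_of_pair": [_fs((0, 1), (1,), (1, 2), (2,))],
    # a inside b, crossing into the b∩c lens
    "in_one_cross": [_fs((0, 1), (0, 1, 2), (1,), (1, 2), (2,))],
    # a covered by b ∪ c, straddling the lens (no discrete elements in a)
    "covered_by_union": [
        _fs((0, 1), (0, 2), (0, 1, 2), (1,), (2,), (1, 2))
    ],
    # pairwise overlaps with an empty triple intersection
    "ring": [_fs((0,), (1,), (2,), (0, 1), (0, 2), (1, 2))],
}

_CONFIGS_2 = {
    "disjoint2": [_fs((0,), (1,))],
    "nested2": [_fs((0, 1), (1,))],   # a strictly inside b
    "equal2": [_fs((0, 1),)],
    "overlap2": [_fs((0,), (1,), (0, 1))],
}

_CLASS_OF_CONFIG_3 = {
    "disjoint3": DiagramClass.EULER_3_DISJOINT,
    "chain": DiagramClass.EULER_3_CHAIN,
    "nested_pair_disjoint": DiagramClass.EULER_3_NESTED_PAIR_DISJOINT,
    "two_disjoint_in_one": DiagramClass.EULER_3_TWO_DISJOINT_IN_ONE,
    "two_overlap_in_one": DiagramClass.EULER_3_TWO_OVERLAP_IN_ONE,
    "overlap_pair_disjoint": DiagramClass.EULER_3_OVERLAP_PAIR_DISJOINT,
    "in_lens": DiagramClass.EULER_3_IN_LENS,
    "in_one_of_pair": DiagramClass.EULER_3_IN_ONE_OF_PAIR,
    "in_one_cross": DiagramClass.EULER_3_IN_ONE_CROSS,
    "covered_by_union": DiagramClass.EULER_3_COVERED_BY_UNION,
    "ring": DiagramClass.EULER_3_RING,
}

# embedded two-set relations inside a three-set diagram (third set empty)
_CLASS_OF_CONFIG_2_IN_3 = {
    "disjoint2": DiagramClass.EULER_3_DISJOINT,
    "nested2": DiagramClass.EULER_3_NESTED_PAIR_DISJOINT,
    "equal2": DiagramClass.EULER_3_NESTED_PAIR_DISJOINT,
    "overlap2": DiagramClass.EULER_3_OVERLAP_PAIR_DISJOINT,
}


@dataclass(frozen=True)
class EulerPlan:
    """Result of pattern matching: which configuration realizes the
    nonzero pattern, and which original set plays which role."""

    diagram_class: DiagramClass
    config: str
    roles: tuple[int, ...]         # roles[k] = original index playing role k
    empty_sets: tuple[int, ...]    # original indices with zero total
    role_pattern: frozenset        # matched pattern in role space


def _remap_pattern(pattern: frozenset, perm: Sequence[int]) -> frozenset:
    """Re-key a pattern so that original index perm[k] becomes role k."""
    pos = {orig: role for role, orig in enumerate(perm)}
    return frozenset(tuple(sorted(pos[i] for i in key)) for key in pattern)


def _euler_plan(card: RegionCardinalities) -> EulerPlan | None:
    """Match the nonzero pattern against the realizable Euler catalogue.

    Returns None when no configuration matches (Venn fallback)."""
    n = card.n
    pattern = card.nonzero_pattern()
    nonempty = [i for i in range(n) if card.set_total(i) > 0]
    empty = tuple(i for i in range(n) if i not in nonempty)
    m = len(nonempty)
    if m == 0:
        return None
    if m == 1:
        cls = (DiagramClass.EULER_2_DISJOINT if n == 2
               else DiagramClass.EULER_3_DISJOINT)
        return EulerPlan(cls, "single", (nonempty[0],), empty, _fs((0,)))
    configs = _CONFIGS_2 if m == 2 else _CONFIGS_3
    for perm in itertools.permutations(nonempty):
        role_pattern = _remap_pattern(pattern, perm)
        for config, accepted in configs.items():
            if role_pattern in accepted:
                if n == 2:
                    cls = {
                        "disjoint2": DiagramClass.EULER_2_DISJOINT,
                        "nested2": DiagramClass.EULER_2_INCLUSION,
                        "equal2": DiagramClass.EULER_2_INCLUSION,
                    }.get(config)
                    if cls is None:  # overlap2: a full two-set Venn
                        return None
                elif m == 2:
                    cls = _CLASS_OF_CONFIG_2_IN_3[config]
                else:
                    cls = _CLASS_OF_CONFIG_3[config]
                return EulerPlan(cls, config, tuple(perm), empty, role_pattern)
    return None


def classify_diagram(card: RegionCardinalities, euler_enabled: bool = True) -> DiagramClass:
    """Select the diagram case for a cardinality table.

    With Euler recognition off, with four sets, or with no empty region,
    the standard n-set Venn diagram is chosen.  Otherwise the zero pattern
    picks an Euler case; unrealizable patterns yield the Venn fallback.
    """
    n = card.n
    venn = DiagramClass[f"VENN_{n}"]
    if not euler_enabled or n in (1, 4):
        return venn
    pattern = card.nonzero_pattern()
    if len(pattern) == len(all_region_keys(n)) or not pattern:
        return venn
    plan = _euler_plan(card)
    if plan is None:
        return DiagramClass.FALLBACK_VENN_3 if n == 3 else venn
    return plan.diagram_class


# ---------------------------------------------------------------------------
# Canvas fitting
# ---------------------------------------------------------------------------

def fit_to_canvas(shapes: Sequence[Shape], margin: float = 0.05) -> list[Shape]:
    """Uniformly rescale and translate shapes so their joint bounding box
    fills the canvas square [margin, 1-margin] (aspect preserved)."""
    bounds = np.array([s.bounds() for s in shapes])
    x0, y0 = bounds[:, 0].min(), bounds[:, 1].min()
    x1, y1 = bounds[:, 2].max(), bounds[:, 3].max()
    w, h = x1 - x0, y1 - y0
    span = max(w, h)
    if span <= 0:
        span = 1.0
    s = (1.0 - 2.0 * margin) / span
    cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)

    def move(shape: Shape) -> Shape:
        nx = 0.5 + s * (shape.center[0] - cx)
        ny = 0.5 + s * (shape.center[1] - cy)
        if isinstance(shape, Circle):
            return Circle((nx, ny), shape.radius * s)
        return Ellipse((nx, ny), shape.semi_major * s, shape.semi_minor * s, shape.angle)

    return [move(s_) for s_ in shapes]


def _tiny_circles(k: int) -> list[Circle]:
    """Parked circles standing in for empty sets along the bottom margin."""
    return [Circle((0.08 + 0.08 * j, 0.08), TINY_RADIUS) for j in range(k)]


# ---------------------------------------------------------------------------
# Canonical (unscaled) Venn arrangements
# ---------------------------------------------------------------------------

VENN_2_RADIUS = 0.30
VENN_2_CENTERS = ((0.38, 0.5), (0.62, 0.5))
VENN_3_RADIUS = 0.28
VENN_3_SIDE = 0.25  # equilateral triangle of centers
# classic four-ellipse arrangement; constants tuned so all 15 regions are
# non-degenerate (checked by the sampling oracle in the test suite)
VENN_4_ELLIPSES = (
    ((0.350, 0.400), 0.36, 0.22, 140.0),
    ((0.450, 0.500), 0.36, 0.22, 140.0),
    ((0.550, 0.500), 0.36, 0.22, 40.0),
    ((0.650, 0.400), 0.36, 0.22, 40.0),
)


def layout_venn(card: RegionCardinalities,
                diagram_class: DiagramClass | None = None) -> Layout:
    """Canonical unscaled Venn arrangement for 1-4 sets.

    All 2**n - 1 regions are non-degenerate by construction; regions whose
    count is zero are still displayed.
    """
    n = card.n
    if n == 1:
        shapes: list[Shape] = [Circle((0.5, 0.5), 0.30)]
    elif n == 2:
        shapes = [Circle(c, VENN_2_RADIUS) for c in VENN_2_CENTERS]
    elif n == 3:
        rc = VENN_3_SIDE / math.sqrt(3.0)
        angles = (150.0, 30.0, 270.0)
        shapes = [
            Circle(
                (0.5 + rc * math.cos(math.radians(a)),
                 0.5 + rc * math.sin(math.radians(a))),
                VENN_3_RADIUS,
            )
            for a in angles
        ]
    else:
        shapes = [Ellipse(c, a, b, ang) for c, a, b, ang in VENN_4_ELLIPSES]
    cls = diagram_class or DiagramClass[f"VENN_{n}"]
    return Layout(shapes=fit_to_canvas(shapes), diagram_class=cls,
                  set_labels=card.labels)


# ---------------------------------------------------------------------------
# Area-proportional layouts
# ---------------------------------------------------------------------------

def _scaled_pair(
    t0: int, t1: int, inter: int, style: StyleConfig
) -> tuple[list[Circle], bool]:
    """Two circles with areas ∝ totals and center distance solved from the
    intersection count.  Returns (circles-on-canvas, degenerate-tangency)."""
    gap = style.tangency_gap
    if t0 == 0 and t1 == 0:
        raise EmptyDiagramError("both set totals are zero")
    if t0 == 0 or t1 == 0:
        # one empty set: a minimum-radius stand-in beside the real circle
        big = Circle((0.5, 0.5), 0.30)
        small = Circle((0.5 - 0.30 - 3 * style.min_radius, 0.5), style.min_radius)
        circles = [big, small] if t1 == 0 else [small, big]
        return circles, True
    r0 = radius_from_area(float(t0))
    r1 = radius_from_area(float(t1))
    degenerate = inter == 0 or inter == min(t0, t1)
    d = solve_distance(r0, r1, float(inter))
    circles = fit_to_canvas(
        [Circle((0.0, 0.0), r0), Circle((d, 0.0), r1)], style.margin
    )
    c0, c1 = circles
    if degenerate and not math.isclose(c0.radius, c1.radius, rel_tol=1e-12):
        # visible gap so tangent strokes do not coincide
        if inter == 0:
            d_new = c0.radius + c1.radius + gap
        else:
            d_new = max(0.0, abs(c0.radius - c1.radius) - gap)
        direction = 1.0 if c1.center[0] >= c0.center[0] else -1.0
        if inter > 0 and c0.radius < c1.radius:
            # c0 is the inner circle: move it, keep the outer fixed
            c0 = Circle((c1.center[0] - direction * d_new, c1.center[1]), c0.radius)
        else:
            c1 = Circle((c0.center[0] + direction * d_new, c0.center[1]), c1.radius)
        circles = [c0, c1]
    elif degenerate and inter == 0:
        c1 = Circle((c0.center[0] + c0.radius + c1.radius + gap, c0.center[1]), c1.radius)
        circles = [c0, c1]
    return circles, degenerate


def layout_scaled_two_set(card: RegionCardinalities, style: StyleConfig | None = None,
                          diagram_class: DiagramClass = DiagramClass.VENN_2) -> Layout:
    """Scaled two-set layout: radii ∝ sqrt(set totals), center distance
    inverted from the intersection count, rescaled to the canvas.

    Degenerate counts (empty intersection, total inclusion) produce
    tangency with a small visible gap."""
    if card.n != 2:
        raise WrongClassError("layout_scaled_two_set requires n = 2")
    style = style or StyleConfig()
    circles, _ = _scaled_pair(card.set_total(0), card.set_total(1),
                              card[(0, 1)], style)
    return Layout(shapes=list(circles), diagram_class=diagram_class,
                  set_labels=card.labels, scaled=True)


def check_three_set_scaling(card: RegionCardinalities, scaled: bool,
                            euler_enabled: bool = True) -> None:
    """Refuse area-proportional scaling of a three-set Venn diagram.

    With circles the drawing is fixed by the three pairwise distances, so
    the triple-intersection count could not change it; an accurate scaled
    three-set Venn diagram is therefore impossible and the request errors
    rather than silently misleading."""
    if not scaled or card.n != 3:
        return
    cls = classify_diagram(card, euler_enabled=euler_enabled)
    if cls in (DiagramClass.VENN_3, DiagramClass.FALLBACK_VENN_3):
        raise UnsupportedScalingError(
            "scaling of three-set Venn diagrams is disabled: circle geometry is "
            "fixed by the pairwise overlaps and cannot honour the triple "
            "intersection; retry without scaling"
        )


# templates for the three-set Euler configurations, in role space (a, b, c)
def _template_3(config: str, role_pattern: frozenset) -> list[Circle]:
    if config == "disjoint3":
        return [Circle((0.18, 0.5), 0.14), Circle((0.5, 0.5), 0.14),
                Circle((0.82, 0.5), 0.14)]
    if config == "chain":
        strict_ab = (1, 2) in role_pattern or (0, 1) in role_pattern
        strict_bc = (2,) in role_pattern
        r_c = 0.34
        r_b = 0.22 if strict_bc else r_c
        r_a = 0.12 if strict_ab else r_b
        x_c = 0.5
        x_b = x_c + (0.55 * (r_c - r_b))
        x_a = x_b + (0.55 * (r_b - r_a))
        return [Circle((x_a, 0.5), r_a), Circle((x_b, 0.5), r_b),
                Circle((x_c, 0.5), r_c)]
    if config == "nested_pair_disjoint":
        strict = (1,) in role_pattern
        r_b, r_a = (0.26, 0.14) if strict else (0.24, 0.24)
        x_a = 0.30 + (0.55 * (r_b - r_a))
        return [Circle((x_a, 0.5), r_a), Circle((0.30, 0.5), r_b),
                Circle((0.80, 0.5), 0.16)]
    if config == "two_disjoint_in_one":
        return [Circle((0.38, 0.5), 0.13), Circle((0.64, 0.5), 0.13),
                Circle((0.5, 0.5), 0.34)]
    if config == "two_overlap_in_one":
        return [Circle((0.42, 0.5), 0.15), Circle((0.58, 0.5), 0.15),
                Circle((0.5, 0.5), 0.34)]
    if config == "overlap_pair_disjoint":
        return [Circle((0.30, 0.5), 0.18), Circle((0.45, 0.5), 0.18),
                Circle((0.82, 0.5), 0.14)]
    if config == "in_lens":
        return [Circle((0.5, 0.5), 0.10), Circle((0.38, 0.5), 0.26),
                Circle((0.62, 0.5), 0.26)]
    if config == "in_one_of_pair":
        return [Circle((0.27, 0.5), 0.10), Circle((0.40, 0.5), 0.28),
                Circle((0.72, 0.5), 0.22)]
    if config == "in_one_cross":
        return [Circle((0.56, 0.5), 0.11), Circle((0.40, 0.5), 0.30),
                Circle((0.78, 0.5), 0.26)]
    if config == "covered_by_union":
        return [Circle((0.5, 0.5), 0.13), Circle((0.33, 0.5), 0.27),
                Circle((0.67, 0.5), 0.27)]
    if config == "ring":
        rc = 0.30 / math.sqrt(3.0)
        return [
            Circle((0.5 + rc * math.cos(math.radians(a)),
                    0.5 + rc * math.sin(math.radians(a))), 0.16)
            for a in (150.0, 30.0, 270.0)
        ]
    raise WrongClassError(f"unknown Euler configuration {config!r}")


def _template_2(config: str) -> list[Circle]:
    if config == "disjoint2":
        return [Circle((0.27, 0.5), 0.20), Circle((0.73, 0.5), 0.20)]
    if config == "nested2":
        return [Circle((0.57, 0.5), 0.15), Circle((0.5, 0.5), 0.30)]
    if config == "equal2":
        return [Circle((0.5, 0.5), 0.26), Circle((0.5, 0.5), 0.26)]
    if config == "overlap2":
        return [Circle(c, VENN_2_RADIUS) for c in VENN_2_CENTERS]
    raise WrongClassError(f"unknown Euler configuration {config!r}")


def _scaled_3(config: str, totals: Sequence[float], style: StyleConfig
              ) -> list[Circle] | None:
    """Exact-area circles for the scalable three-set configurations.

    Returns None when the exact geometry cannot be packed (the caller then
    warns and falls back to template proportions)."""
    r = [radius_from_area(t) if t > 0 else 0.0 for t in totals]
    gap = style.tangency_gap * max(r) * 10  # gap in abstract units
    if config == "disjoint3":
        x0 = 0.0
        x1 = r[0] + r[1] + 0.25 * (r[0] + r[1])
        x2 = x1 + r[1] + r[2] + 0.25 * (r[1] + r[2])
        return [Circle((x0, 0.0), r[0]), Circle((x1, 0.0), r[1]),
                Circle((x2, 0.0), r[2])]
    if config == "chain":
        x_c = 0.0
        x_b = x_c + 0.55 * (r[2] - r[1])
        x_a = x_b + 0.55 * (r[1] - r[0])
        return [Circle((x_a, 0.0), max(r[0], 1e-9)),
                Circle((x_b, 0.0), max(r[1], 1e-9)),
                Circle((x_c, 0.0), r[2])]
    if config == "nested_pair_disjoint":
        x_a = 0.55 * (r[1] - r[0])
        x_c = r[1] + r[2] + 0.25 * (r[1] + r[2])
        return [Circle((x_a, 0.0), max(r[0], 1e-9)), Circle((0.0, 0.0), r[1]),
                Circle((x_c, 0.0), r[2])]
    if config == "two_disjoint_in_one":
        need = r[0] + r[1] + gap
        avail = 2.0 * r[2] - r[0] - r[1] - gap
        if avail <= 0 or need / avail > 0.92:
            return None
        f = max(0.6, need / avail)
        return [Circle((-(r[2] - r[0] - 0.5 * gap) * f, 0.0), r[0]),
                Circle(((r[2] - r[1] - 0.5 * gap) * f, 0.0), r[1]),
                Circle((0.0, 0.0), r[2])]
    return None


def layout_euler(card: RegionCardinalities, diagram_class: DiagramClass,
                 scaled: bool = False, style: StyleConfig | None = None) -> Layout:
    """Arrangement for a recognized Euler case.

    Scalable cases (inclusion/disjointness only) honour the set totals;
    other scaled requests log a warning and keep template proportions."""
    if not diagram_class.is_euler:
        raise WrongClassError(f"{diagram_class} is not an Euler case")
    style = style or StyleConfig()
    plan = _euler_plan(card)
    if plan is None or plan.diagram_class is not diagram_class:
        raise WrongClassError(
            f"cardinalities do not realize {diagram_class} "
            f"(matched {plan.diagram_class if plan else 'no Euler case'})"
        )
    n = card.n

    if scaled and diagram_class not in SCALABLE_EULER:
        logger.warning(
            "scaled layout not available for %s (partial overlaps present); "
            "using template proportions", diagram_class.value,
        )
        scaled = False

    if n == 2 and scaled:
        return layout_scaled_two_set(card, style, diagram_class)

    m = len(plan.roles)
    role_circles: list[Circle] | None = None
    if scaled:
        totals = [float(card.set_total(i)) for i in plan.roles]
        if m == 2 or m == 1:
            t0 = totals[0]
            t1 = totals[1] if m == 2 else 0.0
            inter = float(card.pair_total(plan.roles[0], plan.roles[1])) if m == 2 else 0.0
            r0 = radius_from_area(t0)
            r1 = radius_from_area(t1) if t1 > 0 else 0.0
            if m == 1 or t1 == 0:
                role_circles = [Circle((0.0, 0.0), r0)]
            else:
                d = solve_distance(r0, r1, inter)
                if inter == 0:
                    d += 0.1 * (r0 + r1)
                elif inter >= min(t0, t1):
                    d = max(0.0, abs(r0 - r1) * 0.45)
                role_circles = [Circle((0.0, 0.0), r0), Circle((d, 0.0), r1)]
        else:
            role_circles = _scaled_3(plan.config, totals, style)
        if role_circles is None:
            logger.warning(
                "exact-area geometry for %s cannot be packed; "
                "using template proportions", diagram_class.value,
            )
            scaled = False

    if not scaled or role_circles is None:
        if m == 1:
            role_circles = [Circle((0.5, 0.5), 0.30)]
        elif m == 2:
            role_circles = _template_2(plan.config)
        else:
            role_circles = _template_3(plan.config, plan.role_pattern)

    fitted = fit_to_canvas(role_circles, style.margin)
    shapes: list[Shape] = [None] * n  # type: ignore[list-item]
    for role, orig in enumerate(plan.roles):
        shapes[orig] = fitted[role]
    for tiny, orig in zip(_tiny_circles(len(plan.empty_sets)), plan.empty_sets):
        shapes[orig] = tiny
    return Layout(shapes=shapes, diagram_class=diagram_class,
                  set_labels=card.labels, scaled=scaled)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def _shape_extent(shape: Shape) -> float:
    return shape.radius if isinstance(shape, Circle) else shape.semi_major


def _boundary_distance(shapes: Sequence[Shape], x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Approximate distance from points to the nearest shape boundary."""
    dist = np.full(x.shape, np.inf)
    for shape in shapes:
        if isinstance(shape, Circle):
            d = np.abs(np.hypot(x - shape.center[0], y - shape.center[1]) - shape.radius)
        else:
            theta = math.radians(shape.angle)
            dx, dy = x - shape.center[0], y - shape.center[1]
            u = dx * math.cos(theta) + dy * math.sin(theta)
            v = -dx * math.sin(theta) + dy * math.cos(theta)
            rho = np.hypot(u / shape.semi_major, v / shape.semi_minor)
            d = np.abs(1.0 - rho) * shape.semi_minor
        dist = np.minimum(dist, d)
    return dist


def _interior_anchor(shapes: Sequence[Shape], key: RegionKey,
                     seed: int) -> tuple[float, float] | None:
    """A point well inside a region, for regions whose centroid falls
    outside them (crescents around a nested shape).

    Samples the bounding box and returns the region hit farthest from any
    shape boundary (an approximate pole of inaccessibility)."""
    rng = np.random.default_rng(seed)
    bounds = np.array([s.bounds() for s in shapes])
    x0, y0 = bounds[:, 0].min(), bounds[:, 1].min()
    x1, y1 = bounds[:, 2].max(), bounds[:, 3].max()
    xs = rng.uniform(x0, x1, 40_000)
    ys = rng.uniform(y0, y1, 40_000)
    code = np.zeros(xs.shape, dtype=np.int64)
    for i, shape in enumerate(shapes):
        code |= shape.contains(xs, ys).astype(np.int64) << i
    want = sum(1 << i for i in key)
    mask = code == want
    if not mask.any():
        return None
    xs, ys = xs[mask], ys[mask]
    best = int(np.argmax(_boundary_distance(shapes, xs, ys)))
    return (float(xs[best]), float(ys[best]))


def _zero_region_anchor(shapes: Sequence[Shape], key: RegionKey) -> tuple[float, float]:
    """Placement for the numeral of a region with no drawable area
    (degenerate tangency cases in scaled layouts)."""
    if len(key) == 1:
        shape = shapes[key[0]]
        others = [s for i, s in enumerate(shapes) if i != key[0]]
        if others:
            ox = float(np.mean([s.center[0] for s in others]))
            oy = float(np.mean([s.center[1] for s in others]))
            dx, dy = shape.center[0] - ox, shape.center[1] - oy
            norm = math.hypot(dx, dy)
            u = (dx / norm, dy / norm) if norm > 1e-9 else (-1.0, 0.0)
        else:
            u = (0.0, 1.0)
        ext = _shape_extent(shape)
        return (shape.center[0] + u[0] * (ext + 0.025),
                shape.center[1] + u[1] * (ext + 0.025))
    xs = [shapes[i].center[0] for i in key]
    ys = [shapes[i].center[1] for i in key]
    return (float(np.mean(xs)), float(np.mean(ys)))


def attach_labels(
    layout: Layout,
    card: RegionCardinalities,
    style: StyleConfig | None = None,
    n_samples: int = DEFAULT_SAMPLES,
    seed: int = DEFAULT_SEED,
) -> Layout:
    """Place area labels at region centroids, caption labels per the style,
    and a leader line for a too-small lens in scaled two-set layouts.

    Venn classes label every region (zeros included); Euler classes label
    only the populated regions."""
    style = style or StyleConfig()
    oracle = region_areas_and_centroids(layout.shapes, n_samples=n_samples, seed=seed)
    venn_mode = not layout.diagram_class.is_euler

    region_anchors: dict[RegionKey, tuple[float, float]] = {}
    region_labels: dict[RegionKey, str] = {}
    for key in all_region_keys(card.n):
        count = card[key]
        if count == 0 and not venn_mode:
            continue
        area, centroid = oracle[key]
        if centroid is not None and point_region(layout.shapes, *centroid) != key:
            # non-convex region (e.g. a crescent around a nested circle)
            centroid = _interior_anchor(layout.shapes, key, seed + 1)
        if centroid is None:
            centroid = _zero_region_anchor(layout.shapes, key)
        region_anchors[key] = centroid
        region_labels[key] = str(count)

    leader_lines: list[tuple[tuple[float, float], tuple[float, float]]] = []
    if layout.scaled and card.n == 2 and card[(0, 1)] > 0:
        c0, c1 = layout.shapes
        if isinstance(c0, Circle) and isinstance(c1, Circle):
            d = math.hypot(c1.center[0] - c0.center[0], c1.center[1] - c0.center[1])
            width = c0.radius + c1.radius - d
            if abs(c0.radius - c1.radius) < d and 0 < width < style.small_region_threshold:
                inner = region_anchors[(0, 1)]
                top = max(c0.center[1] + c0.radius, c1.center[1] + c1.radius)
                outer = (inner[0], top + style.leader_offset)
                leader_lines.append((inner, outer))
                region_anchors[(0, 1)] = outer

    caption_anchors: dict[str, tuple[float, float, str]] = {}
    centers = np.array([s.center for s in layout.shapes], dtype=float)
    hub = centers.mean(axis=0)
    for i, label in enumerate(layout.set_labels):
        shape = layout.shapes[i]
        if style.caption_mode == "explicit" and label in style.caption_positions:
            x, y = style.caption_positions[label]
            caption_anchors[label] = (x, y, style.caption_justification)
            continue
        if style.caption_mode == "text":
            anchor = region_anchors.get((i,))
            if anchor is None:
                anchor = shape.center
            caption_anchors[label] = (anchor[0], anchor[1] - style.caption_distance,
                                      "center")
            continue
        dx, dy = shape.center[0] - hub[0], shape.center[1] - hub[1]
        norm = math.hypot(dx, dy)
        if norm < 1e-9:
            theta = math.radians(90.0 + 120.0 * i)
            dx, dy, norm = math.cos(theta), math.sin(theta), 1.0
        u = (dx / norm, dy / norm)
        ext = _shape_extent(shape)
        x = shape.center[0] + u[0] * (ext + style.caption_distance)
        y = shape.center[1] + u[1] * (ext + style.caption_distance)
        ha = "left" if u[0] > 0.3 else ("right" if u[0] < -0.3 else "center")
        caption_anchors[label] = (x, y, ha)

    return replace(layout, region_anchors=region_anchors,
                   region_labels=region_labels, caption_anchors=caption_anchors,
                   leader_lines=leader_lines)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def build_layout(
    card: RegionCardinalities,
    style: StyleConfig | None = None,
    n_samples: int = DEFAULT_SAMPLES,
    seed: int = DEFAULT_SEED,
) -> Layout:
    """Classify, place, label and transform in one call."""
    style = style or StyleConfig()
    cls = classify_diagram(card, euler_enabled=style.euler)
    check_three_set_scaling(card, style.scaled, euler_enabled=style.euler)
    if cls.is_euler:
        layout = layout_euler(card, cls, scaled=style.scaled, style=style)
    elif cls is DiagramClass.VENN_2 and style.scaled:
        layout = layout_scaled_two_set(card, style)
    else:
        if style.scaled and cls is DiagramClass.VENN_4:
            logger.warning("scaling is not available for four-set diagrams; "
                           "drawing unscaled")
        layout = layout_venn(card, cls)
    layout = attach_labels(layout, card, style, n_samples=n_samples, seed=seed)
    return layout.transformed(style.rotation, style.invert)
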