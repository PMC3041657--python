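"""Circle and ellipse geometry for area-proportional diagrams.

The closed-form two-circle lens area is strictly decreasing in the center
distance, which makes its inversion (distance from a target intersection
area) a guaranteed bisection.  Three circles are then placed from the three
pairwise distances by triangle construction; the triple intersection never
enters the construction, which is exactly why circular three-set diagrams
cannot in general be drawn area-proportionally.

Ellipse regions have no closed form here: a seeded rejection-sampling
oracle (:func:`region_areas_and_centroids`) is the single source of truth
for ellipse-region areas and for all region centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleOverlapError, InvalidInputError, UnrealizableArrangementError

CANVAS_CENTER = (0.5, 0.5)

#: default sample count and seed for the Monte-Carlo region oracle
DEFAULT_SAMPLES = 1_000_000
DEFAULT_SEED = 20110126


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0 and math.isfinite(self.radius)):
            raise InvalidInputError(f"circle radius must be positive, got {self.radius}")
        if not all(math.isfinite(c) for c in self.center):
            raise InvalidInputError("circle center must be finite")

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius**2

    def bounds(self) -> tuple[float, float, float, float]:
        cx, cy = self.center
        return (cx - self.radius, cy - self.radius, cx + self.radius, cy + self.radius)


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float  # degrees counter-clockwise

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise InvalidInputError("require semi_major >= semi_minor > 0")

    @property
    def area(self) -> float:
        return math.pi * self.semi_major * self.semi_minor

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        theta = math.radians(self.angle)
        dx = x - self.center[0]
        dy = y - self.center[1]
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        return (u / self.semi_major) ** 2 + (v / self.semi_minor) ** 2 <= 1.0

    def bounds(self) -> tuple[float, float, float, float]:
        # tight axis-aligned bounds of a rotated ellipse
        theta = math.radians(self.angle)
        hx = math.hypot(self.semi_major * math.cos(theta), self.semi_minor * math.sin(theta))
        hy = math.hypot(self.semi_major * math.sin(theta), self.semi_minor * math.cos(theta))
        cx, cy = self.center
        return (cx - hx, cy - hy, cx + hx, cy + hy)


Shape = Circle | Ellipse


@dataclass(frozen=True)
class ThreeCircleArrangement:
    """Three circles with their recorded pairwise center distances."""

    circles: tuple[Circle, Circle, Circle]
    d_ab: float
    d_bc: float
    d_ac: float


def radius_from_area(area: float) -> float:
    """Radius of the circle of a given area (A = pi r^2)."""
    if not area > 0:
        raise InvalidInputError(f"area must be positive, got {area}")
    return math.sqrt(area / math.pi)


def lens_area(d: float, r1: float, r2: float) -> float:
    """Area of intersection of two circles with radii r1, r2 at center
    distance d.

    Total on d >= 0: returns the full smaller circle when one circle
    contains the other (d <= |r1 - r2|) and 0 when they are disjoint
    (d >= r1 + r2); between those bounds the standard circular-segment
    closed form applies.
    """
    if d < 0 or r1 <= 0 or r2 <= 0:
        raise InvalidInputError("require d >= 0 and positive radii")
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    if d >= r1 + r2:
        return 0.0
    cos1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1)
    cos2 = (d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2)
    cos1 = min(1.0, max(-1.0, cos1))
    cos2 = min(1.0, max(-1.0, cos2))
    tri = (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    return (
        r1 * r1 * math.acos(cos1)
        + r2 * r2 * math.acos(cos2)
        - 0.5 * math.sqrt(max(0.0, tri))
    )


def solve_distance(r1: float, r2: float, target: float, tol: float = 1e-9,
                   max_iter: int = 200) -> float:
    """Center distance at which two circles intersect in ``target`` area.

    The lens area is strictly decreasing on [|r1 - r2|, r1 + r2], so plain
    bisection converges; iteration stops when the area residual is within
    ``tol`` (absolute).  A target of 0 returns external tangency, a target
    of the full smaller circle returns internal tangency.
    """
    if r1 <= 0 or r2 <= 0:
        raise InvalidInputError("radii must be positive")
    max_area = math.pi * min(r1, r2) ** 2
    if not 0.0 <= target <= max_area + tol:
        raise InfeasibleOverlapError(
            f"intersection area {target} outside feasible range [0, {max_area}]"
        )
    if target <= 0.0:
        return r1 + r2
    if target >= max_area:
        return abs(r1 - r2)
    lo, hi = abs(r1 - r2), r1 + r2  # lens(lo) = max_area, lens(hi) = 0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a = lens_area(mid, r1, r2)
        if abs(a - target) <= tol:
            return mid
        if a > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def place_three_circles(
    r_a: float, r_b: float, r_c: float,
    area_ab: float, area_bc: float, area_ac: float,
    tol: float = 1e-9,
) -> ThreeCircleArrangement:
    """Place three circles from radii and the three pairwise intersection
    areas.

    A sits at the origin, B on the +x axis, C in the upper half-plane; the
    three solved distances form the (unique) triangle of centers.  The
    triple intersection plays no role.  If the distances violate the
    triangle inequality the arrangement is unrealizable — except in the
    all-disjoint case, which is returned as a row of separated circles.
    """
    if area_ab == area_bc == area_ac == 0.0:
        gap_ab = 0.25 * (r_a + r_b)
        gap_bc = 0.25 * (r_b + r_c)
        a = Circle((0.0, 0.0), r_a)
        b = Circle((r_a + r_b + gap_ab, 0.0), r_b)
        c = Circle((b.center[0] + r_b + r_c + gap_bc, 0.0), r_c)
        return ThreeCircleArrangement(
            circles=(a, b, c),
            d_ab=b.center[0],
            d_bc=c.center[0] - b.center[0],
            d_ac=c.center[0],
        )
    d_ab = solve_distance(r_a, r_b, area_ab, tol)
    d_bc = solve_distance(r_b, r_c, area_bc, tol)
    d_ac = solve_distance(r_a, r_c, area_ac, tol)
    eps = 1e-12
    if (d_ab > d_bc + d_ac + eps or d_bc > d_ab + d_ac + eps
            or d_ac > d_ab + d_bc + eps):
        raise UnrealizableArrangementError(
            f"distances d_ab={d_ab:.6g}, d_bc={d_bc:.6g}, d_ac={d_ac:.6g} "
            "violate the triangle inequality"
        )
    a = Circle((0.0, 0.0), r_a)
    if d_ab < eps:
        # A and B concentric; C anywhere at distance d_ac (== d_bc)
        b = Circle((0.0, 0.0), r_b)
        c = Circle((0.0, d_ac), r_c) if d_ac > 0 else Circle((0.0, 0.0), r_c)
    else:
        b = Circle((d_ab, 0.0), r_b)
        cx = (d_ab**2 + d_ac**2 - d_bc**2) / (2.0 * d_ab)
        cy = math.sqrt(max(0.0, d_ac**2 - cx**2))
        c = Circle((cx, cy), r_c)
    return ThreeCircleArrangement(circles=(a, b, c), d_ab=d_ab, d_bc=d_bc, d_ac=d_ac)


def region_areas_and_centroids(
    shapes: Sequence[Shape],
    n_samples: int = DEFAULT_SAMPLES,
    seed: int = DEFAULT_SEED,
) -> dict[tuple[int, ...], tuple[float, tuple[float, float] | None]]:
    """Monte-Carlo region oracle.

    Uniform rejection sampling over the joint bounding box of the shapes;
    each sample is assigned to the region keyed by the subset of shapes
    containing it.  Returns, for every non-empty subset of shape indices,
    ``(area, centroid)`` with ``area = box_area * hit_fraction`` and the
    centroid the mean of the hits (``None`` for regions with no hits,
    which report area 0).  Deterministic for a fixed seed.
    """
    if not shapes:
        raise InvalidInputError("at least one shape is required")
    if n_samples < 10_000:
        raise InvalidInputError("n_samples must be at least 10^4")
    n = len(shapes)
    bounds = np.array([s.bounds() for s in shapes])
    x0, y0 = bounds[:, 0].min(), bounds[:, 1].min()
    x1, y1 = bounds[:, 2].max(), bounds[:, 3].max()
    box_area = (x1 - x0) * (y1 - y0)

    rng = np.random.default_rng(seed)
    xs = rng.uniform(x0, x1, n_samples)
    ys = rng.uniform(y0, y1, n_samples)
    code = np.zeros(n_samples, dtype=np.int64)
    for i, shape in enumerate(shapes):
        code |= shape.contains(xs, ys).astype(np.int64) << i

    hits = np.bincount(code, minlength=1 << n)
    sum_x = np.bincount(code, weights=xs, minlength=1 << n)
    sum_y = np.bincount(code, weights=ys, minlength=1 << n)

    out: dict[tuple[int, ...], tuple[float, tuple[float, float] | None]] = {}
    for bits in range(1, 1 << n):
        key = tuple(i for i in range(n) if bits & (1 << i))
        h = int(hits[bits])
        if h == 0:
            out[key] = (0.0, None)
        else:
            out[key] = (
                box_area * h / n_samples,
                (sum_x[bits] / h, sum_y[bits] / h),
            )
    return out


# ---------------------------------------------------------------------------
# Rigid transforms (rotation about the canvas center, mirror inversion)
# ---------------------------------------------------------------------------

def transform_point(
    point: tuple[float, float],
    rotation_deg: float,
    invert: bool,
    center: tuple[float, float] = CANVAS_CENTER,
) -> tuple[float, float]:
    """Apply inversion (reflection across the vertical axis through
    ``center``) and then a counter-clockwise rotation about ``center``."""
    x, y = point
    if invert:
        x = 2.0 * center[0] - x
    theta = math.radians(rotation_deg)
    dx, dy = x - center[0], y - center[1]
    return (
        center[0] + dx * math.cos(theta) - dy * math.sin(theta),
        center[1] + dx * math.sin(theta) + dy * math.cos(theta),
    )


def transform_shape(
    shape: Shape,
    rotation_deg: float,
    invert: bool,
    center: tuple[float, float] = CANVAS_CENTER,
) -> Shape:
    """Co-transform a shape: centers move as points; an ellipse's angle is
    mirrored by the inversion and advanced by the rotation."""
    new_center = transform_point(shape.center, rotation_deg, invert, center)
    if isinstance(shape, Circle):
        return replace(shape, center=new_center)
    angle = -shape.angle if invert else shape.angle
    return replace(shape, center=new_center, angle=angle + rotation_deg)
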