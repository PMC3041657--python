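# Methods

This note records the models, algorithms, defaults and design decisions
behind `vennforge`, in the spirit of a package vignette: what is computed,
under which assumptions, and where the genuinely open choices were made.

## 1. Region model

For `n` named sets (1 ≤ n ≤ 4) the plane decomposes into `2^n − 1`
*partial areas* — one region per non-empty subset `S` of sets, containing
the elements that belong to exactly the sets in `S`. Region keys are
canonical sorted tuples of 0-based set indices; the display order of sets
is the input order. Counts are derived from element sets by a single pass
over the union (each element's membership bit-vector indexes its region),
or supplied directly as a partial-area table, in which case absent regions
are zero-filled and negative counts, more than four sets, and the all-zero
table are rejected as distinct errors. Duplicate elements within one input
list collapse to a single member: the inputs are sets, and list-based entry
formats should not change that semantics.

Two invariants pin the model down and are property-tested: the region
counts sum to the size of the union (conservation), and summing the
regions containing index `i` recovers `|set_i|` (projection).

## 2. Circle geometry

**Lens area.** Two circles (radii `r1`, `r2`, center distance `d`)
intersect in the standard circular-segment closed form; the implementation
is total on `d ≥ 0` by returning the full smaller circle for
`d ≤ |r1 − r2|` and 0 for `d ≥ r1 + r2`. Arguments of `acos` are clamped
to [−1, 1] and the triangle product to ≥ 0 to absorb floating-point noise
at the tangency boundaries.

**Distance solve.** The lens area is strictly decreasing in `d` between
internal and external tangency, so the inverse problem (find `d` realizing
a target intersection area) is solved by plain bisection: absolute area
tolerance 1e−9, at most 200 iterations (the bracket halves each step, so
the tolerance is reached long before the cap). Bisection was chosen over a
derivative-based or generic root finder because the stopping rule here is
an *area* residual, monotonicity guarantees convergence, and the cost
(≲ 60 lens evaluations) is negligible. Targets of exactly 0 or the full
smaller circle short-circuit to the tangency distances; targets outside
`[0, π·min(r1,r2)²]` raise an infeasible-overlap error.

**Three circles.** Given three radii and three pairwise intersection
areas, the three solved distances determine a unique triangle of centers:
A at the origin, B on the +x axis, C in the upper half-plane (the
canonical orientation; rotation and inversion provide the alternatives).
The triple intersection never enters the construction — this is precisely
why scaled three-set Venn diagrams are refused (§4). A triangle-inequality
violation raises an unrealizable-arrangement error, except when all three
pairwise areas are zero, which is returned as a row of disjoint circles
with gaps of 25% of the mean radius pair.

**Monte-Carlo region oracle.** Region areas and centroids for arbitrary
circle/ellipse arrangements come from uniform rejection sampling over the
joint bounding box: area = box area × hit fraction, centroid = mean of
hits, deterministic for a fixed seed (default 10^6 samples, default seed
20110126). The standard error of a region area is
`box·sqrt(p(1−p)/N)`; at 10^6 samples a region occupying ~10% of the box
is measured to ~0.1% relative error. The oracle is the single source of
truth for ellipse-region areas and all label anchors, and the independent
cross-check for the closed-form lens (agreement within 3 standard errors
is asserted in the tests, alongside a shapely polygon-buffer oracle).

**Transforms.** Inversion is reflection across the vertical axis through
the canvas center (0.5, 0.5); rotation is counter-clockwise about the same
point, applied after the inversion. Ellipse angles are negated by the
mirror and advanced by the rotation; all label anchors and leader lines
co-transform; label *texts* never change.

## 3. Diagram classification

With Euler recognition off, with four sets, or with no empty region, the
diagram is the standard `VENN_n`. Otherwise the zero/nonzero pattern of
the counts is matched, up to set permutation, against a catalogue of
configurations that circles can realize **exactly** (the emitted layout
must show positive area precisely for the populated regions):

| configuration | pattern realized |
|---|---|
| three disjoint circles | only the three exclusive regions |
| nested chain A ⊆ B ⊆ C | triple region + suffix regions (equalities drawn as coincident circles) |
| nested pair + disjoint third | A∩B, B-only, C-only |
| two disjoint circles inside a third | A∩C, B∩C, C-only |
| two overlapping circles inside a third | A∩C, B∩C, A∩B∩C, C-only |
| overlapping pair + disjoint third | A, B, A∩B, C |
| circle inside a lens | A∩B∩C, B∩C, B, C |
| circle inside one member of an overlapping pair | A∩B, B, B∩C, C |
| the same, crossing into the lens | A∩B, A∩B∩C, B, B∩C, C |
| one set covered by the union of the other two | everything except A-only |
| pairwise overlaps with empty triple ("ring") | everything except A∩B∩C |

Sets with zero total are stripped before matching and drawn as parked
radius-0.015 circles (area ≈ 7.1e−4 of the canvas, below the 1e−3
threshold treated as degenerate); a two-set relation among the remaining
sets maps to the corresponding three-set class. Every pattern outside the
catalogue — including the canonical impossible case of two disjoint sets
exactly comprising the third, which would require the outer circle to
equal the union of two disjoint circles — falls back to a standard Venn
diagram, so no input dead-ends. Exhaustive enumeration (all 7 two-set and
128 three-set patterns) shows the catalogue handles 71 of the 128
three-set patterns; the rest take the fallback.

The exact case list a circle-and-ellipse engine "should" support is an
open design choice; this catalogue was chosen so that every emitted layout
is verifiable against the sampling oracle, and it deliberately errs on the
side of falling back to a Venn diagram rather than drawing a misleading
Euler approximation.

## 4. Scaling policy

- **Two sets:** always scalable. Radii are `sqrt(total/π)` in count units,
  the center distance comes from the bisection solve targeting the
  intersection count, and the arrangement is rescaled to the canvas.
  Degenerate counts produce tangency — external for an empty intersection,
  internal for total inclusion — opened up by a 0.01-canvas-unit gap so the
  strokes do not coincide (equal sets stay coincident).
- **Three-set Venn:** refused with an unsupported-scaling error. The three
  pairwise distances already fix a circular drawing, so the
  triple-intersection count cannot alter it; drawing "scaled" circles would
  silently misrepresent that count. Ellipse or polygon fits exist but need
  iterative optimization and lose the familiar circular form; they are out
  of scope.
- **Three-set Euler:** scalable exactly when the geometry is fully
  determined by set totals plus inclusion/disjointness — disjoint triples,
  nested chains, a nested pair with a disjoint third, and two disjoint sets
  inside a third. Nested offsets place the inner circle at 55% of the
  radius difference (deterministic, leaves room for the crescent label);
  disjoint gaps are 25% of the radius sum. Two-disjoint-inside-one has a
  packing constraint (the two inner circles must fit on a diameter); when
  exact areas cannot be packed, and for every non-scalable case, the
  request logs a warning and falls back to template proportions.

## 5. Labels, captions, leader lines

Numeric area labels sit at region centroids from the sampling oracle. When
a centroid falls outside its own region (crescents around a nested circle
are non-convex), the anchor moves to an approximate pole of
inaccessibility: the sampled in-region point farthest from any shape
boundary (40 000 auxiliary samples). Venn classes label every region,
zeros included; Euler classes label only populated regions. Regions with
no drawable area (degenerate tangency in scaled two-set mode) get
heuristic anchors — the midpoint between shapes for multi-set keys, a
point just outside the shape away from the others for exclusive keys.

In scaled two-set layouts a lens narrower than 0.04 canvas units
(configurable) is too small for its numeral: the label moves 0.05 above
the upper shape boundary and a leader line connects it to the lens.

Captions default to sitting outside each shape, pushed away from the mean
of the shape centers by the shape extent plus `caption_distance` (0.05);
justification follows the push direction. `"text"` mode instead attaches
the caption below the set's exclusive-region numeral at `caption_distance`;
`"explicit"` mode takes absolute positions per set.

## 6. Rendering

Drawing uses matplotlib's object-oriented Agg backend (no global pyplot
state) on a unit-square axes; order is fills → shape lines → area labels →
leader lines → captions → titles, each artist tagged with a `gid` so tests
can assert content without rasterizing glyphs. Defaults: white background,
a four-colour semi-transparent palette (alpha 0.5), solid black outlines of
width 2, sans-serif labels at 2.5% of canvas height, 3000×3000 px at
300 DPI, TIFF with LZW compression. BMP is written by rasterizing to PNG
and converting through Pillow (matplotlib has no BMP writer). SVG output
fixes the matplotlib hash salt and strips the date so identical inputs
yield byte-identical files. With no output path, a `FigureHandle` wrapping
the live figure is returned; nothing is written.

## 7. The random-set generator

`generate_random_sets(n_sets, universe_size, membership_prob, seed)` gives
each of `universe_size` elements an independent Bernoulli(`membership_prob`)
membership in each set. This emulates the *combinatorial* structure of
overlapping result lists — every region pattern arises with its binomial
probability — and is ideal for exercising the region model, classifier and
scaling code across many seeds. It does **not** emulate correlated
membership (genes co-regulated across conditions), heavy-tailed set sizes,
or identifier noise; passing tests therefore certify the set algebra and
geometry, not robustness to messy real-world identifier handling, which is
deliberately out of scope (no gene-ID normalization is attempted).

## 8. Problem sizes and tolerances in the test suite

Unit tests run the oracle at 3×10^5 samples (region non-degeneracy needs
only coarse areas); accuracy-critical checks — closed form vs oracle,
scaled two-set proportions (2% relative), transform invariance — use 10^6
samples, where Monte-Carlo noise is an order of magnitude below the
asserted tolerances. The oracle-equivalence property runs 100 seeded
fixtures with universes up to 200 elements. Hypothesis property tests are
derandomized for reproducibility. The acceptance script mirrors these
sizes; a full run takes a few seconds on one core.

## 9. Known limitations

- At most four sets for Venn, three for Euler; no polygon-based Euler
  fitting, so the unsupported patterns render as Venn fallbacks.
- Scaled three-set Euler support is limited to the
  inclusion/disjointness-determined cases; partially overlapping Euler
  cases keep template proportions.
- The four-ellipse Venn constants guarantee all 15 regions are
  non-degenerate but the region *areas* are not proportional to counts
  (four-set scaling is not offered).
- Caption auto-placement is heuristic; dense custom styles may need
  explicit caption positions.
- The Monte-Carlo oracle's label anchors inherit sampling jitter (≲ 10^−3
  canvas units at the default sample count); fix the seed for pixel-stable
  output, as the CLI does by default.
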