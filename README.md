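# vennforge

Publication-quality, highly customizable **Venn and Euler diagrams** for up
to four sets, with area-proportional (scaled) layouts where circle geometry
permits them.

Comparing overlapping result lists — differentially expressed genes under
two treatments, peak calls from three replicates, variant sets from four
callers — is an everyday task in bioinformatics. `vennforge` turns named
element sets (or directly supplied region counts) into the full table of
2^n − 1 *partial areas* (the regions bounded by the shape outlines that
cannot be subdivided further), picks an appropriate diagram:

- **Venn diagrams** (1–4 sets): every region is drawn, zero counts included;
- **Euler diagrams** (2–3 sets): only non-zero regions appear, recognized
  automatically from the zero pattern of the counts (nested, disjoint and
  mixed cases), with a Venn fallback for the patterns no circle/ellipse
  arrangement can realize;

and renders a high-resolution figure (TIFF by default; PNG/JPEG/BMP/SVG too)
or returns an in-memory figure handle.

## The geometry at the core

For two circles with radii $r_1, r_2$ at center distance $d$, the
intersection ("lens") area has the closed form

$$A(d) = r_1^2\cos^{-1}\!\frac{d^2+r_1^2-r_2^2}{2dr_1}
       + r_2^2\cos^{-1}\!\frac{d^2+r_2^2-r_1^2}{2dr_2}
       - \tfrac12\sqrt{(-d+r_1+r_2)(d+r_1-r_2)(d-r_1+r_2)(d+r_1+r_2)}$$

$A(d)$ is strictly decreasing on $\left(|r_1-r_2|,\ r_1+r_2\right)$, so a given
intersection area corresponds to a **unique** center distance, found here by
bisection to an area tolerance of 1e−9. With set areas $A_A = \pi r^2$ this
yields exact area-proportional two-set diagrams. For three circles the three
pairwise distances $d_{AB}, d_{BC}, d_{AC}$ form a unique triangle — which
means the triple-intersection count can never influence a circular drawing.
An "accurate" scaled three-set Venn diagram is therefore geometrically
impossible, and `vennforge` refuses to draw one (scaled three-set *Euler*
cases built purely from inclusion and disjointness remain available). A
seeded Monte-Carlo rejection-sampling oracle measures region areas and
centroids for everything without a closed form (ellipse regions, label
anchors) and underpins the test suite.

## Worked example

```python
import vennforge as vf

up_tumour  = {"TP53", "MYC", "EGFR", "KRAS", "CDK4", "MDM2", "CCND1"}
up_treated = {"MYC", "KRAS", "CCND1", "BCL2", "STAT3"}

sets = vf.SetCollection.from_dict({"tumour": up_tumour, "treated": up_treated})
card = vf.compute_region_cardinalities(sets)
print("region counts:", {"&".join(card.labels[i] for i in k): v
                         for k, v in sorted(card.counts.items())})
print("diagram class:", vf.classify_diagram(card).value)

style = vf.parse_style({"scaled": True})
layout = vf.build_layout(card, style, n_samples=200_000, seed=1)
path = vf.render_diagram(layout, style,
                         vf.RenderSpec(path="overlap.tiff",
                                       width=1200, height=1200, dpi=300))
print("wrote:", path)
r0, r1 = (s.radius for s in layout.shapes)
print(f"radius ratio tumour/treated: {r0/r1:.3f}")
```

prints

```
region counts: {'tumour': 4, 'tumour&treated': 3, 'treated': 2}
diagram class: VENN_2
wrote: overlap.tiff
radius ratio tumour/treated: 1.183
```

Four genes are tumour-only, two treated-only and three shared, all three
regions are populated so the diagram is a standard two-set Venn, and because
scaling is on, the circle radii honour the set totals: 7 versus 5 elements
gives a radius ratio of √(7/5) ≈ 1.183, and the lens is sized so drawn
areas are proportional to 4 : 3 : 2.

The same run from the shell:

```bash
vennforge --sets tumour.txt --sets treated.txt --scaled --out overlap.tiff
```

Styling (fills, alpha, line styles, fonts, captions, titles, rotation,
inversion, margins) comes from a JSON document passed as `--config` or to
`vennforge.parse_style`; unknown keys warn, invalid values error naming the
key. See `docs/methods.md` for the full model, the Euler case catalogue and
all defaults.

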