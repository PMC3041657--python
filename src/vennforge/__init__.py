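"""vennforge: highly customizable Venn and Euler diagrams for up to four sets.

The pipeline is sets → region cardinalities → diagram class → layout →
figure.  The convenience function :func:`venn_diagram` runs the whole
pipeline; the individual stages live in :mod:`vennforge.sets`,
:mod:`vennforge.geometry`, :mod:`vennforge.layout` and
:mod:`vennforge.render`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    ConfigError,
    EmptyDiagramError,
    FormatError,
    InfeasibleOverlapError,
    InvalidInputError,
    UnrealizableArrangementError,
    UnsupportedScalingError,
    UnsupportedSizeError,
    VennForgeError,
    WrongClassError,
)
from .geometry import (
    Circle,
    Ellipse,
    ThreeCircleArrangement,
    lens_area,
    place_three_circles,
    radius_from_area,
    region_areas_and_centroids,
    solve_distance,
    transform_point,
    transform_shape,
)
from .layout import (
    DiagramClass,
    Layout,
    attach_labels,
    build_layout,
    check_three_set_scaling,
    classify_diagram,
    layout_euler,
    layout_scaled_two_set,
    layout_venn,
)
from .render import FigureHandle, RenderSpec, build_figure, render_diagram
from .sets import (
    RegionCardinalities,
    SetCollection,
    compute_region_cardinalities,
    generate_random_sets,
    parse_region_counts,
    read_counts_json,
    read_set_lists,
    read_set_table,
    read_sets_json,
    validate_cardinalities,
)
from .style import StyleConfig, parse_style, serialize_style

__version__ = "1.0.0"

__all__ = [
    "venn_diagram",
    "SetCollection", "RegionCardinalities", "compute_region_cardinalities",
    "validate_cardinalities", "generate_random_sets", "parse_region_counts",
    "read_set_lists", "read_set_table", "read_sets_json", "read_counts_json",
    "Circle", "Ellipse", "ThreeCircleArrangement", "radius_from_area",
    "lens_area", "solve_distance", "place_three_circles",
    "region_areas_and_centroids", "transform_point", "transform_shape",
    "DiagramClass", "Layout", "classify_diagram", "build_layout",
    "layout_venn", "layout_scaled_two_set", "layout_euler", "attach_labels",
    "check_three_set_scaling",
    "StyleConfig", "parse_style", "serialize_style",
    "RenderSpec", "FigureHandle", "build_figure", "render_diagram",
    "VennForgeError", "InvalidInputError", "UnsupportedSizeError",
    "EmptyDiagramError", "InfeasibleOverlapError",
    "UnrealizableArrangementError", "UnsupportedScalingError",
    "WrongClassError", "ConfigError", "FormatError",
]


def venn_diagram(
    sets: Mapping[str, Iterable] | None = None,
    counts: Mapping[str, int] | None = None,
    style: Mapping | StyleConfig | None = None,
    out: str | Path | None = None,
    width: int = 3000,
    height: int = 3000,
    dpi: int = 300,
    n_samples: int | None = None,
    seed: int | None = None,
):
    """One-call diagram generation.

    Parameters
    ----------
    sets
        Mapping of set name to elements (1-4 sets), or None.
    counts
        Direct partial-area input: mapping of ``&``-joined set names to
        region counts (used when ``sets`` is None).
    style
        A :class:`StyleConfig`, a JSON-compatible mapping of style keys,
        or None for defaults.
    out
        Output file path; when None an in-memory :class:`FigureHandle`
        is returned instead of writing a file.

    Returns
    -------
    pathlib.Path or FigureHandle
    """
    from .geometry import DEFAULT_SAMPLES, DEFAULT_SEED

    if sets is not None:
        collection = (sets if isinstance(sets, SetCollection)
                      else SetCollection.from_dict(sets))
        card = compute_region_cardinalities(collection)
        card = validate_cardinalities(card.n, card.counts, card.labels)
    elif counts is not None:
        card = (counts if isinstance(counts, RegionCardinalities)
                else parse_region_counts(counts))
    else:
        raise InvalidInputError("either sets or counts must be given")

    if isinstance(style, StyleConfig):
        cfg = style
    else:
        cfg = parse_style(style)
    layout = build_layout(
        card, cfg,
        n_samples=n_samples or DEFAULT_SAMPLES,
        seed=seed or DEFAULT_SEED,
    )
    spec = RenderSpec(path=out, width=width, height=height, dpi=dpi)
    return render_diagram(layout, cfg, spec)
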