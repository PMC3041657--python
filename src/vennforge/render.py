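"""Figure assembly and export.

A labeled :class:`~vennforge.layout.Layout` is drawn with matplotlib (Agg,
no global pyplot state) in a fixed order — shape fills, shape lines, area
labels, leader lines, captions, titles — and either written to a file
(TIFF by default, at the requested pixel dimensions and DPI) or returned
as an in-memory :class:`FigureHandle` for further manipulation by the
host plotting environment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import matplotlib.patches as mpatches
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.backends.backend_svg import FigureCanvasSVG
from matplotlib.figure import Figure

from .errors import FormatError, VennForgeError
from .geometry import Circle, Ellipse
from .layout import Layout
from .style import StyleConfig

#: supported output formats and the matplotlib/Pillow format names
FORMATS = {
    "tiff": "tiff",
    "tif": "tiff",
    "png": "png",
    "jpeg": "jpg",
    "jpg": "jpg",
    "bmp": "bmp",
    "svg": "svg",
}

_LINESTYLES = {"solid": "-", "dashed": "--", "dotted": ":", "dashdot": "-."}

#: fixed hash salt so SVG output is byte-identical across runs
_SVG_HASHSALT = "vennforge"


@dataclass
class RenderSpec:
    """Output contract: where and how large to draw."""

    path: str | Path | None = None
    format: str | None = None  # inferred from the path extension when absent
    width: int = 3000
    height: int = 3000
    dpi: int = 300
    tiff_compression: str = "tiff_lzw"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.dpi <= 0:
            raise VennForgeError("width, height and dpi must be positive")
        fmt = self.format
        if fmt is None and self.path is not None:
            fmt = Path(self.path).suffix.lstrip(".").lower() or "tiff"
        if fmt is None:
            fmt = "tiff"
        fmt = fmt.lower()
        if fmt not in FORMATS:
            raise FormatError(
                f"unsupported output format {fmt!r}; choose from "
                f"{sorted(set(FORMATS.values()))}"
            )
        self.format = FORMATS[fmt]


class FigureHandle:
    """Opaque in-memory figure returned when no output path is given.

    Exposes the underlying matplotlib figure plus a ``save`` method so the
    caller can post-process or embed the drawing."""

    def __init__(self, figure: Figure, spec: RenderSpec):
        self.figure = figure
        self.spec = spec

    def save(self, path: str | Path, format: str | None = None) -> Path:
        spec = RenderSpec(path=path, format=format, width=self.spec.width,
                          height=self.spec.height, dpi=self.spec.dpi,
                          tiff_compression=self.spec.tiff_compression)
        _write(self.figure, spec)
        return Path(path)

    def svg_bytes(self) -> bytes:
        """Serialize to SVG in memory (deterministic byte stream)."""
        buf = io.BytesIO()
        with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
            FigureCanvasSVG(self.figure)
            self.figure.savefig(buf, format="svg", metadata={"Date": None})
        return buf.getvalue()


def _font_kwargs(face: str) -> dict:
    return {
        "fontweight": "bold" if "bold" in face else "normal",
        "fontstyle": "italic" if "italic" in face else "normal",
    }


def _patch(shape, **kwargs) -> mpatches.Patch:
    if isinstance(shape, Circle):
        return mpatches.Circle(shape.center, shape.radius, **kwargs)
    if isinstance(shape, Ellipse):
        return mpatches.Ellipse(shape.center, 2 * shape.semi_major,
                                2 * shape.semi_minor, angle=shape.angle, **kwargs)
    raise VennForgeError(f"cannot draw shape {shape!r}")


def build_figure(layout: Layout, style: StyleConfig | None = None,
                 spec: RenderSpec | None = None) -> Figure:
    """Draw a labeled layout onto a fresh matplotlib figure."""
    style = style or StyleConfig()
    spec = spec or RenderSpec()
    n = layout.n

    fig = Figure(figsize=(spec.width / spec.dpi, spec.height / spec.dpi),
                 dpi=spec.dpi)
    FigureCanvasAgg(fig)
    fig.patch.set_facecolor(style.background)
    ax = fig.add_axes((0.0, 0.0, 1.0, 1.0))
    ax.set_xlim(0.0, 1.0)
    ax.set_ylim(0.0, 1.0)
    ax.set_aspect("equal")
    ax.set_axis_off()

    canvas_pts = spec.height / spec.dpi * 72.0  # canvas height in points
    label_size = style.label_font_size or 0.025 * canvas_pts
    caption_size = style.caption_font_size or 0.025 * canvas_pts
    title_size = style.title_font_size or 0.035 * canvas_pts

    fills = style.fills(n)
    alphas = style.alphas(n)
    line_styles = style.line_styles(n)
    line_widths = style.line_widths(n)
    edge_colors = style.edge_colors(n)

    # 1. fills
    for i, shape in enumerate(layout.shapes):
        ax.add_patch(_patch(shape, facecolor=fills[i], alpha=alphas[i],
                            edgecolor="none", linewidth=0, zorder=1,
                            gid=f"fill-{i}"))
    # 2. shape lines
    for i, shape in enumerate(layout.shapes):
        if line_styles[i] == "blank":
            continue
        ax.add_patch(_patch(shape, facecolor="none",
                            edgecolor=edge_colors[i],
                            linestyle=_LINESTYLES[line_styles[i]],
                            linewidth=line_widths[i], zorder=2,
                            gid=f"line-{i}"))
    # 3. area labels
    for key in sorted(layout.region_labels):
        x, y = layout.region_anchors[key]
        ax.text(x, y, layout.region_labels[key], ha="center", va="center",
                fontsize=label_size, color=style.label_color,
                fontfamily=style.label_font_family,
                **_font_kwargs(style.label_font_face),
                zorder=3, gid="area-label")
    # 4. leader lines
    for (x0, y0), (x1, y1) in layout.leader_lines:
        ax.plot([x0, x1], [y0, y1], color=style.label_color, linewidth=1.0,
                zorder=4, gid="leader-line")
    # 5. captions
    for label, (x, y, ha) in layout.caption_anchors.items():
        text = style.captions.get(label, label)
        ax.text(x, y, text, ha=ha, va="center", fontsize=caption_size,
                color=style.caption_color, fontfamily=style.caption_font_family,
                **_font_kwargs(style.caption_font_face),
                zorder=5, gid="caption-label")
    # 6. titles
    if style.main_title:
        fig.text(style.title_position[0], style.title_position[1],
                 style.main_title, ha="center", va="top", fontsize=title_size,
                 color=style.title_color, gid="main-title")
    if style.sub_title:
        fig.text(style.title_position[0], style.title_position[1] - 0.04,
                 style.sub_title, ha="center", va="top",
                 fontsize=0.8 * title_size, color=style.title_color,
                 gid="sub-title")
    return fig


def _write(fig: Figure, spec: RenderSpec) -> None:
    path = Path(spec.path)
    save_kwargs: dict = {"dpi": spec.dpi, "facecolor": fig.get_facecolor()}
    if spec.format == "tiff":
        save_kwargs["pil_kwargs"] = {"compression": spec.tiff_compression}
    if spec.format == "svg":
        save_kwargs["metadata"] = {"Date": None}
        with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
            fig.savefig(path, format="svg", **save_kwargs)
        return
    if spec.format == "bmp":
        # matplotlib has no BMP writer; rasterize to PNG and convert
        from PIL import Image

        buf = io.BytesIO()
        fig.savefig(buf, format="png", **save_kwargs)
        buf.seek(0)
        with Image.open(buf) as im:
            im.convert("RGB").save(path, format="BMP",
                                   dpi=(spec.dpi, spec.dpi))
        return
    try:
        fig.savefig(path, format=spec.format, **save_kwargs)
    except OSError as exc:
        raise VennForgeError(f"cannot write {path}: {exc}") from exc


def render_diagram(layout: Layout, style: StyleConfig | None = None,
                   spec: RenderSpec | None = None) -> Path | FigureHandle:
    """Render a labeled layout.

    With an output path, writes the file at the requested pixel dimensions
    and DPI and returns the path; without one, returns a
    :class:`FigureHandle` and writes nothing."""
    style = style or StyleConfig()
    spec = spec or RenderSpec()
    fig = build_figure(layout, style, spec)
    if spec.path is None:
        return FigureHandle(fig, spec)
    _write(fig, spec)
    return Path(spec.path)
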