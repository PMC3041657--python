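"""The graphical parameter surface.

Four major groups are exposed — shape-fill, shape-line, labels and titles —
plus diagram-level options (margin, rotation, inversion, Euler recognition,
area-proportional scaling).  Defaults are chosen to produce a sensible
publication-ready figure with no configuration at all; every field can be
overridden from a JSON document via :func:`parse_style`.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from matplotlib.colors import is_color_like

from .errors import ConfigError

#: default per-set fill palette (cycled for fewer sets)
DEFAULT_FILLS = ("dodgerblue", "goldenrod", "mediumseagreen", "orchid")

LINE_STYLES = ("solid", "dashed", "dotted", "dashdot", "blank")
CAPTION_MODES = ("default", "text", "explicit")
FONT_FACES = ("plain", "bold", "italic", "bold-italic")


def _per_set(value, n: int) -> list:
    """Broadcast a scalar or cycle a sequence to one value per set."""
    if isinstance(value, (list, tuple)):
        return [value[i % len(value)] for i in range(n)]
    return [value] * n


@dataclass
class StyleConfig:
    """Validated style settings for one diagram."""

    # shape-fill
    fill_colors: Sequence[str] = DEFAULT_FILLS
    fill_alpha: float | Sequence[float] = 0.5
    # shape-line
    line_style: str | Sequence[str] = "solid"
    line_width: float | Sequence[float] = 2.0
    line_colors: str | Sequence[str] = "black"
    # area labels (the numerals inside regions)
    label_font_family: str = "sans-serif"
    label_font_face: str = "plain"
    label_font_size: float | None = None  # points; None -> 2.5% of canvas height
    label_color: str = "black"
    # caption labels (set names)
    captions: Mapping[str, str] = field(default_factory=dict)
    caption_mode: str = "default"
    caption_positions: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    caption_justification: str = "center"
    caption_distance: float = 0.05
    caption_font_family: str = "sans-serif"
    caption_font_face: str = "plain"
    caption_font_size: float | None = None
    caption_color: str = "black"
    # titles
    main_title: str = ""
    sub_title: str = ""
    title_font_size: float | None = None
    title_color: str = "black"
    title_position: tuple[float, float] = (0.5, 0.97)
    # diagram-level
    margin: float = 0.05
    rotation: float = 0.0
    invert: bool = False
    euler: bool = True
    scaled: bool = False
    # layout fine-tuning
    small_region_threshold: float = 0.04  # canvas units, lens width triggering a leader line
    leader_offset: float = 0.05           # label height above the upper shape boundary
    tangency_gap: float = 0.01            # visible gap at degenerate scaled tangency
    min_radius: float = 0.02              # stand-in radius for an empty set in Venn mode
    background: str = "white"

    def fills(self, n: int) -> list[str]:
        return _per_set(list(self.fill_colors), n)

    def alphas(self, n: int) -> list[float]:
        return _per_set(self.fill_alpha, n)

    def line_styles(self, n: int) -> list[str]:
        return _per_set(self.line_style, n)

    def line_widths(self, n: int) -> list[float]:
        return _per_set(self.line_width, n)

    def edge_colors(self, n: int) -> list[str]:
        return _per_set(self.line_colors, n)


_FIELDS = {f.name: f for f in dataclasses.fields(StyleConfig)}

_COLOR_KEYS = {"label_color", "caption_color", "title_color", "background"}
_FRACTION_KEYS = {"margin", "caption_distance", "small_region_threshold",
                  "leader_offset", "tangency_gap", "min_radius"}
_SIZE_KEYS = {"label_font_size", "caption_font_size", "title_font_size"}


def _check_color(key: str, value: Any) -> None:
    if not (isinstance(value, str) and is_color_like(value)):
        raise ConfigError(f"invalid value for {key!r}: {value!r} is not a known color")


def _validate(key: str, value: Any) -> Any:
    if key == "fill_colors" or key == "line_colors":
        values = value if isinstance(value, (list, tuple)) else [value]
        for v in values:
            _check_color(key, v)
        return value
    if key in _COLOR_KEYS:
        _check_color(key, value)
        return value
    if key == "fill_alpha":
        values = value if isinstance(value, (list, tuple)) else [value]
        for v in values:
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ConfigError(f"invalid value for 'fill_alpha': {v!r} not in [0, 1]")
        return value
    if key == "line_style":
        values = value if isinstance(value, (list, tuple)) else [value]
        for v in values:
            if v not in LINE_STYLES:
                raise ConfigError(
                    f"invalid value for 'line_style': {v!r}; choose from {LINE_STYLES}"
                )
        return value
    if key == "line_width":
        values = value if isinstance(value, (list, tuple)) else [value]
        for v in values:
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"invalid value for 'line_width': {v!r} must be > 0")
        return value
    if key in _SIZE_KEYS:
        if value is not None and not (isinstance(value, (int, float)) and value > 0):
            raise ConfigError(f"invalid value for {key!r}: {value!r} must be > 0")
        return value
    if key in _FRACTION_KEYS:
        if not (isinstance(value, (int, float)) and 0.0 <= value < 0.5):
            raise ConfigError(f"invalid value for {key!r}: {value!r} not in [0, 0.5)")
        return value
    if key == "caption_mode":
        if value not in CAPTION_MODES:
            raise ConfigError(
                f"invalid value for 'caption_mode': {value!r}; choose from {CAPTION_MODES}"
            )
        return value
    if key in {"label_font_face", "caption_font_face"}:
        if value not in FONT_FACES:
            raise ConfigError(
                f"invalid value for {key!r}: {value!r}; choose from {FONT_FACES}"
            )
        return value
    if key == "rotation":
        if not isinstance(value, (int, float)):
            raise ConfigError(f"invalid value for 'rotation': {value!r} must be a number")
        return float(value) % 360.0
    if key in {"invert", "euler", "scaled"}:
        if not isinstance(value, bool):
            raise ConfigError(f"invalid value for {key!r}: {value!r} must be a boolean")
        return value
    if key in {"captions", "caption_positions"}:
        if not isinstance(value, dict):
            raise ConfigError(f"invalid value for {key!r}: expected an object")
        if key == "caption_positions":
            return {k: tuple(v) for k, v in value.items()}
        return value
    if key == "title_position":
        try:
            x, y = value
            return (float(x), float(y))
        except (TypeError, ValueError):
            raise ConfigError(f"invalid value for 'title_position': {value!r}") from None
    return value


def parse_style(document: Mapping[str, Any] | str | Path | None) -> StyleConfig:
    """Build a :class:`StyleConfig` from a JSON document (mapping, JSON
    string, file path, or None for all defaults).

    Unknown keys produce a warning and are ignored; invalid values raise a
    :class:`~vennforge.errors.ConfigError` naming the key.
    """
    if document is None:
        return StyleConfig()
    if isinstance(document, (str, Path)):
        p = Path(document)
        text = p.read_text(encoding="utf-8") if p.exists() else str(document)
        document = json.loads(text)
        if not isinstance(document, dict):
            raise ConfigError("style document must be a JSON object")
    kwargs: dict[str, Any] = {}
    for key, value in document.items():
        if key not in _FIELDS:
            warnings.warn(f"unknown style key {key!r} ignored", stacklevel=2)
            continue
        kwargs[key] = _validate(key, value)
    return StyleConfig(**kwargs)


def serialize_style(style: StyleConfig) -> dict[str, Any]:
    """Dump a config to a plain JSON-compatible dict; round-trips through
    :func:`parse_style`."""
    out: dict[str, Any] = {}
    for f in dataclasses.fields(StyleConfig):
        value = getattr(style, f.name)
        if isinstance(value, tuple):
            value = list(value)
        if isinstance(value, dict):
            value = {k: (list(v) if isinstance(v, tuple) else v) for k, v in value.items()}
        out[f.name] = value
    return out
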