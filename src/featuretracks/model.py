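"""Domain types for position-based protein feature drawings.

A *feature* is a labeled interval (or single residue) on a protein
sequence, with 1-based inclusive coordinates — the UniProt and GFF3
convention, so nothing is shifted on read. All computation lives in
:mod:`featuretracks.layout`; this module only defines the value types
and validates their invariants at construction time.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from .errors import ConfigError, CoordinateError, VocabularyError, WindowError

_HEX_COLOR = re.compile(r"^#[0-9A-Fa-f]{6}$")
_NAMED_COLOR = re.compile(r"^[A-Za-z]+$")


def is_valid_color(value: str) -> bool:
    """Accept CSS named colors (pattern check only) and #RRGGBB hex."""
    return bool(_HEX_COLOR.match(value) or _NAMED_COLOR.match(value))


class GlyphKind(str, Enum):
    """Closed vocabulary of drawable shapes.

    Regions are rectangles or bridges (inverted-U, e.g. disulfide bonds);
    single-residue sites use point glyphs keyed to the feature type:
    circles for metal binding, diamonds for active sites, waves for
    lipidation, hexagons for glycosylation, triangles for other modified
    residues, and a plain vertical line otherwise.
    """

    RECT = "rect"
    CIRCLE = "circle"
    DIAMOND = "diamond"
    TRIANGLE = "triangle"
    HEXAGON = "hexagon"
    WAVE = "wave"
    BRIDGE = "bridge"
    LINE = "line"

    @classmethod
    def parse(cls, value: str) -> "GlyphKind":
        try:
            return cls(value)
        except ValueError:
            raise VocabularyError(
                f"unknown glyph kind {value!r}; expected one of "
                + ", ".join(k.value for k in cls)
            ) from None


#: Glyphs anchored at a point (cx, cy, r) rather than a box.
POINT_GLYPHS = frozenset(
    {GlyphKind.CIRCLE, GlyphKind.DIAMOND, GlyphKind.TRIANGLE,
     GlyphKind.HEXAGON, GlyphKind.WAVE, GlyphKind.LINE}
)


class RenderStyle(str, Enum):
    """The three layout styles: minimum non-overlapping tracks,
    one row per feature type, or everything centered on the sequence line."""

    NON_OVERLAPPING = "nonOverlapping"
    ROWS = "rows"
    CENTERED = "centered"

    @classmethod
    def parse(cls, value: str) -> "RenderStyle":
        try:
            return cls(value)
        except ValueError:
            raise VocabularyError(
                f"unknown render style {value!r}; expected one of "
                + ", ".join(k.value for k in cls)
            ) from None


@dataclass(frozen=True)
class Feature:
    """One annotation on the sequence, 1-based inclusive coordinates.

    ``start == end`` is legal and marks a single-residue site;
    ``start > end`` is rejected (no wrap-around). Colors are stored
    verbatim (named or #RRGGBB) and validated by pattern only.
    """

    feature_id: str
    start: int
    end: int
    type_label: str = ""
    type_code: str = ""
    type_category: str = ""
    feature_label: str = ""
    evidence_text: str = ""
    evidence_code: str = ""
    color: Optional[str] = None
    shape_hint: Optional[GlyphKind] = None

    def __post_init__(self):
        if not self.feature_id:
            raise CoordinateError("feature_id must be non-empty")
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise CoordinateError(
                f"feature {self.feature_id!r}: coordinates must be integers"
            )
        if self.start < 1:
            raise CoordinateError(
                f"feature {self.feature_id!r}: start {self.start} < 1"
            )
        if self.start > self.end:
            raise CoordinateError(
                f"feature {self.feature_id!r}: start {self.start} > end {self.end}"
            )
        if self.color is not None and not is_valid_color(self.color):
            raise CoordinateError(
                f"feature {self.feature_id!r}: invalid color {self.color!r}"
            )
        if self.shape_hint is not None and not isinstance(self.shape_hint, GlyphKind):
            raise VocabularyError(
                f"feature {self.feature_id!r}: shape_hint must be a GlyphKind"
            )

    @property
    def is_site(self) -> bool:
        return self.start == self.end


def validate_feature(
    feature_id,
    start,
    end,
    type_label="",
    type_code="",
    type_category="",
    feature_label="",
    evidence_text="",
    evidence_code="",
    color=None,
    shape_hint=None,
) -> Feature:
    """Validating constructor accepting loosely-typed raw fields.

    Coerces numeric strings, parses ``shape_hint`` from its string form,
    and raises :class:`CoordinateError` / :class:`VocabularyError` on
    invalid input. Never returns a partially-valid value.
    """
    try:
        start = int(start)
        end = int(end)
    except (TypeError, ValueError):
        raise CoordinateError(
            f"feature {feature_id!r}: non-numeric coordinates "
            f"({start!r}, {end!r})"
        ) from None
    if isinstance(shape_hint, str):
        shape_hint = GlyphKind.parse(shape_hint)
    return Feature(
        feature_id=str(feature_id),
        start=start,
        end=end,
        type_label=str(type_label or ""),
        type_code=str(type_code or ""),
        type_category=str(type_category or ""),
        feature_label=str(feature_label or ""),
        evidence_text=str(evidence_text or ""),
        evidence_code=str(evidence_code or ""),
        color=color,
        shape_hint=shape_hint,
    )


@dataclass(frozen=True)
class LayoutConfig:
    """Canvas geometry, residue window, and style for one drawing.

    Pixel defaults mirror a typical 700 px wide view: 20 px margins,
    ruler ticks every 50 px, 10 px tracks separated by a 2 px gap. The
    centered style draws taller glyphs (40 px) on its own sequence line.
    ``requested_start``/``requested_stop`` select the visible residue
    window; ``None`` stop means the full sequence.
    """

    sequence_length: int
    requested_start: int = 1
    requested_stop: Optional[int] = None
    size_x: int = 700
    left_margin: int = 20
    right_margin: int = 20
    pixels_division: int = 50
    ruler_y: int = 20
    above_ruler: int = 10
    below_ruler: int = 30
    sequence_line_y: int = 54
    centered_sequence_line_y: int = 95
    track_height: int = 10
    centered_track_height: int = 40
    track_gap: int = 2
    style: RenderStyle = RenderStyle.NON_OVERLAPPING
    show_vertical_grid: bool = False
    show_horizontal_grid: bool = False

    def __post_init__(self):
        if isinstance(self.style, str):
            object.__setattr__(self, "style", RenderStyle.parse(self.style))
        if self.requested_stop is None:
            object.__setattr__(self, "requested_stop", self.sequence_length)
        if self.size_x <= self.left_margin + self.right_margin:
            raise ConfigError(
                f"size_x {self.size_x} must exceed margins "
                f"{self.left_margin}+{self.right_margin}"
            )
        if not (1 <= self.requested_start <= self.requested_stop
                <= self.sequence_length):
            raise ConfigError(
                f"window {self.requested_start}..{self.requested_stop} invalid "
                f"for sequence length {self.sequence_length}"
            )
        if self.pixels_division <= 0:
            raise ConfigError("pixels_division must be > 0")
        if self.track_height <= 0 or self.centered_track_height <= 0:
            raise ConfigError("track heights must be > 0")

    @property
    def window_length(self) -> int:
        return self.requested_stop - self.requested_start + 1

    def track_height_for(self, style: RenderStyle) -> int:
        return (self.centered_track_height if style is RenderStyle.CENTERED
                else self.track_height)

    def sequence_line_y_for(self, style: RenderStyle) -> int:
        return (self.centered_sequence_line_y if style is RenderStyle.CENTERED
                else self.sequence_line_y)

    def with_window(self, start: int, stop: int) -> "LayoutConfig":
        if not (1 <= start <= stop <= self.sequence_length):
            raise WindowError(
                f"window {start}..{stop} invalid for sequence length "
                f"{self.sequence_length}"
            )
        return replace(self, requested_start=start, requested_stop=stop)

    def with_style(self, style) -> "LayoutConfig":
        if isinstance(style, str):
            style = RenderStyle.parse(style)
        return replace(self, style=style)


@dataclass(frozen=True)
class DerivedGeometry:
    """Quantities computed from a LayoutConfig: the usable horizontal
    extent, the residue-to-pixel scale factor (kept at full float
    precision), and — once features are placed — the total canvas height."""

    ruler_length: int
    unitsize: float
    size_y: Optional[int] = None


@dataclass(frozen=True)
class PlacedFeature:
    """A Feature with fully resolved pixel geometry for one style.

    ``style_blocks`` carries the (heightOrRadius, y) pair for every style
    so a written document can switch styles without re-layout.
    """

    feature: Feature
    glyph: GlyphKind
    x: int
    y: int
    width: int
    height: int
    cx: int
    cy: int
    r: int
    track_index: int
    fill: str
    stroke: str
    fill_opacity: float
    stroke_width: int
    tooltip: str
    clipped_left: bool = False
    clipped_right: bool = False
    style_blocks: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RulerTick:
    x_px: int
    label: int


@dataclass(frozen=True)
class LegendEntry:
    type_label: str
    type_category: str
    color: str
    glyph: GlyphKind


@dataclass
class LayoutDocument:
    """A complete resolved drawing: placed features (sorted by track then
    x), ruler ticks, legend, and the configuration that produced them.
    Self-sufficient for rendering — the renderer does no layout math."""

    segment_id: str
    config: LayoutConfig
    derived: DerivedGeometry
    placed: list
    ticks: list
    legend: list
    extras: dict = field(default_factory=dict)
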