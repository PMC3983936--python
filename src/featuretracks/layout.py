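"""Layout engine: all geometry for the three drawing styles.

This is the component that turns residue coordinates into pixels. The
horizontal mapping is

    x(p) = left_margin + (p - requested_start + 1) * unitsize

with ``unitsize = ruler_length / window_length`` pixels per residue and
half-up rounding applied only at final pixel emission; all intermediate
arithmetic stays at full float precision. Vertical placement depends on
the style: *centered* puts every glyph astride the sequence line,
*nonOverlapping* packs features greedily into the minimum number of
tracks (first-fit on start-sorted intervals, which achieves the maximum
overlap depth), and *rows* gives each feature type its own row ordered
by (category, label).

Everything here is deterministic: identical inputs produce identical
documents, byte for byte once serialized.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import WindowError
from .model import (
    POINT_GLYPHS,
    DerivedGeometry,
    Feature,
    GlyphKind,
    LayoutConfig,
    LayoutDocument,
    LegendEntry,
    PlacedFeature,
    RenderStyle,
    RulerTick,
)

#: Fixed 12-color palette (ColorBrewer Set3) used when a feature carries
#: no explicit color; indexed by a stable hash of the type code.
PALETTE = (
    "#8DD3C7", "#FFFFB3", "#BEBADA", "#FB8072", "#80B1D3", "#FDB462",
    "#B3DE69", "#FCCDE5", "#D9D9D9", "#BC80BD", "#CCEBC5", "#FFED6F",
)

DEFAULT_FILL_OPACITY = 0.5
DEFAULT_STROKE_WIDTH = 1


def round_half_up(value: float) -> int:
    """Round to nearest integer, exact .5 ties away from zero (upward)."""
    return int(math.floor(value + 0.5))


def derive_geometry(config: LayoutConfig) -> DerivedGeometry:
    """Usable horizontal extent and pixels-per-residue scale.

    ``unitsize`` is kept fractional (e.g. 660 px / 96 residues = 6.875);
    rounding it here would accumulate a visible drift across the ruler.
    """
    ruler_length = config.size_x - config.left_margin - config.right_margin
    unitsize = ruler_length / config.window_length
    return DerivedGeometry(ruler_length=ruler_length, unitsize=unitsize)


def position_to_pixel(p: int, config: LayoutConfig,
                      derived: DerivedGeometry) -> int:
    """Map residue ``p`` to its pixel x coordinate.

    Domain is ``requested_start - 1 .. requested_stop``: the window
    origin (start - 1) lands exactly on the left margin and the window
    stop exactly on ``left_margin + ruler_length``.
    """
    if not (config.requested_start - 1 <= p <= config.requested_stop):
        raise WindowError(
            f"position {p} outside window "
            f"{config.requested_start}..{config.requested_stop} "
            "(clip features before mapping)"
        )
    offset = (p - config.requested_start + 1) * derived.unitsize
    return round_half_up(config.left_margin + offset)


def region_width(start: int, end: int, unitsize: float) -> int:
    """Pixel width of the region [start, end]; 0 for a single residue
    (a point glyph is drawn instead of a degenerate rectangle)."""
    return round_half_up((end - start) * unitsize)


def assign_tracks(features: Sequence[Feature]) -> Dict[str, int]:
    """Greedy first-fit interval partitioning into non-overlapping tracks.

    Features are sorted by (start, end, feature_id) and each is placed on
    the lowest-index track whose last feature ends before this one starts
    (closed intervals: sharing a residue counts as overlap). On
    start-sorted input this greedy is optimal — the number of tracks
    equals the maximum overlap depth of the interval set.
    """
    ordered = sorted(features, key=lambda f: (f.start, f.end, f.feature_id))
    track_last_end: List[int] = []
    assignment: Dict[str, int] = {}
    for f in ordered:
        for idx, last_end in enumerate(track_last_end):
            if last_end < f.start:
                track_last_end[idx] = f.end
                assignment[f.feature_id] = idx
                break
        else:
            track_last_end.append(f.end)
            assignment[f.feature_id] = len(track_last_end) - 1
    return assignment


def assign_rows(features: Sequence[Feature]) -> Dict[str, int]:
    """One row per distinct type label, ordered by (category, label)."""
    keys = sorted({(f.type_category, f.type_label) for f in features})
    row_of_label: Dict[str, int] = {}
    for category, label in keys:
        if label not in row_of_label:
            row_of_label[label] = len(row_of_label)
    return {f.feature_id: row_of_label[f.type_label] for f in features}


def default_glyph(type_label: str, type_code: str = "",
                  single_residue: bool = False) -> GlyphKind:
    """Field-convention glyph for a feature type.

    Case-insensitive substring rules on the label (and code): metal
    binding → circle, active site → diamond, lipidation → wave,
    glycosylation → hexagon, modified residue / PTM → triangle,
    disulfide / bridge → bridge. Anything else is a vertical line for a
    single residue and a rectangle for a region.
    """
    text = f"{type_label} {type_code}".lower()
    if "metal" in text:
        return GlyphKind.CIRCLE
    if "active site" in text or "active_site" in text:
        return GlyphKind.DIAMOND
    if "lipid" in text:
        return GlyphKind.WAVE
    if "glycosyl" in text:
        return GlyphKind.HEXAGON
    if "modified residue" in text or "modified_residue" in text or "ptm" in text:
        return GlyphKind.TRIANGLE
    if "disulfid" in text or "bridge" in text:
        return GlyphKind.BRIDGE
    return GlyphKind.LINE if single_residue else GlyphKind.RECT


def assign_color(type_code: str, explicit_color: Optional[str] = None) -> str:
    """Explicit color wins verbatim; otherwise a stable (md5-based) hash
    of the type code indexes the fixed palette, so the same code maps to
    the same color across runs and platforms."""
    if explicit_color:
        return explicit_color
    digest = hashlib.md5(type_code.encode("utf-8")).hexdigest()
    return PALETTE[int(digest, 16) % len(PALETTE)]


def clip_to_window(
    features: Iterable[Feature], config: LayoutConfig
) -> List[Tuple[Feature, bool, bool]]:
    """Drop features wholly outside the window; truncate partial overlaps
    to the window bounds, flagging which edge was cut so the renderer can
    mark the truncation."""
    out = []
    for f in features:
        if f.end < config.requested_start or f.start > config.requested_stop:
            continue
        clip_left = f.start < config.requested_start
        clip_right = f.end > config.requested_stop
        if clip_left or clip_right:
            f = replace(
                f,
                start=max(f.start, config.requested_start),
                end=min(f.end, config.requested_stop),
            )
        out.append((f, clip_left, clip_right))
    return out


def _tooltip(f: Feature) -> str:
    span = str(f.start) if f.is_site else f"{f.start}–{f.end}"
    text = f"{f.feature_label} — {f.type_label} ({span})"
    if f.evidence_text:
        text += f" [{f.evidence_text}]"
    return text


def _style_y(config: LayoutConfig, style: RenderStyle, index: int) -> int:
    th = config.track_height_for(style)
    if style is RenderStyle.CENTERED:
        return round_half_up(config.sequence_line_y_for(style) - th / 2)
    first = config.sequence_line_y_for(style) + config.track_gap
    return first + index * (th + config.track_gap)


def place_features(
    features: Sequence[Feature],
    config: LayoutConfig,
    derived: DerivedGeometry,
    style: Optional[RenderStyle] = None,
    clip_flags: Optional[Dict[str, Tuple[bool, bool]]] = None,
) -> List[PlacedFeature]:
    """Resolve pixel geometry for every feature under ``style``.

    Features must already be clipped to the window. The returned list is
    sorted by (track_index, x). Each PlacedFeature carries per-style
    (heightOrRadius, y) blocks for all three styles so that a serialized
    document supports style switching without re-layout.
    """
    style = style or config.style
    clip_flags = clip_flags or {}
    tracks = assign_tracks(features)
    rows = assign_rows(features)

    def index_for(st: RenderStyle, f: Feature) -> int:
        if st is RenderStyle.NON_OVERLAPPING:
            return tracks[f.feature_id]
        if st is RenderStyle.ROWS:
            return rows[f.feature_id]
        return 0

    x_max = config.left_margin + derived.ruler_length
    placed: List[PlacedFeature] = []
    for f in features:
        glyph = f.shape_hint or default_glyph(
            f.type_label, f.type_code, single_residue=f.is_site
        )
        x = position_to_pixel(f.start, config, derived)
        width = region_width(f.start, f.end, derived.unitsize)
        width = max(0, min(width, x_max - x))  # rounding never spills past the ruler
        th = config.track_height_for(style)
        y = _style_y(config, style, index_for(style, f))
        if glyph in POINT_GLYPHS:
            cy = round_half_up(y + th / 2)
        else:
            cy = y
        color = assign_color(f.type_code, f.color)
        cl, cr = clip_flags.get(f.feature_id, (False, False))
        blocks = {
            st.value: {
                "heightOrRadius": config.track_height_for(st),
                "y": _style_y(config, st, index_for(st, f)),
            }
            for st in RenderStyle
        }
        placed.append(
            PlacedFeature(
                feature=f,
                glyph=glyph,
                x=x,
                y=y,
                width=width,
                height=th,
                cx=x,
                cy=cy,
                r=th,
                track_index=index_for(style, f),
                fill=color,
                stroke=color,
                fill_opacity=DEFAULT_FILL_OPACITY,
                stroke_width=DEFAULT_STROKE_WIDTH,
                tooltip=_tooltip(f),
                clipped_left=cl,
                clipped_right=cr,
                style_blocks=blocks,
            )
        )
    placed.sort(key=lambda p: (p.track_index, p.x, p.feature.feature_id))
    return placed


def compute_ruler(config: LayoutConfig,
                  derived: DerivedGeometry) -> List[RulerTick]:
    """Ticks every ``pixels_division`` px from the left margin, plus a
    terminal tick at the right end of the ruler.

    Labels come from the inverse pixel mapping; the origin is labeled
    ``requested_start``, the terminal tick ``requested_stop``, and
    interior ticks whose label would repeat an earlier one are dropped
    (this happens under heavy zoom, where unitsize exceeds the division).
    """
    lm = config.left_margin
    end_x = lm + derived.ruler_length
    ticks: List[RulerTick] = []
    seen = set()
    k = 0
    while lm + k * config.pixels_division <= end_x:
        x = lm + k * config.pixels_division
        if k == 0:
            label = config.requested_start
        else:
            label = (round_half_up((x - lm) / derived.unitsize)
                     + config.requested_start - 1)
            label = min(max(label, config.requested_start),
                        config.requested_stop)
        if k == 0:
            ticks.append(RulerTick(x_px=x, label=label))
            seen.add(label)
        elif x < end_x and label < config.requested_stop and label not in seen:
            ticks.append(RulerTick(x_px=x, label=label))
            seen.add(label)
        k += 1
    ticks.append(RulerTick(x_px=end_x, label=config.requested_stop))
    return ticks


def build_legend(placed: Sequence[PlacedFeature]) -> List[LegendEntry]:
    """One entry per distinct (label, color, glyph), ordered by
    (category, label)."""
    entries = {}
    for p in placed:
        key = (p.feature.type_label, p.fill, p.glyph)
        if key not in entries:
            entries[key] = LegendEntry(
                type_label=p.feature.type_label,
                type_category=p.feature.type_category,
                color=p.fill,
                glyph=p.glyph,
            )
    return sorted(
        entries.values(), key=lambda e: (e.type_category, e.type_label)
    )


LEGEND_LINE_HEIGHT = 20
LEGEND_PADDING = 10


def legend_height(entries: Sequence[LegendEntry]) -> int:
    if not entries:
        return 0
    return LEGEND_PADDING + LEGEND_LINE_HEIGHT * len(entries)


def build_layout(segment_id: str, features: Sequence[Feature],
                 config: LayoutConfig) -> LayoutDocument:
    """Compose the full pipeline: derive geometry, clip to the window,
    assign tracks/rows, place glyphs, compute ruler and legend, and
    derive the canvas height (deepest glyph bottom + below-ruler space +
    legend height)."""
    derived = derive_geometry(config)
    clipped = clip_to_window(features, config)
    visible = [f for f, _, _ in clipped]
    flags = {f.feature_id: (cl, cr) for f, cl, cr in clipped}
    placed = place_features(visible, config, derived, config.style, flags)
    ticks = compute_ruler(config, derived)
    legend = build_legend(placed)

    bottom = config.sequence_line_y_for(config.style)
    for p in placed:
        glyph_bottom = p.cy + p.r if p.glyph in POINT_GLYPHS else p.y + p.height
        bottom = max(bottom, glyph_bottom)
    size_y = bottom + config.below_ruler + legend_height(legend)
    derived = replace(derived, size_y=size_y)

    return LayoutDocument(
        segment_id=segment_id,
        config=config,
        derived=derived,
        placed=placed,
        ticks=ticks,
        legend=legend,
    )


def zoom(features: Sequence[Feature], config: LayoutConfig,
         new_start: int, new_stop: int,
         segment_id: str = "") -> LayoutDocument:
    """Re-layout the same features under a narrower (or wider) residue
    window. Features wholly outside the window are dropped; partial
    overlaps are clipped and flagged. Zooming to the current window is a
    no-op, and unitsize grows as the window shrinks."""
    new_config = config.with_window(new_start, new_stop)
    return build_layout(segment_id, features, new_config)
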