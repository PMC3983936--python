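"""SVG renderer for resolved layout documents.

The renderer is deliberately dumb: it performs zero layout math and
simply draws what a :class:`~featuretracks.model.LayoutDocument` says —
glyph outlines, the ruler with its ticks, the sequence line, optional
grid lines, and the legend. Tooltips become SVG ``<title>`` children
(hover text in standard viewers). Output is byte-deterministic for equal
documents. PNG export is optional at runtime: if no raster backend is
importable, :func:`export_png` raises a capability error instead of
crashing the pipeline.
"""
from __future__ import annotations

import math
import re
import xml.etree.ElementTree as ET
from typing import Optional

from .errors import CapabilityError, GeometryError
from .model import POINT_GLYPHS, GlyphKind, LayoutDocument, RenderStyle

SVG_NS = "http://www.w3.org/2000/svg"


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def glyph_outline(kind: GlyphKind, cx=None, cy=None, r=None,
                  x=None, y=None, width=None, height=None) -> dict:
    """Geometric outline of one glyph as an SVG-element description.

    Returns a dict with an ``element`` key (rect, circle, polygon,
    polyline, path or line) plus the element's geometry; polygon-like
    glyphs expose a ``points`` list of (x, y) vertex pairs. Raises
    :class:`GeometryError` when the fields required by ``kind`` are
    missing.
    """
    def need(**fields):
        absent = [name for name, val in fields.items() if val is None]
        if absent:
            raise GeometryError(
                f"glyph {kind.value!r} requires {', '.join(absent)}"
            )

    if kind is GlyphKind.RECT:
        need(x=x, y=y, width=width, height=height)
        return {"element": "rect", "x": x, "y": y,
                "width": max(width, 1), "height": height}
    if kind is GlyphKind.CIRCLE:
        need(cx=cx, cy=cy, r=r)
        return {"element": "circle", "cx": cx, "cy": cy, "r": r}
    if kind is GlyphKind.DIAMOND:
        need(cx=cx, cy=cy, r=r)
        return {"element": "polygon",
                "points": [(cx, cy - r), (cx + r, cy),
                           (cx, cy + r), (cx - r, cy)]}
    if kind is GlyphKind.TRIANGLE:
        need(cx=cx, cy=cy, r=r)
        return {"element": "polygon",
                "points": [(cx, cy - r), (cx + r, cy + r), (cx - r, cy + r)]}
    if kind is GlyphKind.HEXAGON:
        need(cx=cx, cy=cy, r=r)
        points = [
            (cx + r * math.cos(math.radians(60 * k)),
             cy + r * math.sin(math.radians(60 * k)))
            for k in range(6)
        ]
        return {"element": "polygon", "points": points}
    if kind is GlyphKind.WAVE:
        # crest then trough: two joined semicircular arcs spanning 2r
        need(cx=cx, cy=cy, r=r)
        half = r / 2
        d = (f"M {_fmt(cx - r)},{_fmt(cy)} "
             f"A {_fmt(half)},{_fmt(half)} 0 0 1 {_fmt(cx)},{_fmt(cy)} "
             f"A {_fmt(half)},{_fmt(half)} 0 0 0 {_fmt(cx + r)},{_fmt(cy)}")
        return {"element": "path", "d": d}
    if kind is GlyphKind.BRIDGE:
        # inverted U connecting two residues above the track
        need(x=x, y=y, width=width, height=height)
        return {"element": "polyline",
                "points": [(x, y + height), (x, y),
                           (x + width, y), (x + width, y + height)]}
    if kind is GlyphKind.LINE:
        need(cx=cx, cy=cy, r=r)
        return {"element": "line",
                "x1": cx, "y1": cy - r, "x2": cx, "y2": cy + r}
    raise GeometryError(f"unknown glyph kind {kind!r}")


def _outline_element(outline: dict) -> ET.Element:
    name = outline["element"]
    attrs = {}
    if name in ("polygon", "polyline"):
        attrs["points"] = " ".join(
            f"{_fmt(px)},{_fmt(py)}" for px, py in outline["points"]
        )
    else:
        for key, val in outline.items():
            if key != "element":
                attrs[key] = _fmt(val)
    return ET.Element(name, attrs)


def _safe_id(feature_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", feature_id)


def render_svg(doc: LayoutDocument,
               highlight_id: Optional[str] = None) -> str:
    """Render a layout document to SVG 1.1 text.

    One ``<g class="feature">`` per placed feature, carrying fill,
    stroke, opacity and a ``<title>`` tooltip; stable element ids derive
    from the feature id. ``highlight_id`` draws one feature with a
    thickened stroke — the static stand-in for interactive selection.
    Clipped edges are marked with a short dashed line.
    """
    cfg = doc.config
    size_y = doc.derived.size_y or (
        cfg.sequence_line_y_for(cfg.style) + cfg.below_ruler
    )
    lm = cfg.left_margin
    ruler_end = lm + doc.derived.ruler_length

    svg = ET.Element(
        "svg",
        {
            "xmlns": SVG_NS,
            "version": "1.1",
            "width": str(cfg.size_x),
            "height": str(size_y),
            "viewBox": f"0 0 {cfg.size_x} {size_y}",
        },
    )

    if cfg.show_vertical_grid:
        grid = ET.SubElement(svg, "g", {"class": "grid-vertical",
                                        "stroke": "#DDDDDD",
                                        "stroke-width": "1"})
        for tick in doc.ticks:
            ET.SubElement(grid, "line", {
                "x1": str(tick.x_px), "y1": str(cfg.ruler_y),
                "x2": str(tick.x_px), "y2": str(size_y - cfg.below_ruler),
            })
    if cfg.show_horizontal_grid:
        grid = ET.SubElement(svg, "g", {"class": "grid-horizontal",
                                        "stroke": "#DDDDDD",
                                        "stroke-width": "1"})
        th = cfg.track_height_for(cfg.style)
        y = cfg.sequence_line_y_for(cfg.style) + cfg.track_gap
        while y < size_y - cfg.below_ruler:
            ET.SubElement(grid, "line", {
                "x1": str(lm), "y1": str(y),
                "x2": str(ruler_end), "y2": str(y),
            })
            y += th + cfg.track_gap

    ruler = ET.SubElement(svg, "g", {"class": "ruler", "stroke": "#333333",
                                     "stroke-width": "1"})
    ET.SubElement(ruler, "line", {
        "x1": str(lm), "y1": str(cfg.ruler_y),
        "x2": str(ruler_end), "y2": str(cfg.ruler_y),
    })
    for tick in doc.ticks:
        ET.SubElement(ruler, "line", {
            "x1": str(tick.x_px), "y1": str(cfg.ruler_y - 3),
            "x2": str(tick.x_px), "y2": str(cfg.ruler_y + 3),
        })
        label = ET.SubElement(ruler, "text", {
            "x": str(tick.x_px), "y": str(cfg.ruler_y - 5),
            "font-size": "9", "text-anchor": "middle",
            "stroke": "none", "fill": "#333333",
        })
        label.text = str(tick.label)

    seq_y = cfg.sequence_line_y_for(cfg.style)
    ET.SubElement(svg, "line", {
        "class": "sequence-line",
        "x1": str(lm), "y1": str(seq_y),
        "x2": str(ruler_end), "y2": str(seq_y),
        "stroke": "#555555", "stroke-width": "1",
    })

    features_g = ET.SubElement(svg, "g", {"class": "features"})
    for p in doc.placed:
        stroke_width = p.stroke_width
        if highlight_id is not None and p.feature.feature_id == highlight_id:
            stroke_width = p.stroke_width * 3
        group = ET.SubElement(features_g, "g", {
            "class": "feature",
            "id": f"feature-{_safe_id(p.feature.feature_id)}",
            "fill": p.fill,
            "stroke": p.stroke,
            "fill-opacity": _fmt(p.fill_opacity),
            "stroke-width": str(stroke_width),
        })
        title = ET.SubElement(group, "title")
        title.text = p.tooltip
        if p.glyph in POINT_GLYPHS:
            outline = glyph_outline(p.glyph, cx=p.cx, cy=p.cy, r=p.r)
        else:
            outline = glyph_outline(p.glyph, x=p.x, y=p.y,
                                    width=p.width, height=p.height)
        shape = _outline_element(outline)
        if p.glyph in (GlyphKind.BRIDGE, GlyphKind.WAVE, GlyphKind.LINE):
            shape.set("fill", "none")
        group.append(shape)
        for clipped, edge_x in ((p.clipped_left, p.x),
                                (p.clipped_right, p.x + p.width)):
            if clipped:
                ET.SubElement(group, "line", {
                    "class": "clipped-edge",
                    "x1": str(edge_x), "y1": str(p.y - 2),
                    "x2": str(edge_x), "y2": str(p.y + p.height + 2),
                    "stroke-dasharray": "2,2",
                })

    if doc.legend:
        legend_g = ET.SubElement(svg, "g", {"class": "legend"})
        y = size_y - 20 * len(doc.legend)
        for entry in doc.legend:
            swatch_outline = (
                glyph_outline(entry.glyph, cx=lm + 6, cy=y + 6, r=6)
                if entry.glyph in POINT_GLYPHS
                else glyph_outline(entry.glyph, x=lm, y=y, width=12, height=12)
            )
            swatch = _outline_element(swatch_outline)
            swatch.set("fill", entry.color)
            swatch.set("stroke", entry.color)
            if entry.glyph in (GlyphKind.BRIDGE, GlyphKind.WAVE,
                               GlyphKind.LINE):
                swatch.set("fill", "none")
            legend_g.append(swatch)
            text = ET.SubElement(legend_g, "text", {
                "x": str(lm + 18), "y": str(y + 11),
                "font-size": "11", "fill": "#333333",
            })
            text.text = (f"{entry.type_label} ({entry.type_category})"
                         if entry.type_category else entry.type_label)
            y += 20

    return ET.tostring(svg, encoding="unicode")


def export_png(svg_text: str, scale: float = 1.0) -> bytes:
    """Rasterize SVG text to PNG via the optional ``cairosvg`` backend.

    Raises :class:`CapabilityError` with a remediation hint when no
    backend is importable — the tool then degrades to SVG-only output.
    """
    try:
        import cairosvg
    except ImportError:
        raise CapabilityError(
            "PNG export needs the optional 'cairosvg' raster backend "
            "(pip install cairosvg); running in SVG-only mode"
        ) from None
    return cairosvg.svg2png(bytestring=svg_text.encode("utf-8"), scale=scale)
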