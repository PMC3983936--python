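"""Readers and writers for the three annotation dialects.

* simple-features JSON: a flat document with ``sequenceId``,
  ``sequenceLength`` and a ``features`` array whose elements use the
  keys ``featureId, featureStart, featureEnd, typeLabel, typeCode,
  featureLabel, typeCategory, evidenceText, evidenceCode, color, type``.
* GFF3 (9-column, single segment per document): standard interchange for
  position-based annotation; coordinates are 1-based inclusive in both
  dialects, so nothing is ever shifted.
* computed-layout JSON: the fully resolved drawing (``featuresArray``,
  ``segment``, ``legend``, ``configuration`` with ``unitsize`` etc.), the
  renderer's sole input. ``write_layout_json`` and ``read_layout_json``
  are exact inverses on valid documents.

Unknown keys in the JSON dialects are ignored with a logged warning, not
an error, for forward compatibility. Feature ids are opaque strings,
case-preserved, never normalized.
"""
from __future__ import annotations

import json
import logging
import urllib.parse
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import MultiSegmentError, ParseError, SchemaError
from .layout import round_half_up
from .model import (
    DerivedGeometry,
    Feature,
    GlyphKind,
    LayoutConfig,
    LayoutDocument,
    LegendEntry,
    PlacedFeature,
    RenderStyle,
    RulerTick,
    validate_feature,
)

logger = logging.getLogger(__name__)

_SIMPLE_KEYS = {
    "featureId", "featureStart", "featureEnd", "typeLabel", "typeCode",
    "featureLabel", "typeCategory", "evidenceText", "evidenceCode",
    "color", "type",
}


# ---------------------------------------------------------------------------
# simple-features dialect

def read_simple_features(text: str) -> Tuple[str, int, List[Feature]]:
    """Parse the simple-features JSON dialect.

    Returns ``(segment_id, sequence_length, features)``. Each array
    element needs numeric ``featureStart``/``featureEnd``; everything
    else is optional (defaults are resolved later by the layout engine,
    not here). The element's ``type`` key is a glyph hint.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"not valid JSON: {exc}") from None
    for key in ("sequenceId", "sequenceLength", "features"):
        if key not in doc:
            raise ParseError(f"simple-features document missing {key!r}")
    segment_id = str(doc["sequenceId"])
    sequence_length = int(doc["sequenceLength"])

    features: List[Feature] = []
    for i, raw in enumerate(doc["features"]):
        if "featureStart" not in raw or "featureEnd" not in raw:
            raise ParseError(
                f"features[{i}]: missing featureStart/featureEnd"
            )
        if not isinstance(raw["featureStart"], (int, float)) or \
           not isinstance(raw["featureEnd"], (int, float)):
            raise ParseError(f"features[{i}]: non-numeric coordinates")
        unknown = set(raw) - _SIMPLE_KEYS
        if unknown:
            logger.warning(
                "features[%d]: ignoring unknown keys %s", i, sorted(unknown)
            )
        features.append(
            validate_feature(
                feature_id=raw.get("featureId") or f"F{i}",
                start=raw["featureStart"],
                end=raw["featureEnd"],
                type_label=raw.get("typeLabel", ""),
                type_code=raw.get("typeCode", ""),
                type_category=raw.get("typeCategory", ""),
                feature_label=raw.get("featureLabel", ""),
                evidence_text=raw.get("evidenceText", ""),
                evidence_code=raw.get("evidenceCode", "").strip(),
                color=raw.get("color"),
                shape_hint=raw.get("type"),
            )
        )
    return segment_id, sequence_length, features


def write_simple_features(segment_id: str, sequence_length: int,
                          features: Sequence[Feature]) -> str:
    """Inverse of :func:`read_simple_features`."""
    out = []
    for f in features:
        el = {
            "featureId": f.feature_id,
            "featureStart": f.start,
            "featureEnd": f.end,
            "typeLabel": f.type_label,
            "typeCode": f.type_code,
            "typeCategory": f.type_category,
            "featureLabel": f.feature_label,
            "evidenceText": f.evidence_text,
            "evidenceCode": f.evidence_code,
        }
        if f.color is not None:
            el["color"] = f.color
        if f.shape_hint is not None:
            el["type"] = f.shape_hint.value
        out.append(el)
    return json.dumps(
        {"sequenceId": segment_id, "sequenceLength": sequence_length,
         "features": out},
        indent=1,
    )


# ---------------------------------------------------------------------------
# GFF3

_GFF_ATTR_MAP = {
    "ID": "feature_id",
    "Note": "feature_label",
    "Ontology_term": "type_code",
    "typeCategory": "type_category",
    "evidenceText": "evidence_text",
    "evidenceCode": "evidence_code",
    "color": "color",
    "shape": "shape_hint",
}


def _gff_unescape(value: str) -> str:
    return urllib.parse.unquote(value)


def _gff_escape(value: str) -> str:
    return urllib.parse.quote(value, safe=" :/()[]'.,-_|")


def read_gff3(text: str) -> Tuple[Optional[str], List[Feature]]:
    """Parse a single-segment GFF3 document.

    Column 1 is the segment id (one per document — a second seqid raises
    :class:`MultiSegmentError`), column 3 the type label, columns 4/5 the
    1-based inclusive coordinates, copied unshifted. ``ID`` becomes the
    feature id and ``Note`` the display label; attributes with no field
    mapping are preserved in ``evidence_text``.
    """
    segment_id: Optional[str] = None
    features: List[Feature] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(
                f"line {lineno}: expected 9 tab-separated columns, "
                f"got {len(cols)}"
            )
        seqid, _source, ftype, start, end = cols[0], cols[1], cols[2], cols[3], cols[4]
        if segment_id is None:
            segment_id = seqid
        elif seqid != segment_id:
            raise MultiSegmentError(
                f"line {lineno}: seqid {seqid!r} differs from {segment_id!r} "
                "(one segment per document)"
            )
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise ParseError(
                f"line {lineno}: non-numeric coordinates {start!r}/{end!r}"
            ) from None
        fields: Dict[str, str] = {"type_label": ftype}
        extra = []
        if cols[8] not in (".", ""):
            for item in cols[8].split(";"):
                if not item:
                    continue
                if "=" not in item:
                    raise ParseError(
                        f"line {lineno}: malformed attribute {item!r}"
                    )
                key, value = item.split("=", 1)
                value = _gff_unescape(value)
                if key in _GFF_ATTR_MAP:
                    fields[_GFF_ATTR_MAP[key]] = value
                else:
                    extra.append(f"{key}={value}")
        if extra and "evidence_text" not in fields:
            fields["evidence_text"] = "; ".join(extra)
        features.append(
            validate_feature(
                feature_id=fields.get("feature_id")
                or f"{seqid}_{ftype}_{start_i}_{end_i}_{lineno}",
                start=start_i,
                end=end_i,
                type_label=fields.get("type_label", ""),
                type_code=fields.get("type_code", ""),
                type_category=fields.get("type_category", ""),
                feature_label=fields.get("feature_label", ""),
                evidence_text=fields.get("evidence_text", ""),
                evidence_code=fields.get("evidence_code", ""),
                color=fields.get("color"),
                shape_hint=fields.get("shape_hint"),
            )
        )
    return segment_id, features


def write_gff3(segment_id: str, features: Sequence[Feature],
               sequence_length: Optional[int] = None) -> str:
    """Inverse of :func:`read_gff3` for the attribute set this package
    maps; emits a ``##sequence-region`` pragma when the length is known."""
    lines = ["##gff-version 3"]
    if sequence_length is not None:
        lines.append(f"##sequence-region {segment_id} 1 {sequence_length}")
    for f in features:
        attrs = [f"ID={_gff_escape(f.feature_id)}"]
        if f.feature_label:
            attrs.append(f"Note={_gff_escape(f.feature_label)}")
        if f.type_code:
            attrs.append(f"Ontology_term={_gff_escape(f.type_code)}")
        if f.type_category:
            attrs.append(f"typeCategory={_gff_escape(f.type_category)}")
        if f.evidence_text:
            attrs.append(f"evidenceText={_gff_escape(f.evidence_text)}")
        if f.evidence_code:
            attrs.append(f"evidenceCode={_gff_escape(f.evidence_code)}")
        if f.color:
            attrs.append(f"color={_gff_escape(f.color)}")
        if f.shape_hint:
            attrs.append(f"shape={f.shape_hint.value}")
        lines.append(
            "\t".join(
                [segment_id, ".", f.type_label or "region", str(f.start),
                 str(f.end), ".", ".", ".", ";".join(attrs)]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# computed-layout dialect

def write_layout_json(doc: LayoutDocument) -> str:
    """Serialize a resolved drawing.

    All pixel fields are integers except ``unitsize``, which stays at
    full float precision. Each feature entry carries the per-style
    ``nonOverlappingStyle``/``centeredStyle``/``rowsStyle`` blocks plus
    flat geometry for the active style, so a consumer can re-style the
    document without any layout math.
    """
    cfg = doc.config
    features_array = []
    for p in doc.placed:
        f = p.feature
        el = {
            "nonOverlappingStyle": p.style_blocks.get("nonOverlapping", {}),
            "centeredStyle": p.style_blocks.get("centered", {}),
            "rowsStyle": p.style_blocks.get("rows", {}),
            "featureLabel": f.feature_label,
            "evidenceText": f.evidence_text,
            "evidenceCode": f.evidence_code,
            "typeCode": f.type_code,
            "typeCategory": f.type_category,
            "featureId": f.feature_id,
            "featureTypeLabel": f.type_label,
            "featureStart": f.start,
            "featureEnd": f.end,
            "type": p.glyph.value,
            "fillOpacity": p.fill_opacity,
            "stroke": p.stroke,
            "height": p.height,
            "r": p.r,
            "y": p.y,
            "x": p.x,
            "cy": p.cy,
            "cx": p.cx,
            "strokeWidth": p.stroke_width,
            "fill": p.fill,
            "width": p.width,
            "tooltip": p.tooltip,
            "trackIndex": p.track_index,
            "clippedLeft": p.clipped_left,
            "clippedRight": p.clipped_right,
        }
        if f.color is not None:
            el["color"] = f.color
        if f.shape_hint is not None:
            el["shapeHint"] = f.shape_hint.value
        features_array.append(el)

    configuration = {
        "style": cfg.style.value,
        "nonOverlapping": cfg.style is RenderStyle.NON_OVERLAPPING,
        "requestedStart": cfg.requested_start,
        "requestedStop": cfg.requested_stop,
        "rulerY": cfg.ruler_y,
        "rulerLength": doc.derived.ruler_length,
        "belowRuler": cfg.below_ruler,
        "pixelsDivision": cfg.pixels_division,
        "aboveRuler": cfg.above_ruler,
        "sizeY": doc.derived.size_y,
        "sizeX": cfg.size_x,
        "rightMargin": cfg.right_margin,
        "leftMargin": cfg.left_margin,
        "sequenceLineY": cfg.sequence_line_y,
        "sequenceLineYCentered": cfg.centered_sequence_line_y,
        "sequenceLength": cfg.sequence_length,
        "unitsize": doc.derived.unitsize,
        "trackHeight": cfg.track_height,
        "centeredTrackHeight": cfg.centered_track_height,
        "trackGap": cfg.track_gap,
        "verticalGrid": cfg.show_vertical_grid,
        "horizontalGrid": cfg.show_horizontal_grid,
    }
    for key in ("dasSources", "dasReference"):
        if key in doc.extras:
            configuration[key] = doc.extras[key]

    payload = {
        "featuresArray": features_array,
        "segment": doc.segment_id,
        "legend": {
            "keys": [
                {
                    "typeLabel": e.type_label,
                    "typeCategory": e.type_category,
                    "color": e.color,
                    "glyph": e.glyph.value,
                }
                for e in doc.legend
            ]
        },
        "ruler": {"ticks": [{"x": t.x_px, "label": t.label}
                            for t in doc.ticks]},
        "configuration": configuration,
    }
    return json.dumps(payload, indent=1)


_REQUIRED_TOP = ("featuresArray", "segment", "legend", "configuration")
_REQUIRED_CONFIG = (
    "unitsize", "rulerLength", "sizeX", "leftMargin", "rightMargin",
    "requestedStart", "requestedStop", "sequenceLength", "style",
)


def read_layout_json(text: str) -> LayoutDocument:
    """Load a resolved drawing; performs **no** re-layout.

    Raises :class:`SchemaError` listing every missing required key. When
    a feature entry omits residue coordinates (some documents carry only
    pixels), they are recovered by inverting the pixel mapping — the one
    concession to documents produced by other writers.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"not valid JSON: {exc}") from None

    missing = [k for k in _REQUIRED_TOP if k not in doc]
    if "configuration" in doc:
        missing += [
            f"configuration.{k}" for k in _REQUIRED_CONFIG
            if k not in doc["configuration"]
        ]
    if missing:
        raise SchemaError(missing)

    c = doc["configuration"]
    config = LayoutConfig(
        sequence_length=int(c["sequenceLength"]),
        requested_start=int(c["requestedStart"]),
        requested_stop=int(c["requestedStop"]),
        size_x=int(c["sizeX"]),
        left_margin=int(c["leftMargin"]),
        right_margin=int(c["rightMargin"]),
        pixels_division=int(c.get("pixelsDivision", 50)),
        ruler_y=int(c.get("rulerY", 20)),
        above_ruler=int(c.get("aboveRuler", 10)),
        below_ruler=int(c.get("belowRuler", 30)),
        sequence_line_y=int(c.get("sequenceLineY", 54)),
        centered_sequence_line_y=int(c.get("sequenceLineYCentered", 95)),
        track_height=int(c.get("trackHeight", 10)),
        centered_track_height=int(c.get("centeredTrackHeight", 40)),
        track_gap=int(c.get("trackGap", 2)),
        style=RenderStyle.parse(c["style"]),
        show_vertical_grid=bool(c.get("verticalGrid", False)),
        show_horizontal_grid=bool(c.get("horizontalGrid", False)),
    )
    derived = DerivedGeometry(
        ruler_length=int(c["rulerLength"]),
        unitsize=float(c["unitsize"]),
        size_y=int(c["sizeY"]) if c.get("sizeY") is not None else None,
    )

    placed: List[PlacedFeature] = []
    for i, el in enumerate(doc["featuresArray"]):
        if "featureStart" in el and "featureEnd" in el:
            start, end = int(el["featureStart"]), int(el["featureEnd"])
        else:
            # pixels-only entry: invert x(p) = lm + (p - rs + 1) * unitsize
            start = (round_half_up((el["x"] - config.left_margin)
                                   / derived.unitsize)
                     + config.requested_start - 1)
            end = start + round_half_up(el["width"] / derived.unitsize)
        feature = validate_feature(
            feature_id=el.get("featureId") or f"F{i}",
            start=start,
            end=end,
            type_label=el.get("featureTypeLabel", ""),
            type_code=el.get("typeCode", ""),
            type_category=el.get("typeCategory", ""),
            feature_label=el.get("featureLabel", ""),
            evidence_text=el.get("evidenceText", ""),
            evidence_code=el.get("evidenceCode", ""),
            color=el.get("color"),
            shape_hint=el.get("shapeHint"),
        )
        glyph = GlyphKind.parse(el.get("type", "rect"))
        blocks = {
            key: dict(el[block_key])
            for key, block_key in (
                ("nonOverlapping", "nonOverlappingStyle"),
                ("centered", "centeredStyle"),
                ("rows", "rowsStyle"),
            )
            if block_key in el and el[block_key]
        }
        placed.append(
            PlacedFeature(
                feature=feature,
                glyph=glyph,
                x=int(el["x"]),
                y=int(el["y"]),
                width=int(el.get("width", 0)),
                height=int(el.get("height", config.track_height)),
                cx=int(el.get("cx", el["x"])),
                cy=int(el.get("cy", el["y"])),
                r=int(el.get("r", config.track_height)),
                track_index=int(el.get("trackIndex", 0)),
                fill=el.get("fill", "#000000"),
                stroke=el.get("stroke", el.get("fill", "#000000")),
                fill_opacity=float(el.get("fillOpacity", 0.5)),
                stroke_width=int(el.get("strokeWidth", 1)),
                tooltip=el.get("tooltip") or "",
                clipped_left=bool(el.get("clippedLeft", False)),
                clipped_right=bool(el.get("clippedRight", False)),
                style_blocks=blocks,
            )
        )

    raw_legend = doc["legend"]
    keys = raw_legend.get("keys", []) if isinstance(raw_legend, dict) else raw_legend
    legend = [
        LegendEntry(
            type_label=e.get("typeLabel", ""),
            type_category=e.get("typeCategory", ""),
            color=e.get("color", "#000000"),
            glyph=GlyphKind.parse(e.get("glyph", "rect")),
        )
        for e in keys
    ]
    ticks = [
        RulerTick(x_px=int(t["x"]), label=int(t["label"]))
        for t in doc.get("ruler", {}).get("ticks", [])
    ]
    extras = {k: doc["configuration"][k]
              for k in ("dasSources", "dasReference")
              if k in doc["configuration"]}
    return LayoutDocument(
        segment_id=str(doc["segment"]),
        config=config,
        derived=derived,
        placed=placed,
        ticks=ticks,
        legend=legend,
        extras=extras,
    )
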