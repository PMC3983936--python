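{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Computed-layout dialect",
 "description": "A fully resolved drawing: every pixel coordinate precomputed so that a renderer performs no layout math. Pixel fields are integers; unitsize (px per residue) is fractional.",
 "type": "object",
 "required": ["featuresArray", "segment", "legend", "configuration"],
 "properties": {
  "segment": {"type": "string"},
  "featuresArray": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["featureId", "type", "x", "y", "width"],
    "properties": {
     "nonOverlappingStyle": {"$ref": "#/$defs/styleBlock"},
     "centeredStyle": {"$ref": "#/$defs/styleBlock"},
     "rowsStyle": {"$ref": "#/$defs/styleBlock"},
     "featureId": {"type": "string"},
     "featureTypeLabel": {"type": "string"},
     "featureLabel": {"type": "string"},
     "featureStart": {"type": "integer"},
     "featureEnd": {"type": "integer"},
     "typeCode": {"type": "string"},
     "typeCategory": {"type": "string"},
     "evidenceText": {"type": "string"},
     "evidenceCode": {"type": "string"},
     "type": {
      "enum": ["rect", "circle", "diamond", "triangle", "hexagon",
               "wave", "bridge", "line"]
     },
     "x": {"type": "integer"},
     "y": {"type": "integer"},
     "width": {"type": "integer", "minimum": 0},
     "height": {"type": "integer"},
     "cx": {"type": "integer"},
     "cy": {"type": "integer"},
     "r": {"type": "integer"},
     "fill": {"type": "string"},
     "stroke": {"type": "string"},
     "fillOpacity": {"type": "number"},
     "strokeWidth": {"type": "integer"},
     "trackIndex": {"type": "integer", "minimum": 0},
     "clippedLeft": {"type": "boolean"},
     "clippedRight": {"type": "boolean"},
     "tooltip": {"type": "string"}
    }
   }
  },
  "legend": {
   "type": "object",
   "properties": {
    "keys": {
     "type": "array",
     "items": {
      "type": "object",
      "properties": {
       "typeLabel": {"type": "string"},
       "typeCategory": {"type": "string"},
       "color": {"type": "string"},
       "glyph": {"type": "string"}
      }
     }
    }
   }
  },
  "ruler": {
   "type": "object",
   "properties": {
    "ticks": {
     "type": "array",
     "items": {
      "type": "object",
      "required": ["x", "label"],
      "properties": {
       "x": {"type": "integer"},
       "label": {"type": "integer"}
      }
     }
    }
   }
  },
  "configuration": {
   "type": "object",
   "required": ["unitsize", "rulerLength", "sizeX", "leftMargin",
                "rightMargin", "requestedStart", "requestedStop",
                "sequenceLength", "style"],
   "properties": {
    "style": {"enum": ["nonOverlapping", "rows", "centered"]},
    "nonOverlapping": {"type": "boolean"},
    "requestedStart": {"type": "integer"},
    "requestedStop": {"type": "integer"},
    "rulerY": {"type": "integer"},
    "rulerLength": {"type": "integer"},
    "belowRuler": {"type": "integer"},
    "pixelsDivision": {"type": "integer"},
    "aboveRuler": {"type": "integer"},
    "sizeY": {"type": "integer"},
    "sizeX": {"type": "integer"},
    "rightMargin": {"type": "integer"},
    "leftMargin": {"type": "integer"},
    "sequenceLineY": {"type": "integer"},
    "sequenceLineYCentered": {"type": "integer"},
    "sequenceLength": {"type": "integer"},
    "unitsize": {"type": "number"},
    "trackHeight": {"type": "integer"},
    "centeredTrackHeight": {"type": "integer"},
    "trackGap": {"type": "integer"},
    "verticalGrid": {"type": "boolean"},
    "horizontalGrid": {"type": "boolean"},
    "dasSources": {"type": "string"},
    "dasReference": {"type": "string"}
   }
  }
 },
 "$defs": {
  "styleBlock": {
   "type": "object",
   "properties": {
    "heightOrRadius": {"type": "integer"},
    "y": {"type": "integer"}
   }
  }
 }
}
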