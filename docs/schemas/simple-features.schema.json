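{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Simple-features annotation dialect",
 "description": "Flat input dialect: a sequence identifier, its length, and an array of position-based features with 1-based inclusive coordinates. Unknown keys are ignored with a warning.",
 "type": "object",
 "required": ["sequenceId", "sequenceLength", "features"],
 "properties": {
  "sequenceId": {"type": "string"},
  "sequenceLength": {"type": "integer", "minimum": 1},
  "features": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["featureStart", "featureEnd"],
    "properties": {
     "featureId": {"type": "string", "minLength": 1},
     "featureStart": {"type": "integer", "minimum": 1},
     "featureEnd": {"type": "integer", "minimum": 1},
     "typeLabel": {"type": "string"},
     "typeCode": {"type": "string"},
     "typeCategory": {"type": "string"},
     "featureLabel": {"type": "string"},
     "evidenceText": {"type": "string"},
     "evidenceCode": {"type": "string"},
     "color": {
      "type": "string",
      "pattern": "^(#[0-9A-Fa-f]{6}|[A-Za-z]+)$"
     },
     "type": {
      "enum": ["rect", "circle", "diamond", "triangle", "hexagon",
               "wave", "bridge", "line"]
     }
    }
   }
  }
 }
}
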