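{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/cohortviz/viewspec.schema.json",
  "title": "cohortviz view specification",
  "description": "Accepted subset of the declarative visualization grammar: a tree of views, each with optional data/transform/encoding and exactly one of mark, layer, or vconcat.",
  "$ref": "#/$defs/view",
  "$defs": {
    "view": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "name": {"type": "string"},
        "data": {"$ref": "#/$defs/data"},
        "transform": {"type": "array", "items": {"$ref": "#/$defs/transform"}},
        "encoding": {"$ref": "#/$defs/encoding"},
        "mark": {"enum": ["rect", "point", "text", "rule"]},
        "layer": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/view"}},
        "vconcat": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/view"}},
        "visible": {"type": "boolean", "default": true},
        "params": {"type": "object"},
        "height": {"type": "number", "exclusiveMinimum": 0}
      },
      "oneOf": [
        {"required": ["mark"]},
        {"required": ["layer"]},
        {"required": ["vconcat"]}
      ]
    },
    "data": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "url": {"type": "string"},
        "values": {"type": "array", "items": {"type": "object"}},
        "format": {"enum": ["tsv", "csv", "json", "bed"]},
        "oneBased": {"type": "boolean", "default": false}
      },
      "oneOf": [{"required": ["url"]}, {"required": ["values"]}]
    },
    "transform": {
      "type": "object",
      "required": ["type"],
      "properties": {
        "type": {"enum": ["filter", "formula", "flattenSequence", "coverage", "semanticZoom"]},
        "expr": {"type": "string"},
        "as": {"type": "string"},
        "field": {"type": "string"},
        "startField": {"type": "string"},
        "endField": {"type": "string"},
        "posField": {"type": "string"},
        "asField": {"type": "string"},
        "weightField": {"type": "string"},
        "chromField": {"type": "string"},
        "scoreField": {"type": "string"},
        "budget": {"type": "integer", "minimum": 1},
        "zoomLevel": {"type": "number", "minimum": 1}
      }
    },
    "encoding": {
      "type": "object",
      "additionalProperties": false,
      "patternProperties": {
        "^(x|x2|y|y2|color|opacity|size|text|sample)$": {"$ref": "#/$defs/channel"}
      }
    },
    "channel": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "field": {"type": "string"},
        "value": {},
        "type": {"enum": ["quantitative", "ordinal", "nominal", "locus"]},
        "scale": {"$ref": "#/$defs/scale"}
      },
      "oneOf": [{"required": ["field"]}, {"required": ["value"]}]
    },
    "scale": {
      "type": "object",
      "properties": {
        "kind": {"enum": ["linear", "band", "ordinal-color", "linear-color", "locus"]},
        "domain": {"type": "array"},
        "range": {},
        "clamp": {"type": "boolean", "default": false}
      }
    }
  }
}
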