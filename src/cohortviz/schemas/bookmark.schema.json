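{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/cohortviz/bookmark.schema.json",
  "title": "cohortviz bookmark",
  "description": "A shareable exploration snapshot: the reversible-action log (provenance), current scale domains, and per-view visibility.",
  "type": "object",
  "required": ["name"],
  "additionalProperties": false,
  "properties": {
    "name": {"type": "string"},
    "notes": {"type": "string", "description": "Markdown, preserved verbatim"},
    "actions": {"type": "array", "items": {"$ref": "#/$defs/action"}},
    "scaleDomains": {
      "type": "object",
      "additionalProperties": {
        "type": "array", "minItems": 2, "maxItems": 2, "items": {"type": "number"}
      }
    },
    "viewVisibility": {"type": "object", "additionalProperties": {"type": "boolean"}}
  },
  "$defs": {
    "action": {
      "type": "object",
      "required": ["type"],
      "properties": {
        "type": {"enum": ["filterCategory", "filterQuant", "sortBy",
                          "retainFirstOfEach", "groupByCategory", "groupByThreshold"]},
        "attr": {"type": "string"},
        "retain": {"type": "array"},
        "source": {
          "oneOf": [
            {"type": "string"},
            {
              "type": "object",
              "required": ["chrom", "pos", "kind"],
              "properties": {
                "chrom": {"type": "string"},
                "pos": {"type": "integer", "minimum": 0},
                "kind": {"enum": ["log2R", "baf", "loh"]}
              }
            }
          ]
        },
        "op": {"enum": [">=", "<=", ">", "<"]},
        "threshold": {"type": "number"},
        "descending": {"type": "boolean", "default": false}
      }
    }
  }
}
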