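{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/goflow/flowchart.schema.json",
  "title": "Curation flowchart",
  "description": "A rooted binary decision structure for literature curation. Filter and decision nodes ask yes/no questions; terminals carry GO-term payloads. A missing branch must declare an on_fail disposition.",
  "type": "object",
  "required": ["name", "version", "root", "nodes"],
  "properties": {
    "name": {"type": "string"},
    "version": {"type": "string"},
    "root": {"type": "string"},
    "nodes": {
      "type": "object",
      "minProperties": 1,
      "additionalProperties": {"$ref": "#/$defs/node"}
    },
    "term_hierarchy": {
      "type": "object",
      "description": "child GO id -> parent GO id (is_a)",
      "additionalProperties": {"$ref": "#/$defs/goId"}
    }
  },
  "$defs": {
    "goId": {"type": "string", "pattern": "^GO:[0-9]{7}$"},
    "node": {
      "type": "object",
      "required": ["kind", "question"],
      "properties": {
        "kind": {"enum": ["filter", "decision", "terminal"]},
        "question": {"type": "string"},
        "section_hint": {"type": "string"},
        "yes_next": {"type": "string"},
        "no_next": {"type": "string"},
        "on_fail": {"enum": ["filtered", "no_annotation"]},
        "payload": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["term", "aspect"],
            "properties": {
              "term": {"$ref": "#/$defs/goId"},
              "aspect": {"enum": ["BP", "MF"]}
            }
          }
        }
      }
    }
  }
}
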