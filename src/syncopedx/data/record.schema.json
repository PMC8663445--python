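{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://syncopedx.dev/schemas/record.schema.json",
  "title": "SyncopeDx evaluation record (one JSON line per completed assessment)",
  "type": "object",
  "required": ["record_id", "timestamp", "answers", "app_top", "css_total", "risk_class"],
  "additionalProperties": false,
  "properties": {
    "record_id": {
      "type": "string",
      "description": "opaque identifier; carries no patient information"
    },
    "timestamp": {"type": "string", "format": "date-time"},
    "answers": {
      "type": "object",
      "additionalProperties": {"enum": ["yes", "no", "unknown"]}
    },
    "app_top": {"enum": ["vasovagal", "orthostatic", "cardiogenic", "neurogenic_loc"]},
    "user_selected_ddx": {
      "oneOf": [
        {"type": "null"},
        {"enum": ["vasovagal", "orthostatic", "cardiogenic", "neurogenic_loc"]}
      ]
    },
    "css_total": {"type": "integer"},
    "risk_class": {"enum": ["low", "intermediate", "high"]},
    "recommendation_keys": {
      "type": "object",
      "properties": {
        "primary": {"type": "string"},
        "secondary": {"oneOf": [{"type": "null"}, {"type": "string"}]},
        "question_specific": {"type": "array", "items": {"type": "string"}},
        "disposition": {"type": "string"}
      }
    },
    "hypothetical": {
      "type": "boolean",
      "description": "user-flagged test entry; excluded from congruence reporting by default"
    }
  }
}
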