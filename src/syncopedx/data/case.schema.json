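{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://syncopedx.dev/schemas/case.schema.json",
  "title": "SyncopeDx case file",
  "type": "object",
  "required": ["answers"],
  "additionalProperties": false,
  "properties": {
    "answers": {
      "type": "object",
      "description": "map from question id to the clinician's response",
      "additionalProperties": {"enum": ["yes", "no", "unknown"]}
    },
    "user_selected_ddx": {
      "oneOf": [
        {"type": "null"},
        {"enum": ["vasovagal", "orthostatic", "cardiogenic", "neurogenic_loc"]}
      ]
    }
  }
}
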