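{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://syncopedx.dev/schemas/kb.schema.json",
  "title": "SyncopeDx knowledge base",
  "type": "object",
  "required": ["version", "questions", "priors", "css", "recommendations"],
  "additionalProperties": false,
  "properties": {
    "version": {"type": "string"},
    "tie_break_order": {
      "type": "array",
      "items": {"$ref": "#/definitions/etiology"},
      "minItems": 4,
      "maxItems": 4,
      "uniqueItems": true
    },
    "questions": {
      "type": "array",
      "items": {"$ref": "#/definitions/question"}
    },
    "priors": {
      "type": "object",
      "required": ["vasovagal", "orthostatic", "cardiogenic", "neurogenic_loc"],
      "additionalProperties": false,
      "properties": {
        "vasovagal": {"$ref": "#/definitions/probability"},
        "orthostatic": {"$ref": "#/definitions/probability"},
        "cardiogenic": {"$ref": "#/definitions/probability"},
        "neurogenic_loc": {"$ref": "#/definitions/probability"}
      }
    },
    "css": {
      "type": "object",
      "required": ["items", "thresholds"],
      "additionalProperties": false,
      "properties": {
        "items": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["name", "source", "points"],
            "additionalProperties": false,
            "properties": {
              "name": {"type": "string"},
              "source": {
                "type": "string",
                "description": "a question id, or one of the diagnosis-derived markers 'diagnosis:vasovagal' / 'diagnosis:cardiac'"
              },
              "points": {"type": "integer"}
            }
          }
        },
        "thresholds": {
          "type": "object",
          "required": ["low_below", "high_above"],
          "additionalProperties": false,
          "properties": {
            "low_below": {"type": "integer"},
            "high_above": {"type": "integer"}
          }
        }
      }
    },
    "recommendations": {
      "type": "object",
      "required": ["primary", "secondary", "question_specific", "disposition"],
      "additionalProperties": false,
      "properties": {
        "primary": {
          "type": "object",
          "required": ["vasovagal", "orthostatic", "cardiogenic", "neurogenic_loc"],
          "additionalProperties": {"type": "string"}
        },
        "secondary": {
          "type": "object",
          "description": "keys are 'app_etiology|user_etiology' for every discordant ordered pair",
          "additionalProperties": {"type": "string"}
        },
        "question_specific": {
          "type": "object",
          "additionalProperties": {"type": "string"}
        },
        "disposition": {
          "type": "object",
          "required": ["low", "intermediate", "high"],
          "additionalProperties": {"type": "string"}
        }
      }
    }
  },
  "definitions": {
    "etiology": {
      "enum": ["vasovagal", "orthostatic", "cardiogenic", "neurogenic_loc"]
    },
    "probability": {
      "type": "number",
      "exclusiveMinimum": 0,
      "exclusiveMaximum": 1
    },
    "lhr_pair": {
      "oneOf": [
        {"type": "null"},
        {
          "type": "object",
          "required": ["pos", "neg"],
          "additionalProperties": false,
          "properties": {
            "pos": {"type": "number", "exclusiveMinimum": 0},
            "neg": {"type": "number", "exclusiveMinimum": 0}
          }
        }
      ]
    },
    "question": {
      "type": "object",
      "required": ["id", "text", "lhr", "css_input", "prompt_only", "override_for"],
      "additionalProperties": false,
      "properties": {
        "id": {"type": "string", "pattern": "^[a-z][a-z0-9_]*$"},
        "text": {"type": "string"},
        "lhr": {
          "type": "object",
          "additionalProperties": false,
          "properties": {
            "vasovagal": {"$ref": "#/definitions/lhr_pair"},
            "orthostatic": {"$ref": "#/definitions/lhr_pair"},
            "cardiogenic": {"$ref": "#/definitions/lhr_pair"},
            "neurogenic_loc": {"$ref": "#/definitions/lhr_pair"}
          }
        },
        "css_input": {"type": "boolean"},
        "prompt_only": {"type": "boolean"},
        "override_for": {
          "oneOf": [{"type": "null"}, {"$ref": "#/definitions/etiology"}]
        },
        "thresholds": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["value", "unit"],
            "properties": {
              "value": {"type": "number"},
              "unit": {"type": "string"},
              "label": {"type": "string"}
            }
          }
        }
      }
    }
  }
}
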