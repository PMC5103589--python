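{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "phenotab validation report",
  "type": "object",
  "required": ["issues", "compliance", "summary"],
  "properties": {
    "issues": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["severity", "code", "file", "row", "column", "message"],
        "properties": {
          "severity": {"enum": ["error", "warning", "info"]},
          "code": {"type": "string"},
          "file": {"type": "string"},
          "row": {"type": ["integer", "string"]},
          "column": {"type": "string"},
          "message": {"type": "string"}
        }
      }
    },
    "compliance": {
      "type": "object",
      "required": ["configuration", "score", "applicable", "present", "sections"],
      "properties": {
        "configuration": {"type": "string"},
        "score": {"type": "number", "minimum": 0, "maximum": 1},
        "applicable": {"type": "integer"},
        "present": {"type": "integer"},
        "sections": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["applicable", "present", "missing"],
            "properties": {
              "applicable": {"type": "array", "items": {"type": "string"}},
              "present": {"type": "array", "items": {"type": "string"}},
              "missing": {"type": "array", "items": {"type": "string"}}
            }
          }
        },
        "extended_present": {"type": "array", "items": {"type": "string"}}
      }
    },
    "summary": {
      "type": "object",
      "required": ["errors", "warnings", "infos"],
      "properties": {
        "errors": {"type": "integer"},
        "warnings": {"type": "integer"},
        "infos": {"type": "integer"}
      }
    }
  }
}
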