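{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Phenotype (case) definition",
  "description": "A declarative case definition: named search clauses (keyword, lab, or prescription tests over located fields) combined by a boolean logic expression. One definition per YAML/JSON file.",
  "type": "object",
  "required": ["name", "clauses", "logic"],
  "properties": {
    "name": {"type": "string", "minLength": 1},
    "architecture": {
      "enum": ["diagnosis_only", "evidence_only", "combined"]
    },
    "provenance": {"type": "string"},
    "clauses": {
      "type": "object",
      "minProperties": 1,
      "additionalProperties": {"$ref": "#/$defs/clause"}
    },
    "logic": {
      "type": "string",
      "description": "Boolean expression over clause ids with AND / OR / NOT and parentheses; OR binds loosest."
    }
  },
  "$defs": {
    "clause": {
      "type": "object",
      "required": ["section"],
      "properties": {
        "section": {
          "enum": [
            "FRONT_PAGE", "ADMISSION_RECORD", "DISCHARGE_RECORD",
            "SURGERY_RECORD", "DEATH_RECORD", "LAB_RESULTS", "RADIOLOGY",
            "PATHOLOGY", "PHYSICIAN_NOTES", "COST_RECORD", "PRESCRIPTIONS"
          ]
        },
        "fields": {
          "type": "string",
          "description": "Literal field name or glob; '*' matches any run of characters."
        },
        "channel": {"enum": ["text", "structured", "lab", "prescription"]},
        "keywords": {
          "type": "array",
          "description": "AND of groups; each group is an OR of literal terms.",
          "items": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "string", "minLength": 1}
          }
        },
        "analyte": {"type": "string"},
        "comparator": {"enum": ["<", "<=", ">", ">=", "=", "between"]},
        "threshold": {
          "oneOf": [
            {"type": "number"},
            {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}
          ]
        },
        "drugs": {
          "type": "array",
          "minItems": 1,
          "items": {"type": "string", "minLength": 1}
        }
      }
    }
  }
}
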