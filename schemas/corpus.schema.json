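{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "EMR corpus line",
  "description": "One admission per JSON-lines record. Known section names are the SectionKind enumeration; unknown names are preserved under the document's extra bucket.",
  "type": "object",
  "required": ["patient_id", "admission_id"],
  "properties": {
    "patient_id": {"type": "string", "minLength": 1},
    "admission_id": {"type": "string", "minLength": 1},
    "admit_date": {"type": ["string", "null"]},
    "discharge_date": {"type": ["string", "null"]},
    "sections": {
      "type": "object",
      "additionalProperties": {"$ref": "#/$defs/section"}
    }
  },
  "$defs": {
    "section": {
      "type": "object",
      "properties": {
        "structured_fields": {
          "type": "object",
          "additionalProperties": {"type": ["string", "number", "boolean", "null"]}
        },
        "text_fields": {
          "type": "object",
          "additionalProperties": {"type": "string"}
        },
        "lab_results": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["analyte", "value", "unit", "collected_at"],
            "properties": {
              "analyte": {"type": "string", "minLength": 1},
              "value": {"type": "number"},
              "unit": {"type": "string", "minLength": 1},
              "collected_at": {"type": "string"}
            }
          }
        },
        "prescriptions": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["drug_name"],
            "properties": {
              "drug_name": {"type": "string", "minLength": 1},
              "start_date": {"type": ["string", "null"]}
            }
          }
        }
      },
      "additionalProperties": false
    }
  }
}
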