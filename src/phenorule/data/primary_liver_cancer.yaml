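# Exemplar case definition for primary liver cancer (PLC).
# Illustrative fixture authored for this toolkit: diagnosis-field keywords OR
# conclusive-sentence keywords in pathology/radiology reports. It is not a
# reproduction of any hospital's production keyword list.
name: primary_liver_cancer
architecture: combined
provenance: >-
  Exemplar authored from the hepatocellular-carcinoma diagnostic pathway:
  admission-diagnosis keywords, or malignancy keywords in the conclusive
  sentence of a pathology or radiology report.
clauses:
  dx:
    section: ADMISSION_RECORD
    fields: "diagnosis_*"
    channel: text
    keywords:
      - ["原发性肝癌", "肝细胞癌", "肝癌"]
  path:
    section: PATHOLOGY
    fields: conclusion
    channel: text
    keywords:
      - ["肝细胞癌", "胆管细胞癌"]
  radio:
    section: RADIOLOGY
    fields: conclusion
    channel: text
    keywords:
      - ["肝脏恶性肿瘤", "肝占位性病变"]
logic: dx OR path OR radio
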