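# Exemplar case definition for chronic hepatitis B: diagnosis-field keywords
# OR an antiviral prescription. Illustrative fixture authored for this
# toolkit, not a reproduction of any hospital's production keyword list.
name: hepatitis_b
architecture: combined
provenance: >-
  Exemplar authored from hepatitis-B practice: admission-diagnosis keywords,
  or a nucleos(t)ide-analogue antiviral on the electronic prescription list.
clauses:
  dx:
    section: ADMISSION_RECORD
    fields: "diagnosis_*"
    channel: text
    keywords:
      - ["乙型病毒性肝炎", "乙型肝炎", "乙肝"]
  rx:
    section: PRESCRIPTIONS
    channel: prescription
    drugs: ["恩替卡韦", "拉米夫定", "阿德福韦酯", "替比夫定", "替诺福韦"]
logic: dx OR rx
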