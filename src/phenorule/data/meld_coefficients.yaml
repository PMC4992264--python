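# Example coefficient file for the configurable linear severity-score engine.
# This particular set reproduces the standard (UNOS) MELD exactly and is
# shipped as a worked example of the file format; it is NOT a five-variable
# MELD coefficient set — supply your own for that score.
intercept: 6.43
scale: 1.0
round: true
terms:
  - variable: crea
    coefficient: 9.57
    transform: ln
    clamp: [1.0, 4.0]
  - variable: tbil
    coefficient: 3.78
    transform: ln
    clamp: [1.0, null]
  - variable: inr
    coefficient: 11.20
    transform: ln
    clamp: [1.0, null]
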