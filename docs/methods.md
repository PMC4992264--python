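# Methods

## The problem and the approach

Hospital EMR systems that do not code diagnoses (no ICD) document conditions
in free text: enumerated diagnosis fields in the admission and discharge
records, conclusive sentences in radiology and pathology reports, structured
laboratory panels, and drug prescriptions. Because diagnoses are entered one
per field under documentation rules, and conclusive sentences are short and
formulaic, plain keyword search over a small number of high-yield fields is a
workable substitute for NLP. `phenorule` mechanizes that approach as a
three-component case definition:

1. **keyword groups** — alternative literal terms for one concept (Chinese or
   Latin words; punctuation allowed); a clause may require several groups to
   match jointly (AND of ORs), possibly in different fields of the same
   locator, because a diagnosis list is a set of short statements rather than
   one narrative;
2. **field locators** — section plus field pattern plus channel (text, lab,
   prescription); the glob `*` matches any run of characters within a field
   name and nothing else;
3. **boolean logic** — an AND/OR/NOT expression over named clauses; NOT
   encodes exclusion criteria. OR binds loosest, NOT tightest.

A definition's **architecture** records which information it draws on:
`diagnosis_only` (all clauses target enumerated diagnosis fields of the front
page / admission / discharge records), `evidence_only` (none do), or
`combined`. `derive_variants` prunes a combined definition into its
diagnosis-only and evidence-only restrictions by substituting removed leaves
with the identity element of their boolean context (TRUE under AND, FALSE
under OR; NOT flips the context), so the residual tree stays total; a variant
whose tree collapses to a constant is omitted. This mirrors the practice of
authoring several candidate definitions per condition and keeping the one
with the highest validity.

### Matching semantics

A keyword matches a field when it occurs as a **contiguous substring** after
normalization — Unicode NFKC (which unifies full-/half-width Latin letters,
digits and most punctuation), lowercasing, and stripping of leading/trailing
field whitespace. Chinese characters are unaffected. There is deliberately no
tokenization, stemming or negation detection; negated mentions ("rule out
X") are a known false-positive source and are handled, when needed, by
exclusion clauses. Note NFKC does not fold the ideographic full stop `。` to
`.`; keywords should be authored in the script they are expected to appear
in.

Lab clauses compare against the **latest** result per admission for the
analyte (ties broken by input order, with a warning); absence of a section,
field or lab result makes a clause false, never an error. Patient-level flags
are the OR over that patient's admissions; per-admission evaluation is also
available (`--unit admission`).

Every positive call carries an evidence trace — (clause, field, matched term
or lab value, admission) — that can be independently replayed against the
corpus. When a definition fires purely through exclusion logic, the trace
records the absence that allowed it (`leaf_value=False` entries).

## Validation statistics

Against chart-review reference labels, each definition gets a 2×2 confusion
matrix and the four accuracy metrics with **exact (Clopper–Pearson) 95%
binomial CIs**: lower bound = Beta(x, n−x+1) quantile at α/2 (0 when x=0),
upper = Beta(x+1, n−x) quantile at 1−α/2 (1 when x=n). The exact method is
the toolkit's declared convention; it has the convenient property that
all-positive detections (x = n) yield the characteristic lower bounds
96/96 → 96.2%, 18/18 → 81.5%, 5/5 → 47.8%, 40/40 → 91.2%, 32/32 → 89.1%,
445/445 → 99.2%. Percentages are rendered to one decimal, rounding half up.
A metric whose defining margin is empty (e.g. PPV with no positive calls) is
reported as undefined, never as 0.

Inter-rater agreement uses **Cohen's kappa**, po − pe over 1 − pe with pe the
product-of-marginals expectation. When any marginal of the 2×2 rater table is
zero (common for low-prevalence conditions reviewed on modest samples),
pe = 1 and kappa is degenerate; the toolkit then reports the observed
agreement instead and flags the fallback.

**Best-definition selection** ranks by Youden's J = sensitivity +
specificity − 1, breaking ties by PPV and then definition id. "Highest
validity" is a judgement call with no canonical ranking; J is the default
because it weights the two error types equally and is prevalence-free, and
the criterion is a parameter (`key="ppv"` ranks by PPV first).

## Severity scores

The published severity indexes exist in several parameterizations; the
toolkit's conventions are declared and configurable:

- **MELD** (UNOS form): creatinine, bilirubin, INR floored at 1.0 and
  creatinine capped at 4.0 mg/dL; 10·(0.957 ln Cr + 0.378 ln TBIL +
  1.120 ln INR + 0.643), rounded half-up to an integer.
- **MELD-Na** (additive form): MELD + 1.59·(135 − Na), Na clamped to
  [120, 135] mmol/L, reported unrounded.
- **Child-Pugh**: bilirubin <2 / 2–3 / >3 mg/dL, albumin >3.5 / 2.8–3.5 /
  <2.8 g/dL, INR <1.7 / 1.7–2.3 / >2.3 (or PT prolongation <4 / 4–6 / >6 s;
  exactly one coagulation measure must be supplied), ascites and
  encephalopathy grades; total 5–15, classes A = 5–6, B = 7–9, C = 10–15.
  Middle bands are **closed** (TBIL = 2.0 and 3.0 both score 2) — sources
  disagree here, so the convention is stated explicitly.
- **Five-variable MELD**: implemented as a generic linear engine over
  per-variable ln/identity transforms with clamps, configured from a YAML
  coefficient file. No default coefficient set is claimed: the toolkit ships
  only an example file that exactly reproduces standard MELD (and is tested
  to), and refuses to guess the published 5vMELD coefficients.

Canonical units are mg/dL (bilirubin, creatinine), g/dL (albumin) and mmol/L
(sodium); converters handle the µmol/L and g/L units typical of Chinese labs
(÷17.1, ÷88.4, ÷10). The extraction engine converts recognized units before
threshold comparison and passes unrecognized units through unchanged.

Which of several lab draws per admission feeds a severity score is not
standardized; the per-admission **latest** value is this package's documented
choice.

## Comorbidity indexes

Extracted condition flags map to Charlson/Elixhauser components through an
editable TSV table. Charlson weights are the original 1/2/3/6 enumeration;
Elixhauser components count 1 each. Hierarchy rules collapse coexisting
mild/severe forms (mild vs moderate/severe liver disease, diabetes ± 
complications, any malignancy vs metastatic solid tumor) so only the severe
form counts. Counts are banded 0 / 1 / 2 / "3 and more". Age adjustment is
not applied. The packaged map covers a liver-cohort condition panel and is a
starting point, not a canonical enumeration — the Elixhauser component list
varies between 30- and 31-component versions across sources, and users with
different extraction vocabularies should edit the table; unmapped conditions
are reported, never silently dropped.

## Synthetic corpus generator

The generator emulates the *structure* of a semi-structured hospital EMR and
the *statistics* of imperfect documentation:

- conditions are drawn independently per patient with configured prevalences
  (defaults reflect a liver-specialty inpatient case mix: PLC 0.213,
  cirrhosis 0.327, hepatitis B 0.451, hepatitis C 0.089, fatty liver 0.040,
  alcoholic liver disease 0.071, SBP 0.149, variceal hemorrhage 0.044,
  hepatorenal syndrome 0.011, hepatic encephalopathy 0.089, ascites 0.276);
- a true condition plants a keyword satisfying its registered definition
  with probability `doc_sensitivity` (default 0.9), choosing uniformly among
  the definition's planting routes (diagnosis field, pathology/radiology
  conclusion, prescription, or an out-of-range lab value), in a uniformly
  chosen admission of the patient;
- a false condition plants anyway with probability `spurious_rate`
  (default 0.02);
- remaining fields are filled from a small distractor lexicon verified (and
  tested) to contain no registered keyword as a substring, so false
  positives arise only from configured spurious planting;
- everything is reproducible from the mandatory seed (numpy PCG64).

Under these dynamics, measured sensitivity converges to `doc_sensitivity`
and specificity to 1 − `spurious_rate`; the test suite asserts this at
n = 5,000 patients within exact 99% binomial intervals, and at the noiseless
limit (doc_sensitivity 1, spurious_rate 0) extraction recovers truth exactly.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: correlated comorbidity (cirrhosis→ascites and similar
are generated independently; a correlation hook is the natural extension),
linguistically realistic narrative (distractors are stock phrases), negated
or uncertain mentions ("rule out", "suspected"), synonym/abbreviation
variability beyond the authored keyword lists, and inter-hospital
documentation-style differences. Validity measured on synthetic corpora
certifies the *machinery* — matching, logic, aggregation, statistics — not
the clinical adequacy of any keyword list.

## Numerical and design notes

- **Percent rendering** uses decimal half-up at one decimal (not banker's
  rounding), matching conventional clinical-table arithmetic
  (96/450 → 21.3).
- **Exact CI boundary identities**: x = n ⇒ low = 0.025^(1/n); x = 0 ⇒
  high = 1 − 0.025^(1/n); asserted to 1e-9.
- **Logic evaluation** is checked against exhaustive truth-table enumeration
  for trees with ≤ 6 leaves, and the engine against an independent
  brute-force matcher (raw offset-by-offset substring scan, no shared code)
  on random corpora.
- **Determinism**: corpus writer emits fixed key order (byte-identical
  round-trips); extraction output is invariant to corpus shuffling up to row
  order; lab-timestamp ties break to the last result in input order with a
  warning; unparsable dates keep their raw string and are excluded from
  temporal operations with a warning.
- **Problem sizes** used by the test suite and the acceptance script —
  5,000 patients for parameter recovery, 100 random corpora of up to 200
  documents for engine equivalence, 2,000 replicates per (p, n) cell for CI
  coverage — were chosen to make Monte-Carlo error small relative to the
  asserted tolerances while keeping the default run fast.

## Known limitations

- Exemplar definitions (primary liver cancer; hepatitis B with antiviral
  prescriptions; a lab-augmented hepatorenal-syndrome rule) are illustrative
  fixtures demonstrating the format: production keyword lists must be
  authored per site against local documentation style and clinical
  guidelines.
- No negation or uncertainty handling by design; exclusion clauses are the
  only mitigation.
- Kappa CIs, multi-rater agreement and prevalence-adjusted agreement
  statistics are out of scope.
- The comorbidity map is condition-name based; ICD-based mappings are out of
  scope because the target EMRs carry no codes.
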