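"""Evaluate case definitions over documents and corpora.

Matching is deliberately plain: a keyword group matches a field when any of
its terms occurs as a contiguous substring of the field text after
normalization. There is no tokenization, stemming, negation detection or any
other NLP — keyword search over a small number of high-yield fields
(enumerated diagnoses, conclusive sentences, structured labs, prescriptions)
is the method. Negated mentions are a documented false-positive source,
mitigated by exclusion clauses in the definition logic.

Normalization before matching: Unicode NFKC (which unifies full- and
half-width punctuation variants common in Chinese clinical text), lowercasing
of cased letters, and stripping of leading/trailing field whitespace. Chinese
characters are otherwise untouched.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from . import units
from .definition_dsl import (
    KeywordGroup,
    PhenotypeDefinition,
    SearchClause,
    evaluate_logic,
    negative_leaves,
    positive_leaves,
)
from .emr_model import Corpus, EMRDocument, SectionKind, get_texts, latest_lab


def normalize_text(text: str) -> str:
    return unicodedata.normalize("NFKC", text).lower().strip()


def match_keywords(text: str, group: KeywordGroup) -> bool:
    """True iff any term of the group occurs as a substring of the text."""
    norm = normalize_text(text)
    return any(normalize_text(term) in norm for term in group.terms)


def _first_matching_term(text: str, group: KeywordGroup) -> Optional[str]:
    norm = normalize_text(text)
    for term in group.terms:
        if normalize_text(term) in norm:
            return term
    return None


@dataclass(frozen=True)
class EvidenceEntry:
    """One independently re-checkable pointer into the corpus.

    ``leaf_value`` is the clause truth value the entry attests to: True for a
    keyword/lab/drug hit, False for an exclusion clause whose *absence* of a
    match allowed the definition to fire.
    """

    clause_id: str
    field_name: str
    matched: str  # matched keyword, drug name, or "ANALYTE=value"
    admission_id: str
    leaf_value: bool = True


@dataclass
class PhenotypeCall:
    """A per-unit binary call with its evidence trace."""

    patient_id: str
    condition: str
    flag: bool
    evidence: list[EvidenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.flag and not self.evidence:
            raise ValueError("a positive call requires non-empty evidence")


def _compare(value: float, test) -> bool:
    comparator, threshold = test.comparator, test.threshold
    if comparator == "between":
        low, high = threshold
        return low <= value <= high
    t = float(threshold)
    return {
        "<": value < t,
        "<=": value <= t,
        ">": value > t,
        ">=": value >= t,
        "=": value == t,
    }[comparator]


def evaluate_clause(
    doc: EMRDocument, clause: SearchClause, clause_id: str = "clause"
) -> tuple[bool, list[EvidenceEntry]]:
    """Evaluate one clause against one admission.

    Keyword tests require every group to match somewhere within the located
    fields; different groups may match in different fields of the same
    locator (a diagnosis list is a set of short statements, not one
    narrative). A missing section or absent lab is false, never an error.
    """
    if clause.numeric_test is not None:
        test = clause.numeric_test
        result = latest_lab(doc, test.analyte)
        if result is None:
            return False, []
        value = units.maybe_canonical(result.value, test.analyte, result.unit)
        if _compare(value, test):
            return True, [
                EvidenceEntry(
                    clause_id,
                    f"lab:{test.analyte}",
                    f"{test.analyte}={result.value} {result.unit}",
                    doc.admission_id,
                )
            ]
        return False, []

    if clause.presence_test is not None:
        sec = doc.sections.get(SectionKind.PRESCRIPTIONS)
        if sec is None:
            return False, []
        for rx in sec.prescriptions:
            term = _first_matching_term(rx.drug_name, clause.presence_test)
            if term is not None:
                return True, [
                    EvidenceEntry(clause_id, "drug_name", term, doc.admission_id)
                ]
        return False, []

    texts = get_texts(doc, clause.locator)
    evidence: list[EvidenceEntry] = []
    for group in clause.keyword_groups or ():
        hit: Optional[EvidenceEntry] = None
        for field_name, text in texts:
            term = _first_matching_term(text, group)
            if term is not None:
                hit = EvidenceEntry(clause_id, field_name, term, doc.admission_id)
                break
        if hit is None:
            return False, []
        evidence.append(hit)
    if not evidence:  # a keyword test with zero groups matches nothing
        return False, []
    return True, evidence


def evaluate_definition(doc: EMRDocument, defn: PhenotypeDefinition) -> PhenotypeCall:
    """Evaluate the full definition logic on one admission.

    Evidence collects the entries of every true leaf that is not under a NOT
    (exclusion clauses explain a negative, not a positive, call).
    """
    env: dict[str, bool] = {}
    evidence_by_clause: dict[str, list[EvidenceEntry]] = {}
    for cid, clause in defn.clauses.items():
        ok, ev = evaluate_clause(doc, clause, cid)
        env[cid] = ok
        evidence_by_clause[cid] = ev
    flag = evaluate_logic(defn.logic, env)
    evidence: list[EvidenceEntry] = []
    if flag:
        for cid in sorted(positive_leaves(defn.logic)):
            if env[cid]:
                evidence.extend(evidence_by_clause[cid])
        if not evidence:
            # the logic fired purely through exclusion (NOT) clauses: attest
            # the absence that allowed it, so the call still carries a trace
            for cid in sorted(negative_leaves(defn.logic)):
                if not env[cid]:
                    evidence.append(
                        EvidenceEntry(
                            clause_id=cid,
                            field_name="*",
                            matched="<no match>",
                            admission_id=doc.admission_id,
                            leaf_value=False,
                        )
                    )
        if not evidence:  # degenerate tautological logic
            evidence.append(
                EvidenceEntry(
                    clause_id="<logic>",
                    field_name="*",
                    matched="<vacuous>",
                    admission_id=doc.admission_id,
                )
            )
    return PhenotypeCall(
        patient_id=doc.patient_id, condition=defn.name, flag=flag, evidence=evidence
    )


@dataclass
class FlagMatrix:
    """Units × conditions boolean table with per-cell evidence references.

    ``table`` has one row per unit (patient or admission) in first-appearance
    order and exactly one 0/1 column per evaluated definition; no missing
    cells. ``evidence[(unit, condition)]`` lists the supporting entries.
    """

    table: pd.DataFrame
    evidence: dict[tuple[str, str], list[EvidenceEntry]]
    unit: str  # "patient" | "admission"

    def flags_for(self, condition: str) -> dict[str, bool]:
        return {u: bool(v) for u, v in self.table[condition].items()}


def run_extraction(
    corpus: Corpus,
    definitions: Iterable[PhenotypeDefinition],
    unit: str = "patient",
) -> FlagMatrix:
    """Batch-evaluate definitions over a corpus.

    At patient level a condition is flagged when any admission matches (OR
    over admissions); at admission level each admission is its own unit. Row
    order is first-appearance order; re-running yields identical output.
    """
    defs = list(definitions)
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate definition names: {dupes}")
    if unit not in ("patient", "admission"):
        raise ValueError(f"unit must be 'patient' or 'admission', got {unit!r}")

    if unit == "patient":
        row_ids = corpus.patient_ids
        groups = [(pid, corpus.admissions_of(pid)) for pid in row_ids]
    else:
        row_ids = [doc.admission_id for doc in corpus]
        groups = [(doc.admission_id, [doc]) for doc in corpus]

    data: dict[str, list[bool]] = {name: [] for name in names}
    evidence: dict[tuple[str, str], list[EvidenceEntry]] = {}
    for unit_id, docs in groups:
        for defn in defs:
            flag = False
            entries: list[EvidenceEntry] = []
            for doc in docs:
                call = evaluate_definition(doc, defn)
                if call.flag:
                    flag = True
                    entries.extend(call.evidence)
            data[defn.name].append(flag)
            evidence[(unit_id, defn.name)] = entries
    table = pd.DataFrame(data, index=pd.Index(row_ids, name=unit_id_name(unit)))
    return FlagMatrix(table=table, evidence=evidence, unit=unit)


def unit_id_name(unit: str) -> str:
    return "patient_id" if unit == "patient" else "admission_id"
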