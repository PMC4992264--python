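"""Shared fixtures: tiny documents, exemplar definitions, random generators."""

from __future__ import annotations

import random
import unicodedata

import pytest

from phenorule.definition_dsl import (
    KeywordGroup,
    PhenotypeDefinition,
    SearchClause,
    parse_logic,
)
from phenorule.emr_model import (
    Corpus,
    EMRDocument,
    FieldLocator,
    LabResult,
    Prescription,
    Section,
    SectionKind,
)
from phenorule.synthetic_corpus import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def plc_definition(registry):
    return registry["primary_liver_cancer"].definition


@pytest.fixture(scope="session")
def hbv_definition(registry):
    return registry["hepatitis_b"].definition


def make_document(
    patient_id: str = "P1",
    admission_id: str = "A1",
    diagnoses: list[str] | None = None,
    pathology: str | None = None,
    radiology: str | None = None,
    labs: list[LabResult] | None = None,
    drugs: list[str] | None = None,
) -> EMRDocument:
    sections: dict[SectionKind, Section] = {}
    if diagnoses:
        sections[SectionKind.ADMISSION_RECORD] = Section(
            text_fields={f"diagnosis_{i + 1:02d}": d for i, d in enumerate(diagnoses)}
        )
    if pathology is not None:
        sections[SectionKind.PATHOLOGY] = Section(text_fields={"conclusion": pathology})
    if radiology is not None:
        sections[SectionKind.RADIOLOGY] = Section(text_fields={"conclusion": radiology})
    if labs:
        sections[SectionKind.LAB_RESULTS] = Section(lab_results=labs)
    if drugs:
        sections[SectionKind.PRESCRIPTIONS] = Section(
            prescriptions=[Prescription(drug_name=d) for d in drugs]
        )
    return EMRDocument(
        patient_id=patient_id, admission_id=admission_id, sections=sections
    )


@pytest.fixture
def doc_factory():
    return make_document


# ---------------------------------------------------------------------------
# independent brute-force reference implementation (no shared code with the
# engine: raw loops over every term and every start offset)


def _norm(text: str) -> str:
    return unicodedata.normalize("NFKC", text).lower().strip()


def brute_substring(term: str, text: str) -> bool:
    term, text = _norm(term), _norm(text)
    if term == "":
        return True
    for start in range(len(text) - len(term) + 1):
        if text[start : start + len(term)] == term:
            return True
    return False


def brute_clause(doc: EMRDocument, clause: SearchClause) -> bool:
    if clause.numeric_test is not None:
        test = clause.numeric_test
        sec = doc.sections.get(SectionKind.LAB_RESULTS)
        if sec is None:
            return False
        candidates = [r for r in sec.lab_results if r.analyte == test.analyte]
        if not candidates:
            return False
        latest = max(enumerate(candidates), key=lambda ir: (ir[1].collected_at, ir[0]))[1]
        from phenorule.units import maybe_canonical

        value = maybe_canonical(latest.value, test.analyte, latest.unit)
        if test.comparator == "between":
            low, high = test.threshold
            return low <= value <= high
        t = float(test.threshold)
        return {
            "<": value < t,
            "<=": value <= t,
            ">": value > t,
            ">=": value >= t,
            "=": value == t,
        }[test.comparator]
    if clause.presence_test is not None:
        sec = doc.sections.get(SectionKind.PRESCRIPTIONS)
        if sec is None:
            return False
        return any(
            brute_substring(term, rx.drug_name)
            for rx in sec.prescriptions
            for term in clause.presence_test.terms
        )
    sec = doc.sections.get(clause.locator.section)
    if sec is None:
        return False
    texts = [
        t
        for name, t in sec.text_fields.items()
        if t and clause.locator.matches_field(name)
    ]
    groups = clause.keyword_groups or ()
    if not groups:
        return False
    return all(
        any(brute_substring(term, text) for text in texts for term in group.terms)
        for group in groups
    )


def brute_logic(node, env):
    from phenorule.definition_dsl import And, Const, Leaf, Not, Or

    if isinstance(node, Leaf):
        return env[node.clause_id]
    if isinstance(node, Const):
        return node.value
    if isinstance(node, Not):
        return not brute_logic(node.child, env)
    if isinstance(node, And):
        return all(brute_logic(c, env) for c in node.children)
    if isinstance(node, Or):
        return any(brute_logic(c, env) for c in node.children)
    raise TypeError(node)


def brute_definition(doc: EMRDocument, defn: PhenotypeDefinition) -> bool:
    env = {cid: brute_clause(doc, c) for cid, c in defn.clauses.items()}
    return brute_logic(defn.logic, env)


def brute_patient_flags(corpus: Corpus, defn: PhenotypeDefinition) -> dict[str, bool]:
    flags: dict[str, bool] = {}
    for doc in corpus:
        flags[doc.patient_id] = flags.get(doc.patient_id, False) or brute_definition(
            doc, defn
        )
    return flags


# ---------------------------------------------------------------------------
# random corpus + definition generators for equivalence testing


TERMS = [
    "肝癌",
    "原发性肝癌",
    "肝硬化",
    "乙型肝炎",
    "腹水",
    "脂肪肝",
    "肝性脑病",
    "hbv",
    "HCC。",
    "食管静脉曲张",
]
FILLER = ["慢性胃炎", "高血压病", "未见明显异常", "糖尿病", "胆囊结石", ""]


def random_document(rng: random.Random, patient_id: str, admission_id: str) -> EMRDocument:
    sections: dict[SectionKind, Section] = {}
    vocabulary = TERMS + FILLER
    if rng.random() < 0.9:
        n = rng.randint(1, 6)
        sections[SectionKind.ADMISSION_RECORD] = Section(
            text_fields={
                f"diagnosis_{i + 1:02d}": rng.choice(vocabulary) for i in range(n)
            }
        )
    if rng.random() < 0.5:
        sections[SectionKind.PATHOLOGY] = Section(
            text_fields={"conclusion": " ".join(rng.choices(vocabulary, k=2))}
        )
    if rng.random() < 0.5:
        sections[SectionKind.RADIOLOGY] = Section(
            text_fields={"conclusion": rng.choice(vocabulary)}
        )
    if rng.random() < 0.6:
        sections[SectionKind.LAB_RESULTS] = Section(
            lab_results=[
                LabResult(
                    analyte=rng.choice(["TBIL", "ALB", "CREA"]),
                    value=round(rng.uniform(0.2, 30.0), 2),
                    unit="mg/dL" if rng.random() < 0.5 else "umol/L",
                    collected_at=f"2013-01-{rng.randint(1, 28):02d}T{rng.randint(0, 23):02d}:00:00",
                )
                for _ in range(rng.randint(1, 4))
            ]
        )
    if rng.random() < 0.4:
        sections[SectionKind.PRESCRIPTIONS] = Section(
            prescriptions=[
                Prescription(drug_name=rng.choice(["恩替卡韦", "维生素C", "奥美拉唑"]))
                for _ in range(rng.randint(1, 3))
            ]
        )
    return EMRDocument(
        patient_id=patient_id, admission_id=admission_id, sections=sections
    )


def random_corpus(rng: random.Random, n_docs: int) -> Corpus:
    corpus = Corpus()
    n_patients = max(1, n_docs // 2)
    for i in range(n_docs):
        pid = f"P{rng.randint(1, n_patients):04d}"
        corpus.add(random_document(rng, pid, f"A{i:05d}"))
    return corpus


def random_clause(rng: random.Random) -> SearchClause:
    kind = rng.random()
    if kind < 0.6:
        section = rng.choice(
            [SectionKind.ADMISSION_RECORD, SectionKind.PATHOLOGY, SectionKind.RADIOLOGY]
        )
        pattern = "diagnosis_*" if section == SectionKind.ADMISSION_RECORD else "conclusion"
        groups = tuple(
            KeywordGroup(tuple(rng.sample(TERMS, rng.randint(1, 3))))
            for _ in range(rng.randint(1, 2))
        )
        return SearchClause(
            locator=FieldLocator(section=section, field_pattern=pattern, channel="text"),
            keyword_groups=groups,
        )
    if kind < 0.8:
        from phenorule.definition_dsl import NumericTest

        comparator = rng.choice(["<", "<=", ">", ">=", "between"])
        threshold = (
            tuple(sorted((rng.uniform(0.5, 5.0), rng.uniform(0.5, 5.0))))
            if comparator == "between"
            else round(rng.uniform(0.5, 5.0), 2)
        )
        return SearchClause(
            locator=FieldLocator(section=SectionKind.LAB_RESULTS, channel="lab"),
            numeric_test=NumericTest(
                analyte=rng.choice(["TBIL", "ALB", "CREA"]),
                comparator=comparator,
                threshold=threshold,
            ),
        )
    return SearchClause(
        locator=FieldLocator(section=SectionKind.PRESCRIPTIONS, channel="prescription"),
        presence_test=KeywordGroup(tuple(rng.sample(["恩替卡韦", "维生素C", "奥美拉唑"], 2))),
    )


def random_logic_text(rng: random.Random, clause_ids: list[str]) -> str:
    def expr(depth: int) -> str:
        if depth == 0 or rng.random() < 0.4:
            return rng.choice(clause_ids)
        op = rng.choice(["AND", "OR"])
        left, right = expr(depth - 1), expr(depth - 1)
        node = f"({left} {op} {right})"
        if rng.random() < 0.25:
            node = f"NOT {node}"
        return node

    return expr(2)


def random_definition(rng: random.Random, name: str) -> PhenotypeDefinition:
    n_clauses = rng.randint(1, 6)
    clauses = {f"c{i}": random_clause(rng) for i in range(n_clauses)}
    logic = parse_logic(random_logic_text(rng, list(clauses)))
    diag = {cid for cid, c in clauses.items() if c.is_diagnosis_clause()}
    if len(diag) == len(clauses):
        architecture = "diagnosis_only"
    elif not diag:
        architecture = "evidence_only"
    else:
        architecture = "combined"
    return PhenotypeDefinition(
        name=name, architecture=architecture, clauses=clauses, logic=logic
    )
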