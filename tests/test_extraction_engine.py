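"""Keyword matching, clause/definition evaluation, batch extraction."""

from __future__ import annotations

import random

import pytest

from phenorule.definition_dsl import (
    KeywordGroup,
    NumericTest,
    SearchClause,
    parse_definition,
)
from phenorule.emr_model import Corpus, FieldLocator, LabResult, SectionKind
from phenorule.extraction_engine import (
    evaluate_clause,
    evaluate_definition,
    match_keywords,
    run_extraction,
)

from conftest import (
    brute_definition,
    brute_patient_flags,
    brute_substring,
    make_document,
    random_corpus,
    random_definition,
)


class TestMatchKeywords:
    def test_substring_containment(self):
        assert match_keywords("原发性肝癌可能性大", KeywordGroup(("肝癌",)))

    def test_empty_text_never_matches(self):
        assert not match_keywords("", KeywordGroup(("肝癌",)))

    def test_width_and_case_normalization(self):
        # full-width Latin and punctuation unify with half-width; case folds
        assert match_keywords("诊断：ＨＢＶ感染", KeywordGroup(("hbv",)))
        assert match_keywords("HCC．", KeywordGroup(("hcc.",)))  # full-width stop

    def test_no_tokenization(self):
        # matches inside longer words: substring semantics, not word match
        assert match_keywords("酒精性肝硬化失代偿期", KeywordGroup(("肝硬化",)))

    def test_agrees_with_brute_force_offset_scan(self):
        rng = random.Random(5)
        alphabet = "肝癌硬化腹水乙型abcABC。，"
        for _ in range(300):
            text = "".join(rng.choices(alphabet, k=rng.randint(0, 12)))
            terms = tuple(
                "".join(rng.choices(alphabet, k=rng.randint(1, 4)))
                for _ in range(rng.randint(1, 3))
            )
            group = KeywordGroup(terms)
            expected = any(brute_substring(t, text) for t in terms)
            assert match_keywords(text, group) == expected


class TestEvaluateClause:
    def test_pathology_clause_yields_evidence(self):
        doc = make_document(pathology="（肝穿刺）肝细胞癌")
        clause = SearchClause(
            locator=FieldLocator(section=SectionKind.PATHOLOGY, field_pattern="conclusion"),
            keyword_groups=(KeywordGroup(("肝细胞癌",)),),
        )
        flag, evidence = evaluate_clause(doc, clause, "path")
        assert flag
        assert evidence[0].field_name == "conclusion"
        assert evidence[0].matched == "肝细胞癌"

    def test_missing_lab_is_false_not_error(self):
        doc = make_document(diagnoses=["肝硬化"])
        clause = SearchClause(
            locator=FieldLocator(section=SectionKind.LAB_RESULTS, channel="lab"),
            numeric_test=NumericTest(analyte="ALB", comparator="<", threshold=2.8),
        )
        assert evaluate_clause(doc, clause) == (False, [])

    def test_lab_clause_converts_units(self):
        doc = make_document(
            labs=[LabResult(analyte="ALB", value=25.0, unit="g/L",
                            collected_at="2013-01-01T08:00:00")]
        )
        clause = SearchClause(
            locator=FieldLocator(section=SectionKind.LAB_RESULTS, channel="lab"),
            numeric_test=NumericTest(analyte="ALB", comparator="<", threshold=2.8),
        )
        flag, evidence = evaluate_clause(doc, clause)
        assert flag  # 25 g/L = 2.5 g/dL < 2.8
        assert evidence[0].admission_id == "A1"

    def test_and_groups_may_match_different_fields(self):
        doc = make_document(diagnoses=["肝硬化失代偿", "大量腹水"])
        clause = SearchClause(
            locator=FieldLocator(
                section=SectionKind.ADMISSION_RECORD, field_pattern="diagnosis_*"
            ),
            keyword_groups=(KeywordGroup(("肝硬化",)), KeywordGroup(("腹水",))),
        )
        flag, evidence = evaluate_clause(doc, clause)
        assert flag
        assert {e.field_name for e in evidence} == {"diagnosis_01", "diagnosis_02"}

    def test_prescription_presence(self):
        doc = make_document(drugs=["恩替卡韦分散片"])
        clause = SearchClause(
            locator=FieldLocator(section=SectionKind.PRESCRIPTIONS, channel="prescription"),
            presence_test=KeywordGroup(("恩替卡韦",)),
        )
        flag, evidence = evaluate_clause(doc, clause)
        assert flag and evidence[0].matched == "恩替卡韦"


EXCLUSION_SPEC = """
name: plc_excl
architecture: combined
clauses:
  dx:
    section: ADMISSION_RECORD
    fields: 'diagnosis_*'
    keywords: [["肝癌"]]
  mets:
    section: PATHOLOGY
    fields: conclusion
    keywords: [["转移性"]]
logic: dx AND NOT mets
"""


class TestEvaluateDefinition:
    def test_non_matching_document_is_false(self, plc_definition):
        doc = make_document(diagnoses=["肝硬化"])
        call = evaluate_definition(doc, plc_definition)
        assert not call.flag and call.evidence == []

    def test_exclusion_dominates(self):
        defn = parse_definition(EXCLUSION_SPEC)
        doc = make_document(diagnoses=["肝癌"], pathology="转移性腺癌")
        assert not evaluate_definition(doc, defn).flag
        doc2 = make_document(diagnoses=["肝癌"], pathology="肝细胞癌")
        assert evaluate_definition(doc2, defn).flag

    def test_positive_call_has_replayable_evidence(self, plc_definition):
        doc = make_document(diagnoses=["原发性肝癌"], pathology="肝细胞癌")
        call = evaluate_definition(doc, plc_definition)
        assert call.flag and call.evidence
        for entry in call.evidence:
            clause = plc_definition.clauses[entry.clause_id]
            flag, _ = evaluate_clause(doc, clause, entry.clause_id)
            assert flag  # each cited clause re-derives as true

    def test_matches_brute_force_on_random_documents(self):
        rng = random.Random(99)
        corpus = random_corpus(rng, 150)
        defs = [random_definition(rng, f"d{i}") for i in range(5)]
        for doc in corpus:
            for defn in defs:
                assert evaluate_definition(doc, defn).flag == brute_definition(doc, defn)


class TestRunExtraction:
    def test_any_admission_rule(self, plc_definition):
        corpus = Corpus(
            [
                make_document("P1", "A1", diagnoses=["原发性肝癌"]),
                make_document("P1", "A2", diagnoses=["慢性胃炎"]),
                make_document("P2", "A3", diagnoses=["慢性胃炎"]),
            ]
        )
        matrix = run_extraction(corpus, [plc_definition], unit="patient")
        assert matrix.flags_for("primary_liver_cancer") == {"P1": True, "P2": False}

    def test_admission_unit(self, plc_definition):
        corpus = Corpus(
            [
                make_document("P1", "A1", diagnoses=["原发性肝癌"]),
                make_document("P1", "A2", diagnoses=["慢性胃炎"]),
            ]
        )
        matrix = run_extraction(corpus, [plc_definition], unit="admission")
        assert matrix.flags_for("primary_liver_cancer") == {"A1": True, "A2": False}

    def test_empty_definition_list(self):
        corpus = Corpus([make_document("P1", "A1")])
        matrix = run_extraction(corpus, [])
        assert matrix.table.shape == (1, 0)

    def test_duplicate_names_rejected(self, plc_definition):
        corpus = Corpus([make_document("P1", "A1")])
        with pytest.raises(ValueError, match="duplicate"):
            run_extraction(corpus, [plc_definition, plc_definition])

    def test_shuffle_invariance(self):
        rng = random.Random(17)
        corpus = random_corpus(rng, 60)
        defs = [random_definition(rng, f"d{i}") for i in range(3)]
        matrix = run_extraction(corpus, defs)
        shuffled_docs = list(corpus)
        rng.shuffle(shuffled_docs)
        matrix2 = run_extraction(Corpus(shuffled_docs), defs)
        t1 = matrix.table.sort_index()
        t2 = matrix2.table.sort_index()
        assert t1.equals(t2)

    def test_rerun_identical(self):
        rng = random.Random(23)
        corpus = random_corpus(rng, 40)
        defs = [random_definition(rng, "d0")]
        m1 = run_extraction(corpus, defs)
        m2 = run_extraction(corpus, defs)
        assert m1.table.equals(m2.table)


class TestMonotonicity:
    def test_adding_term_never_unmatches(self):
        rng = random.Random(31)
        corpus = random_corpus(rng, 80)
        group = KeywordGroup(("肝癌",))
        wider = KeywordGroup(("肝癌", "腹水"))
        clause = SearchClause(
            locator=FieldLocator(
                section=SectionKind.ADMISSION_RECORD, field_pattern="diagnosis_*"
            ),
            keyword_groups=(group,),
        )
        wider_clause = SearchClause(
            locator=clause.locator, keyword_groups=(wider,)
        )
        for doc in corpus:
            before, _ = evaluate_clause(doc, clause)
            after, _ = evaluate_clause(doc, wider_clause)
            assert after or not before

    def test_adding_or_branch_never_unflags(self, plc_definition, registry):
        rng = random.Random(37)
        corpus = random_corpus(rng, 80)
        # diagnosis-only restriction vs full OR of three clauses
        from phenorule.definition_dsl import derive_variants

        diag_only = derive_variants(plc_definition)[0]
        for doc in corpus:
            narrow = evaluate_definition(doc, diag_only).flag
            wide = evaluate_definition(doc, plc_definition).flag
            assert wide or not narrow

    def test_patient_flags_match_brute_force(self):
        rng = random.Random(43)
        corpus = random_corpus(rng, 100)
        defs = [random_definition(rng, f"d{i}") for i in range(4)]
        matrix = run_extraction(corpus, defs)
        for defn in defs:
            assert matrix.flags_for(defn.name) == brute_patient_flags(corpus, defn)
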