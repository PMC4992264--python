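"""Document model, corpus I/O and field access."""

from __future__ import annotations

import json
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenorule.emr_model import (
    Corpus,
    CorpusError,
    EMRDocument,
    FieldLocator,
    LabResult,
    Section,
    SectionKind,
    get_texts,
    latest_lab,
    load_corpus,
    save_corpus,
)

from conftest import make_document, random_corpus


# --- strategies -------------------------------------------------------------

_text = st.text(
    alphabet=st.characters(
        codec="utf-8", exclude_categories=("Cs", "Cc")
    ),
    max_size=20,
)
_field_name = st.sampled_from(
    [f"diagnosis_{i:02d}" for i in range(1, 6)] + ["conclusion", "chief_complaint"]
)


@st.composite
def documents(draw, idx: int):
    sections = {}
    for kind in draw(
        st.sets(
            st.sampled_from(
                [
                    SectionKind.ADMISSION_RECORD,
                    SectionKind.PATHOLOGY,
                    SectionKind.RADIOLOGY,
                ]
            ),
            max_size=3,
        )
    ):
        sections[kind] = Section(
            text_fields=draw(st.dictionaries(_field_name, _text, max_size=4))
        )
    if draw(st.booleans()):
        sections[SectionKind.LAB_RESULTS] = Section(
            lab_results=[
                LabResult(
                    analyte=draw(st.sampled_from(["TBIL", "ALB"])),
                    value=draw(
                        st.floats(
                            min_value=0.1, max_value=500, allow_nan=False
                        )
                    ),
                    unit="mg/dL",
                    collected_at=f"2013-01-{draw(st.integers(1, 28)):02d}T10:00:00",
                )
                for _ in range(draw(st.integers(0, 3)))
            ]
        )
    return EMRDocument(
        patient_id=f"P{draw(st.integers(1, 5))}",
        admission_id=f"A{idx}",
        admit_date="2013-01-01",
        discharge_date="2013-01-10",
        sections=sections,
    )


@st.composite
def corpora(draw):
    n = draw(st.integers(0, 8))
    return Corpus([draw(documents(i)) for i in range(n)])


# --- corpus I/O -------------------------------------------------------------


class TestCorpusIO:
    def test_count_preserved(self, tmp_path):
        corpus = Corpus(
            [make_document("P1", "A1", ["肝硬化"]), make_document("P1", "A2"),
             make_document("P2", "A3", ["腹水"])]
        )
        path = tmp_path / "c.jsonl"
        save_corpus(corpus, path)
        assert len(load_corpus(path)) == 3

    def test_empty_file_is_empty_corpus(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert len(load_corpus(path)) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        good = json.dumps({"patient_id": "P1", "admission_id": "A1"})
        path.write_text(good + "\n{not json\n")
        with pytest.raises(CorpusError, match="line 2"):
            load_corpus(path)

    def test_duplicate_admission_names_both_lines(self, tmp_path):
        path = tmp_path / "dup.jsonl"
        line = json.dumps({"patient_id": "P1", "admission_id": "A1"})
        path.write_text(line + "\n" + line + "\n")
        with pytest.raises(CorpusError, match=r"lines 1 and 2"):
            load_corpus(path)

    @settings(max_examples=40, deadline=None)
    @given(corpus=corpora())
    def test_round_trip_lossless(self, corpus, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "c.jsonl"
        save_corpus(corpus, path)
        loaded = load_corpus(path)
        assert [d.model_dump() for d in loaded] == [d.model_dump() for d in corpus]
        # a second write is byte-identical (fixed key order)
        path2 = tmp_path_factory.mktemp("rt") / "c2.jsonl"
        save_corpus(loaded, path2)
        assert path.read_text() == path2.read_text()

    def test_unknown_section_preserved_in_extra_bucket(self, tmp_path):
        doc = {
            "patient_id": "P1",
            "admission_id": "A1",
            "sections": {"NURSING_NOTES": {"text_fields": {"note": "术后护理"}}},
        }
        path = tmp_path / "c.jsonl"
        path.write_text(json.dumps(doc, ensure_ascii=False) + "\n")
        loaded = load_corpus(path)
        assert loaded.documents[0].extra_sections["NURSING_NOTES"].text_fields == {
            "note": "术后护理"
        }
        out = tmp_path / "out.jsonl"
        save_corpus(loaded, out)
        assert "NURSING_NOTES" in out.read_text()

    def test_patient_grouping_preserves_order_and_multiset(self):
        rng = random.Random(7)
        corpus = random_corpus(rng, 40)
        seen = []
        for pid in corpus.patient_ids:
            for doc in corpus.admissions_of(pid):
                assert doc.patient_id == pid
                seen.append(doc.admission_id)
        assert sorted(seen) == sorted(d.admission_id for d in corpus)


class TestDocumentInvariants:
    def test_empty_ids_rejected(self):
        with pytest.raises(ValueError):
            EMRDocument(patient_id="", admission_id="A1")

    def test_admit_after_discharge_rejected(self):
        with pytest.raises(ValueError, match="admit_date"):
            EMRDocument(
                patient_id="P1",
                admission_id="A1",
                admit_date="2013-02-01",
                discharge_date="2013-01-01",
            )

    def test_unparsable_dates_tolerated(self):
        doc = EMRDocument(
            patient_id="P1", admission_id="A1", admit_date="春节前", discharge_date=None
        )
        assert doc.admit_date == "春节前"  # raw string kept


# --- get_texts --------------------------------------------------------------


class TestGetTexts:
    def test_matches_populated_diagnosis_fields(self):
        doc = make_document(diagnoses=["肝硬化", "腹水", "乙型肝炎"])
        locator = FieldLocator(
            section=SectionKind.ADMISSION_RECORD, field_pattern="diagnosis_*"
        )
        pairs = get_texts(doc, locator)
        assert [name for name, _ in pairs] == [
            "diagnosis_01",
            "diagnosis_02",
            "diagnosis_03",
        ]

    def test_absent_section_yields_empty(self):
        doc = make_document()
        locator = FieldLocator(section=SectionKind.PATHOLOGY, field_pattern="*")
        assert get_texts(doc, locator) == []

    def test_glob_containment(self):
        locator = FieldLocator(
            section=SectionKind.ADMISSION_RECORD, field_pattern="diagnosis_*"
        )
        assert locator.matches_field("diagnosis_01")
        assert not locator.matches_field("chief_complaint")

    def test_pure_and_independent_of_unrelated_sections(self):
        locator = FieldLocator(
            section=SectionKind.ADMISSION_RECORD, field_pattern="diagnosis_*"
        )
        doc1 = make_document(diagnoses=["肝硬化"], pathology="未见异常")
        doc2 = make_document(diagnoses=["肝硬化"])
        assert get_texts(doc1, locator) == get_texts(doc2, locator)
        assert get_texts(doc1, locator) == get_texts(doc1, locator)


# --- latest_lab -------------------------------------------------------------


def _lab(analyte, value, ts):
    return LabResult(analyte=analyte, value=value, unit="mg/dL", collected_at=ts)


class TestLatestLab:
    def test_later_result_wins(self):
        doc = make_document(
            labs=[_lab("TBIL", 1.0, "2013-01-01T08:00:00"),
                  _lab("TBIL", 2.0, "2013-01-02T08:00:00")]
        )
        assert latest_lab(doc, "TBIL").value == 2.0

    def test_absent_analyte(self):
        doc = make_document(labs=[_lab("TBIL", 1.0, "2013-01-01T08:00:00")])
        assert latest_lab(doc, "NA") is None

    def test_tie_break_last_in_input_order(self):
        doc = make_document(
            labs=[_lab("TBIL", 1.0, "2013-01-01T08:00:00"),
                  _lab("TBIL", 9.0, "2013-01-01T08:00:00")]
        )
        assert latest_lab(doc, "TBIL").value == 9.0

    def test_shuffled_agrees_with_brute_force_scan(self):
        rng = random.Random(42)
        stamps = [f"2013-01-{d:02d}T{h:02d}:00:00" for d, h in
                  zip(rng.sample(range(1, 28), 10), range(10))]
        labs = [_lab("ALB", float(i), ts) for i, ts in enumerate(stamps)]
        rng.shuffle(labs)
        doc = make_document(labs=labs)
        # brute force: max by parsed timestamp
        expected = max(labs, key=lambda r: r.collected_at)
        assert latest_lab(doc, "ALB").value == expected.value
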