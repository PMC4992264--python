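"""Semi-structured EMR document model and corpus I/O.

The document model mirrors the layout of a Chinese hospital EMR: one record per
admission, composed of named sections (front page, admission/discharge records,
lab results, radiology/pathology reports, prescriptions, cost records, ...).
Sections mix structured drop-down fields with free-text fields; the admission
record carries up to 40 enumerated diagnosis text fields. Multiple admissions
of one patient are linked by an opaque patient identifier.

Corpora are exchanged as JSON-lines (UTF-8, one admission per line); the
schema ships with the repository as ``schemas/corpus.schema.json``.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

MAX_DIAGNOSIS_FIELDS = 40
_DIAGNOSIS_FIELD_RE = re.compile(r"^diagnosis_(\d{2})$")


class SectionKind(str, Enum):
    """Closed set of known EMR section names.

    Unknown section names encountered in input files are preserved verbatim in
    the document's ``extra_sections`` bucket; they are never silently dropped.
    """

    FRONT_PAGE = "FRONT_PAGE"
    ADMISSION_RECORD = "ADMISSION_RECORD"
    DISCHARGE_RECORD = "DISCHARGE_RECORD"
    SURGERY_RECORD = "SURGERY_RECORD"
    DEATH_RECORD = "DEATH_RECORD"
    LAB_RESULTS = "LAB_RESULTS"
    RADIOLOGY = "RADIOLOGY"
    PATHOLOGY = "PATHOLOGY"
    PHYSICIAN_NOTES = "PHYSICIAN_NOTES"
    COST_RECORD = "COST_RECORD"
    PRESCRIPTIONS = "PRESCRIPTIONS"


#: Sections whose enumerated ``diagnosis_NN`` text fields hold physician
#: diagnoses (as opposed to supporting clinical evidence).
DIAGNOSIS_SECTIONS = frozenset(
    {SectionKind.FRONT_PAGE, SectionKind.ADMISSION_RECORD, SectionKind.DISCHARGE_RECORD}
)


class LabResult(BaseModel):
    """One structured laboratory measurement."""

    analyte: str
    value: float
    unit: str
    collected_at: str  # ISO-8601 timestamp

    @field_validator("analyte")
    @classmethod
    def _canonical_analyte(cls, v: str) -> str:
        v = v.strip().upper()
        if not v:
            raise ValueError("analyte must be non-empty")
        return v

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError("lab value must be finite")
        return v

    @field_validator("unit")
    @classmethod
    def _unit_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("unit must be non-empty")
        return v


class Prescription(BaseModel):
    """One drug order; only the free-text drug name is guaranteed."""

    drug_name: str
    start_date: Optional[str] = None

    @field_validator("drug_name")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("drug_name must be non-empty")
        return v


class Section(BaseModel):
    """One EMR section: structured fields, free-text fields, labs, drugs.

    ``text_fields`` may contain any Unicode, including Chinese characters and
    full-width punctuation.
    """

    structured_fields: dict[str, Union[str, int, float, bool, None]] = Field(
        default_factory=dict
    )
    text_fields: dict[str, str] = Field(default_factory=dict)
    lab_results: list[LabResult] = Field(default_factory=list)
    prescriptions: list[Prescription] = Field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.structured_fields
            or self.text_fields
            or self.lab_results
            or self.prescriptions
        )


def parse_date(raw: Optional[str]) -> Optional[_dt.date]:
    """Parse an ISO-8601 date, returning None (with a warning) when unparsable.

    Records with unparsable dates keep the raw string and are excluded from
    temporal operations.
    """
    if raw is None:
        return None
    try:
        return _dt.date.fromisoformat(raw[:10])
    except ValueError:
        logger.warning("unparsable date %r; excluded from temporal operations", raw)
        return None


def parse_timestamp(raw: str) -> Optional[_dt.datetime]:
    try:
        return _dt.datetime.fromisoformat(raw)
    except ValueError:
        logger.warning("unparsable timestamp %r; excluded from temporal operations", raw)
        return None


class EMRDocument(BaseModel):
    """One admission's semi-structured record.

    Any section may be absent — documentation is incomplete in real EMRs, and
    every reader tolerates absence.
    """

    patient_id: str
    admission_id: str
    admit_date: Optional[str] = None
    discharge_date: Optional[str] = None
    sections: dict[SectionKind, Section] = Field(default_factory=dict)
    extra_sections: dict[str, Section] = Field(default_factory=dict)

    @field_validator("patient_id", "admission_id")
    @classmethod
    def _ids_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("identifier must be non-empty")
        return v

    @model_validator(mode="after")
    def _date_order(self) -> "EMRDocument":
        a = parse_date(self.admit_date)
        d = parse_date(self.discharge_date)
        if a is not None and d is not None and a > d:
            raise ValueError(
                f"admit_date {self.admit_date} after discharge_date {self.discharge_date}"
            )
        return self

    @model_validator(mode="after")
    def _diagnosis_field_limit(self) -> "EMRDocument":
        for kind in DIAGNOSIS_SECTIONS:
            sec = self.sections.get(kind)
            if sec is None:
                continue
            n = sum(1 for f in sec.text_fields if _DIAGNOSIS_FIELD_RE.match(f))
            if n > MAX_DIAGNOSIS_FIELDS:
                raise ValueError(
                    f"{kind.value} has {n} diagnosis fields; at most "
                    f"{MAX_DIAGNOSIS_FIELDS} are supported"
                )
        return self

    def section(self, kind: SectionKind) -> Optional[Section]:
        return self.sections.get(kind)


class FieldLocator(BaseModel):
    """Addresses a set of fields within one section of a document.

    ``field_pattern`` is either a literal field name or a glob in which ``*``
    matches any run of characters within the field name (no other
    metacharacters are interpreted). Matching is deterministic.
    """

    section: SectionKind
    field_pattern: str = "*"
    channel: str = "text"  # one of {text, structured, lab, prescription}

    @field_validator("channel")
    @classmethod
    def _known_channel(cls, v: str) -> str:
        if v not in {"text", "structured", "lab", "prescription"}:
            raise ValueError(f"unknown channel {v!r}")
        return v

    def matches_field(self, name: str) -> bool:
        return _glob_match(self.field_pattern, name)

    def literal_prefix(self) -> str:
        """The pattern's literal text before the first ``*``."""
        return self.field_pattern.split("*", 1)[0]


def _glob_match(pattern: str, name: str) -> bool:
    # '*' matches any run of characters; everything else is literal.
    regex = ".*".join(re.escape(part) for part in pattern.split("*"))
    return re.fullmatch(regex, name) is not None


class CorpusError(ValueError):
    """Raised for malformed corpus files (line numbers included)."""


class Corpus:
    """An ordered collection of admissions grouped by patient.

    Per-patient grouping preserves input order; the multiset of admission ids
    is preserved from the source file.
    """

    def __init__(self, documents: Iterable[EMRDocument] = ()):
        self.documents: list[EMRDocument] = []
        self._by_patient: dict[str, list[EMRDocument]] = {}
        self._admission_index: dict[str, EMRDocument] = {}
        for doc in documents:
            self.add(doc)

    def add(self, doc: EMRDocument) -> None:
        if doc.admission_id in self._admission_index:
            raise CorpusError(f"duplicate admission_id {doc.admission_id!r}")
        self.documents.append(doc)
        self._by_patient.setdefault(doc.patient_id, []).append(doc)
        self._admission_index[doc.admission_id] = doc

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[EMRDocument]:
        return iter(self.documents)

    @property
    def patient_ids(self) -> list[str]:
        """Patient ids in first-appearance order."""
        return list(self._by_patient)

    def admissions_of(self, patient_id: str) -> list[EMRDocument]:
        return list(self._by_patient.get(patient_id, []))

    def get_admission(self, admission_id: str) -> Optional[EMRDocument]:
        return self._admission_index.get(admission_id)


# ---------------------------------------------------------------------------
# serialization


def _document_to_jsonable(doc: EMRDocument) -> dict:
    out: dict = {
        "patient_id": doc.patient_id,
        "admission_id": doc.admission_id,
        "admit_date": doc.admit_date,
        "discharge_date": doc.discharge_date,
        "sections": {},
    }
    # fixed key order for diffability: known sections in enum order, then extras
    for kind in SectionKind:
        if kind in doc.sections:
            out["sections"][kind.value] = _section_to_jsonable(doc.sections[kind])
    for name in sorted(doc.extra_sections):
        out["sections"][name] = _section_to_jsonable(doc.extra_sections[name])
    return out


def _section_to_jsonable(sec: Section) -> dict:
    out: dict = {}
    if sec.structured_fields:
        out["structured_fields"] = {
            k: sec.structured_fields[k] for k in sorted(sec.structured_fields)
        }
    if sec.text_fields:
        out["text_fields"] = {k: sec.text_fields[k] for k in sorted(sec.text_fields)}
    if sec.lab_results:
        out["lab_results"] = [
            {
                "analyte": r.analyte,
                "value": r.value,
                "unit": r.unit,
                "collected_at": r.collected_at,
            }
            for r in sec.lab_results
        ]
    if sec.prescriptions:
        out["prescriptions"] = [
            {"drug_name": p.drug_name, "start_date": p.start_date}
            for p in sec.prescriptions
        ]
    return out


def document_from_jsonable(data: dict) -> EMRDocument:
    sections: dict[SectionKind, Section] = {}
    extra: dict[str, Section] = {}
    for name, raw in (data.get("sections") or {}).items():
        sec = Section.model_validate(raw)
        try:
            sections[SectionKind(name)] = sec
        except ValueError:
            extra[name] = sec  # unknown name: preserved verbatim
    return EMRDocument(
        patient_id=data["patient_id"],
        admission_id=data["admission_id"],
        admit_date=data.get("admit_date"),
        discharge_date=data.get("discharge_date"),
        sections=sections,
        extra_sections=extra,
    )


def load_corpus(path: Union[str, Path]) -> Corpus:
    """Read a JSON-lines corpus file (one admission per line).

    Raises :class:`CorpusError` naming the line number for a malformed line and
    naming both lines for a duplicate admission id. Blank lines are skipped;
    the document count equals the count of non-blank lines.
    """
    corpus = Corpus()
    seen_lines: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                data = json.loads(line)
                doc = document_from_jsonable(data)
            except Exception as exc:
                raise CorpusError(f"line {lineno}: malformed document: {exc}") from exc
            if doc.admission_id in seen_lines:
                raise CorpusError(
                    f"duplicate admission_id {doc.admission_id!r} on lines "
                    f"{seen_lines[doc.admission_id]} and {lineno}"
                )
            seen_lines[doc.admission_id] = lineno
            corpus.add(doc)
    return corpus


def save_corpus(corpus: Corpus, path: Union[str, Path]) -> None:
    """Write a corpus as JSON-lines with a fixed key order (diff-friendly)."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps(_document_to_jsonable(doc), ensure_ascii=False))
            fh.write("\n")


# ---------------------------------------------------------------------------
# field access


def get_texts(doc: EMRDocument, locator: FieldLocator) -> list[tuple[str, str]]:
    """All populated text fields matched by the locator, in field-name order.

    A missing section yields an empty list — absence is a valid state, never an
    error. The function is pure: its output depends only on the located
    section's text fields.
    """
    if locator.channel != "text":
        raise ValueError(f"get_texts requires a text locator, got {locator.channel!r}")
    sec = doc.sections.get(locator.section)
    if sec is None:
        return []
    return [
        (name, sec.text_fields[name])
        for name in sorted(sec.text_fields)
        if sec.text_fields[name] and locator.matches_field(name)
    ]


def latest_lab(doc: EMRDocument, analyte: str) -> Optional[LabResult]:
    """The lab result with the latest ``collected_at`` for the analyte.

    Returns None when the analyte was never measured. Results with unparsable
    timestamps are excluded. When two results share the latest timestamp the
    last one in input order wins and a warning is logged.
    """
    sec = doc.sections.get(SectionKind.LAB_RESULTS)
    if sec is None:
        return None
    code = analyte.strip().upper()
    best: Optional[LabResult] = None
    best_ts: Optional[_dt.datetime] = None
    tie = False
    for result in sec.lab_results:
        if result.analyte != code:
            continue
        ts = parse_timestamp(result.collected_at)
        if ts is None:
            continue
        if best_ts is None or ts > best_ts:
            best, best_ts, tie = result, ts, False
        elif ts == best_ts:
            best, tie = result, True  # deterministic: last in input order
    if tie:
        logger.warning(
            "admission %s: tied timestamps for %s; using last in input order",
            doc.admission_id,
            code,
        )
    return best
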