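"""Synthetic EMR corpus generator with known ground truth.

The generator emulates the layout of a semi-structured Chinese hospital EMR —
front page, admission/discharge records with enumerated diagnosis fields,
radiology/pathology conclusive sentences, structured labs, prescriptions and a
cost record — and plants condition-specific keywords according to registered
case-definition templates:

* each patient's conditions are drawn independently with the configured
  prevalence (defaults reflect a liver-specialty inpatient case mix);
* a true condition leaves its keyword in one of the fields its definition
  targets with probability ``doc_sensitivity`` (imperfect physician
  documentation);
* a false condition's keyword appears anyway with probability
  ``spurious_rate`` (documentation noise, e.g. rule-out mentions).

Distractor text is drawn from a small packaged lexicon that is disjoint (as
substrings, after matching normalization) from every registered keyword, so
false positives arise only from configured spurious planting. Generation is
fully reproducible from the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .definition_dsl import PhenotypeDefinition, parse_definition
from .emr_model import (
    Corpus,
    EMRDocument,
    LabResult,
    Prescription,
    Section,
    SectionKind,
)
from .extraction_engine import normalize_text, run_extraction
from .validation import ValidityReport, confusion, validity_report

#: Condition prevalences of the default study population (liver-specialty
#: inpatients; proportions of patients carrying each condition).
DEFAULT_PREVALENCE: dict[str, float] = {
    "primary_liver_cancer": 0.213,
    "cirrhosis": 0.327,
    "hepatitis_b": 0.451,
    "hepatitis_c": 0.089,
    "fatty_liver": 0.040,
    "alcoholic_liver_disease": 0.071,
    "spontaneous_bacterial_peritonitis": 0.149,
    "variceal_hemorrhage": 0.044,
    "hepatorenal_syndrome": 0.011,
    "hepatic_encephalopathy": 0.089,
    "ascites": 0.276,
}

DEFAULT_DOC_SENSITIVITY = 0.9
DEFAULT_SPURIOUS_RATE = 0.02

#: Liver-clinic distractor phrases; guaranteed disjoint (as substrings) from
#: every registered keyword — verified by :func:`check_lexicon_disjoint`.
DISTRACTOR_DIAGNOSES = (
    "慢性胃炎",
    "上呼吸道感染",
    "高血压病3级",
    "2型糖尿病",
    "胆囊结石",
    "泌尿系感染",
    "贫血原因待查",
    "腰椎间盘突出症",
    "冠状动脉粥样硬化性心脏病",
    "慢性支气管炎",
)
DISTRACTOR_CONCLUSIONS = (
    "未见明显异常",
    "双肺纹理增多",
    "胆囊壁毛糙",
    "慢性炎症改变",
)
DISTRACTOR_DRUGS = ("维生素C片", "奥美拉唑肠溶胶囊", "阿司匹林肠溶片", "复方甘草酸苷片")


@dataclass(frozen=True)
class PlantRoute:
    """One way a documented condition leaves its trace in the record.

    kind: 'diagnosis' (term into a free diagnosis field), 'pathology' /
    'radiology' (term appended to the conclusive sentence), 'prescription'
    (drug added to the order list), or 'lab' (a result beyond the definition's
    threshold; payload is the term/drug or ``(analyte, value, unit)``).
    """

    kind: str
    payload: Union[str, tuple[str, float, str]]


@dataclass(frozen=True)
class ConditionTemplate:
    """A case definition plus the planting routes that satisfy it."""

    definition: PhenotypeDefinition
    routes: tuple[PlantRoute, ...]


def _load_packaged_definition(name: str) -> PhenotypeDefinition:
    text = resources.files("phenorule.data").joinpath(f"{name}.yaml").read_text(
        encoding="utf-8"
    )
    return parse_definition(text)


def _diagnosis_only_definition(name: str, terms: tuple[str, ...]) -> PhenotypeDefinition:
    return parse_definition(
        yaml_text_for_diagnosis_only(name, terms)
    )


def yaml_text_for_diagnosis_only(name: str, terms: tuple[str, ...]) -> str:
    import json

    return (
        f"name: {name}\n"
        "architecture: diagnosis_only\n"
        "clauses:\n"
        "  dx:\n"
        "    section: ADMISSION_RECORD\n"
        "    fields: 'diagnosis_*'\n"
        "    channel: text\n"
        f"    keywords: [{json.dumps(list(terms), ensure_ascii=False)}]\n"
        "logic: dx\n"
    )


_SIMPLE_CONDITIONS: dict[str, tuple[str, ...]] = {
    "cirrhosis": ("肝硬化",),
    "hepatitis_c": ("丙型病毒性肝炎", "丙型肝炎", "丙肝"),
    "fatty_liver": ("脂肪肝",),
    "alcoholic_liver_disease": ("酒精性肝病",),
    "spontaneous_bacterial_peritonitis": ("自发性细菌性腹膜炎",),
    "variceal_hemorrhage": ("食管胃底静脉曲张破裂出血", "静脉曲张破裂出血"),
    "hepatic_encephalopathy": ("肝性脑病",),
    "ascites": ("腹水",),
}

_HRS_YAML = """
name: hepatorenal_syndrome
architecture: combined
clauses:
  dx:
    section: ADMISSION_RECORD
    fields: 'diagnosis_*'
    channel: text
    keywords: [["肝肾综合征"]]
  crea_high:
    section: LAB_RESULTS
    channel: lab
    analyte: CREA
    comparator: ">="
    threshold: 2.5
logic: dx OR crea_high
"""


def default_registry() -> dict[str, ConditionTemplate]:
    """Templates for the default condition panel.

    Primary liver cancer and hepatitis B use the packaged combined exemplar
    definitions (multiple planting routes, so diagnosis-only and
    evidence-only variants are distinguishable); hepatorenal syndrome
    exercises the lab channel; the remaining conditions are diagnosis-only.
    """
    registry: dict[str, ConditionTemplate] = {}
    registry["primary_liver_cancer"] = ConditionTemplate(
        definition=_load_packaged_definition("primary_liver_cancer"),
        routes=(
            PlantRoute("diagnosis", "原发性肝癌"),
            PlantRoute("pathology", "肝细胞癌"),
            PlantRoute("radiology", "肝脏恶性肿瘤"),
        ),
    )
    registry["hepatitis_b"] = ConditionTemplate(
        definition=_load_packaged_definition("hepatitis_b"),
        routes=(
            PlantRoute("diagnosis", "乙型病毒性肝炎"),
            PlantRoute("prescription", "恩替卡韦"),
        ),
    )
    registry["hepatorenal_syndrome"] = ConditionTemplate(
        definition=parse_definition(_HRS_YAML),
        routes=(
            PlantRoute("diagnosis", "肝肾综合征"),
            PlantRoute("lab", ("CREA", 283.0, "umol/L")),  # 3.2 mg/dL
        ),
    )
    for name, terms in _SIMPLE_CONDITIONS.items():
        registry[name] = ConditionTemplate(
            definition=_diagnosis_only_definition(name, terms),
            routes=(PlantRoute("diagnosis", terms[0]),),
        )
    return registry


def registry_keywords(registry: dict[str, ConditionTemplate]) -> set[str]:
    terms: set[str] = set()
    for template in registry.values():
        for clause in template.definition.clauses.values():
            for group in clause.keyword_groups or ():
                terms.update(group.terms)
            if clause.presence_test is not None:
                terms.update(clause.presence_test.terms)
    return terms


def check_lexicon_disjoint(registry: Optional[dict[str, ConditionTemplate]] = None) -> None:
    """Assert no distractor phrase contains any registered keyword."""
    registry = registry or default_registry()
    keywords = {normalize_text(t) for t in registry_keywords(registry)}
    lexicon = DISTRACTOR_DIAGNOSES + DISTRACTOR_CONCLUSIONS + DISTRACTOR_DRUGS
    for phrase in lexicon:
        norm = normalize_text(phrase)
        for kw in keywords:
            if kw in norm:
                raise AssertionError(
                    f"distractor {phrase!r} contains registered keyword {kw!r}"
                )


class AdmissionsSpec(BaseModel):
    """Distribution of admissions per patient: fixed n, or 1 + Poisson(lam)."""

    kind: str = "fixed"
    n: int = 1
    lam: float = 0.0

    @field_validator("kind")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in ("fixed", "one_plus_poisson"):
            raise ValueError("kind must be 'fixed' or 'one_plus_poisson'")
        return v

    def draw(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return max(1, self.n)
        return 1 + int(rng.poisson(self.lam))


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic corpus. The seed is mandatory."""

    n_patients: int = 450
    prevalence: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    doc_sensitivity: dict[str, float] | float = DEFAULT_DOC_SENSITIVITY
    spurious_rate: dict[str, float] | float = DEFAULT_SPURIOUS_RATE
    admissions_per_patient: AdmissionsSpec = Field(default_factory=AdmissionsSpec)
    seed: int

    @field_validator("n_patients")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_patients must be >= 1")
        return v

    @field_validator("prevalence")
    @classmethod
    def _probabilities(cls, v: dict[str, float]) -> dict[str, float]:
        for name, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{name}] must be in [0, 1], got {p}")
        return v

    def sens_of(self, condition: str) -> float:
        if isinstance(self.doc_sensitivity, dict):
            return self.doc_sensitivity.get(condition, DEFAULT_DOC_SENSITIVITY)
        return self.doc_sensitivity

    def spurious_of(self, condition: str) -> float:
        if isinstance(self.spurious_rate, dict):
            return self.spurious_rate.get(condition, DEFAULT_SPURIOUS_RATE)
        return self.spurious_rate


@dataclass
class SyntheticTruth:
    """Patient-level ground-truth labels plus the config that produced them."""

    labels: dict[str, dict[str, bool]]
    config: GeneratorConfig

    def condition_labels(self, condition: str) -> dict[str, bool]:
        return {pid: flags[condition] for pid, flags in self.labels.items()}

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["patient_id", "condition", "label"])
            for pid, flags in self.labels.items():
                for condition, label in flags.items():
                    writer.writerow([pid, condition, int(label)])


def load_truth(path: Union[str, Path]) -> dict[str, dict[str, bool]]:
    """Read a reference-label table (patient_id, condition, label in {0,1})."""
    labels: dict[str, dict[str, bool]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            labels.setdefault(row["patient_id"], {})[row["condition"]] = bool(
                int(row["label"])
            )
    return labels


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# document assembly


def _baseline_labs(rng: np.random.Generator, collected_at: str) -> list[LabResult]:
    # Chinese-lab units; values centred well inside normal ranges so lab-based
    # clauses fire only on planted values.
    draws = {
        "ALB": (float(rng.normal(42.0, 3.0)), "g/L"),
        "TBIL": (float(rng.normal(14.0, 3.0)), "umol/L"),
        "CREA": (float(rng.normal(72.0, 10.0)), "umol/L"),
        "NA": (float(rng.normal(139.0, 2.0)), "mmol/L"),
        "INR": (float(rng.normal(1.05, 0.05)), ""),
        "PT": (float(rng.normal(12.0, 0.6)), "s"),
    }
    return [
        LabResult(
            analyte=analyte,
            value=round(max(value, 0.1), 2),
            unit=unit or "ratio",
            collected_at=collected_at,
        )
        for analyte, (value, unit) in draws.items()
    ]


def _build_admission(
    patient_id: str,
    admission_id: str,
    rng: np.random.Generator,
    planted_routes: list[PlantRoute],
) -> EMRDocument:
    admit = f"2012-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 28)):02d}"
    stay = int(rng.integers(3, 21))
    month, day = int(admit[5:7]), int(admit[8:10])
    # keep the discharge date a simple same-month offset
    discharge = f"2012-{month:02d}-{min(day + stay, 28):02d}"

    diagnoses: list[str] = []
    pathology_terms: list[str] = []
    radiology_terms: list[str] = []
    drugs: list[str] = list(rng.choice(DISTRACTOR_DRUGS, size=int(rng.integers(0, 3))))
    labs = _baseline_labs(rng, collected_at=f"{admit}T08:00:00")

    for route in planted_routes:
        if route.kind == "diagnosis":
            diagnoses.append(str(route.payload))
        elif route.kind == "pathology":
            pathology_terms.append(str(route.payload))
        elif route.kind == "radiology":
            radiology_terms.append(str(route.payload))
        elif route.kind == "prescription":
            drugs.append(str(route.payload))
        elif route.kind == "lab":
            analyte, value, unit = route.payload  # type: ignore[misc]
            labs.append(
                LabResult(
                    analyte=analyte,
                    value=value,
                    unit=unit,
                    collected_at=f"{admit}T16:00:00",
                )
            )
        else:  # pragma: no cover - registry is validated upstream
            raise ConfigError(f"unknown plant route kind {route.kind!r}")

    # one diagnosis field per diagnosis; distractors fill the remaining slots
    n_distract = int(rng.integers(1, 5))
    diagnoses += list(rng.choice(DISTRACTOR_DIAGNOSES, size=n_distract, replace=False))
    diagnosis_fields = {
        f"diagnosis_{i + 1:02d}": text for i, text in enumerate(diagnoses)
    }

    sections: dict[SectionKind, Section] = {
        SectionKind.FRONT_PAGE: Section(
            structured_fields={
                "sex": "male" if rng.random() < 0.52 else "female",
                "age": int(rng.integers(18, 80)),
            }
        ),
        SectionKind.ADMISSION_RECORD: Section(
            text_fields={
                **diagnosis_fields,
                "chief_complaint": str(rng.choice(DISTRACTOR_CONCLUSIONS)),
            }
        ),
        SectionKind.DISCHARGE_RECORD: Section(
            text_fields={"discharge_summary": str(rng.choice(DISTRACTOR_CONCLUSIONS))}
        ),
        SectionKind.LAB_RESULTS: Section(lab_results=labs),
        SectionKind.RADIOLOGY: Section(
            text_fields={
                "conclusion": "，".join(
                    radiology_terms or [str(rng.choice(DISTRACTOR_CONCLUSIONS))]
                )
            }
        ),
        SectionKind.COST_RECORD: Section(
            structured_fields={"total_cost": round(float(rng.gamma(2.0, 4000.0)), 2)}
        ),
    }
    if pathology_terms:
        sections[SectionKind.PATHOLOGY] = Section(
            text_fields={"conclusion": "，".join(pathology_terms)}
        )
    if drugs:
        sections[SectionKind.PRESCRIPTIONS] = Section(
            prescriptions=[Prescription(drug_name=d) for d in drugs]
        )
    return EMRDocument(
        patient_id=patient_id,
        admission_id=admission_id,
        admit_date=admit,
        discharge_date=discharge,
        sections=sections,
    )


def generate_corpus(
    config: GeneratorConfig,
    registry: Optional[dict[str, ConditionTemplate]] = None,
) -> tuple[Corpus, SyntheticTruth]:
    """Generate a corpus and its ground truth, reproducibly from the seed."""
    registry = registry or default_registry()
    missing = sorted(set(config.prevalence) - set(registry))
    if missing:
        raise ConfigError(
            f"conditions configured without a registered planting template: {missing}"
        )
    rng = np.random.default_rng(config.seed)
    corpus = Corpus()
    labels: dict[str, dict[str, bool]] = {}
    conditions = list(config.prevalence)

    for i in range(config.n_patients):
        pid = f"P{i + 1:06d}"
        truth = {c: bool(rng.random() < config.prevalence[c]) for c in conditions}
        labels[pid] = truth
        n_adm = config.admissions_per_patient.draw(rng)

        # decide documentation per condition, then assign to an admission
        planted: dict[int, list[PlantRoute]] = {k: [] for k in range(n_adm)}
        for condition in conditions:
            documented = (
                rng.random() < config.sens_of(condition)
                if truth[condition]
                else rng.random() < config.spurious_of(condition)
            )
            if documented:
                routes = registry[condition].routes
                route = routes[int(rng.integers(0, len(routes)))]
                planted[int(rng.integers(0, n_adm))].append(route)

        for k in range(n_adm):
            corpus.add(
                _build_admission(pid, f"{pid}-A{k + 1}", rng, planted[k])
            )
    return corpus, SyntheticTruth(labels=labels, config=config)


@dataclass
class BenchmarkResult:
    """Per-condition validity of the registered definitions on synthetic truth."""

    reports: dict[str, ValidityReport]
    truth: SyntheticTruth
    config: GeneratorConfig


def benchmark_run(
    config: GeneratorConfig,
    registry: Optional[dict[str, ConditionTemplate]] = None,
) -> BenchmarkResult:
    """Generate → extract → validate, at patient level."""
    registry = registry or default_registry()
    corpus, truth = generate_corpus(config, registry)
    definitions = [registry[c].definition for c in config.prevalence]
    matrix = run_extraction(corpus, definitions, unit="patient")
    reports: dict[str, ValidityReport] = {}
    for condition in config.prevalence:
        cm = confusion(
            matrix.flags_for(registry[condition].definition.name),
            truth.condition_labels(condition),
        )
        reports[condition] = validity_report(cm)
    return BenchmarkResult(reports=reports, truth=truth, config=config)
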