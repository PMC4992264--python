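"""Liver-disease severity indexes: Child-Pugh, MELD, MELD-Na, configurable 5vMELD.

Conventions (declared, because published variants differ):

* **MELD** uses the UNOS formulation: creatinine, bilirubin and INR floored at
  1.0, creatinine capped at 4.0 mg/dL, value = 10·(0.957·ln(Cr) +
  0.378·ln(TBIL) + 1.120·ln(INR) + 0.643), rounded to the nearest integer
  (half up).
* **MELD-Na** is the additive form MELD + 1.59·(135 − Na) with sodium clamped
  to [120, 135] mmol/L; the sum is reported unrounded.
* **Child-Pugh** middle bands are closed: 2 ≤ TBIL ≤ 3 mg/dL scores 2 points,
  and analogously for albumin, INR and PT prolongation.
* **5vMELD** is a generic configurable linear score over per-variable ln or
  identity transforms with clamps; no default coefficient set is shipped —
  supply one (an example file that reproduces standard MELD is included under
  ``phenorule/data/meld_coefficients.yaml``).

Inputs are in canonical units: bilirubin and creatinine in mg/dL, albumin in
g/dL, sodium in mmol/L (see :mod:`phenorule.units` for conversions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Union

import yaml

from .units import convert_units, convert_from_canonical  # re-exported  # noqa: F401


class MissingInputError(ValueError):
    pass


class DomainError(ValueError):
    pass


class AscitesGrade(str, Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE_SEVERE = "moderate-severe"


class EncephalopathyGrade(str, Enum):
    NONE = "none"
    GRADE_1_2 = "grade1-2"
    GRADE_3_4 = "grade3-4"


@dataclass
class SeverityInputs:
    """The variables feeding the severity scores.

    Exactly one of ``inr`` or ``pt_prolong`` (prothrombin-time prolongation in
    seconds over control) is required for Child-Pugh coagulation scoring.
    """

    tbil: Optional[float] = None  # mg/dL
    alb: Optional[float] = None  # g/dL
    crea: Optional[float] = None  # mg/dL
    na: Optional[float] = None  # mmol/L
    inr: Optional[float] = None
    pt_prolong: Optional[float] = None  # seconds over control
    ascites_grade: Optional[AscitesGrade] = None
    he_grade: Optional[EncephalopathyGrade] = None

    def __post_init__(self) -> None:
        if isinstance(self.ascites_grade, str):
            self.ascites_grade = AscitesGrade(self.ascites_grade)
        if isinstance(self.he_grade, str):
            self.he_grade = EncephalopathyGrade(self.he_grade)
        for name in ("tbil", "alb", "crea", "na", "inr"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be positive, got {v}")


@dataclass
class SeverityScore:
    name: str
    value: float
    components: dict[str, float] = field(default_factory=dict)
    cp_class: Optional[str] = None  # Child-Pugh letter A/B/C


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _band(value: float, low: float, high: float) -> int:
    """1/2/3 points for best/middle/worst band with closed middle bounds."""
    if value < low:
        return 1
    if value <= high:
        return 2
    return 3


def child_pugh(inputs: SeverityInputs) -> SeverityScore:
    """Child-Pugh score: five components each 1–3 points, total 5–15.

    Bands: bilirubin <2 / 2–3 / >3 mg/dL; albumin >3.5 / 2.8–3.5 / <2.8 g/dL;
    INR <1.7 / 1.7–2.3 / >2.3 (or PT prolongation <4 / 4–6 / >6 s); ascites
    none/mild/moderate-severe; encephalopathy none / grade 1–2 / grade 3–4.
    Class A = 5–6 points, B = 7–9, C = 10–15.
    """
    required = {
        "tbil": inputs.tbil,
        "alb": inputs.alb,
        "ascites_grade": inputs.ascites_grade,
        "he_grade": inputs.he_grade,
    }
    for name, v in required.items():
        if v is None:
            raise MissingInputError(f"Child-Pugh requires {name}")
    if (inputs.inr is None) == (inputs.pt_prolong is None):
        raise MissingInputError(
            "Child-Pugh requires exactly one coagulation measure: inr or pt_prolong"
        )

    components: dict[str, float] = {}
    components["bilirubin"] = _band(inputs.tbil, 2.0, 3.0)
    # albumin bands run the other way: higher is better
    if inputs.alb > 3.5:
        components["albumin"] = 1
    elif inputs.alb >= 2.8:
        components["albumin"] = 2
    else:
        components["albumin"] = 3
    if inputs.inr is not None:
        components["coagulation"] = _band(inputs.inr, 1.7, 2.3)
    else:
        components["coagulation"] = _band(inputs.pt_prolong, 4.0, 6.0)
    components["ascites"] = {
        AscitesGrade.NONE: 1,
        AscitesGrade.MILD: 2,
        AscitesGrade.MODERATE_SEVERE: 3,
    }[inputs.ascites_grade]
    components["encephalopathy"] = {
        EncephalopathyGrade.NONE: 1,
        EncephalopathyGrade.GRADE_1_2: 2,
        EncephalopathyGrade.GRADE_3_4: 3,
    }[inputs.he_grade]

    total = int(sum(components.values()))
    if total <= 6:
        letter = "A"
    elif total <= 9:
        letter = "B"
    else:
        letter = "C"
    return SeverityScore(
        name="child_pugh", value=total, components=components, cp_class=letter
    )


def meld(crea: float, tbil: float, inr: float) -> SeverityScore:
    """UNOS MELD: labs floored at 1.0, creatinine capped at 4.0 mg/dL."""
    for name, v in (("crea", crea), ("tbil", tbil), ("inr", inr)):
        if v <= 0:
            raise DomainError(f"{name} must be positive, got {v}")
    c = min(max(crea, 1.0), 4.0)
    b = max(tbil, 1.0)
    i = max(inr, 1.0)
    raw = 10.0 * (0.957 * math.log(c) + 0.378 * math.log(b) + 1.120 * math.log(i) + 0.643)
    return SeverityScore(
        name="meld",
        value=_round_half_up(raw),
        components={
            "creatinine": 0.957 * math.log(c),
            "bilirubin": 0.378 * math.log(b),
            "inr": 1.120 * math.log(i),
            "raw": raw,
        },
    )


def meld_na(meld_value: float, na: float) -> SeverityScore:
    """Additive MELD-Na: MELD + 1.59·(135 − Na), Na clamped to [120, 135]."""
    if na <= 0:
        raise DomainError(f"na must be positive, got {na}")
    clamped = min(max(na, 120.0), 135.0)
    value = meld_value + 1.59 * (135.0 - clamped)
    return SeverityScore(
        name="meld_na",
        value=value,
        components={"meld": meld_value, "na_clamped": clamped},
    )


# ---------------------------------------------------------------------------
# configurable five-variable MELD engine


class CoefficientError(ValueError):
    pass


def meld_5v(
    values: dict[str, float], coefficients: Union[dict, str]
) -> SeverityScore:
    """Generic configurable linear severity score.

    ``coefficients`` is a mapping (or YAML text) of the form::

        intercept: 6.43
        scale: 1.0            # multiplier applied to the whole sum
        round: false          # round half-up to integer when true
        terms:
          - variable: crea
            coefficient: 9.57
            transform: ln     # ln | identity
            clamp: [1.0, 4.0] # optional [low, high]; null disables a side

    Every configured variable must be present in ``values``.
    """
    if isinstance(coefficients, str):
        coefficients = yaml.safe_load(coefficients)
    if not isinstance(coefficients, dict) or "terms" not in coefficients:
        raise CoefficientError("coefficient config must be a mapping with 'terms'")
    total = float(coefficients.get("intercept", 0.0))
    components: dict[str, float] = {"intercept": total}
    for term in coefficients["terms"]:
        var = term["variable"]
        if var not in values:
            raise CoefficientError(f"coefficient config requires variable {var!r}")
        x = float(values[var])
        clamp = term.get("clamp")
        if clamp is not None:
            low, high = clamp
            if low is not None:
                x = max(x, float(low))
            if high is not None:
                x = min(x, float(high))
        transform = term.get("transform", "identity")
        if transform == "ln":
            if x <= 0:
                raise DomainError(f"ln transform requires positive {var}, got {x}")
            x = math.log(x)
        elif transform != "identity":
            raise CoefficientError(f"unknown transform {transform!r}")
        contribution = float(term["coefficient"]) * x
        components[var] = contribution
        total += contribution
    total *= float(coefficients.get("scale", 1.0))
    value: float = _round_half_up(total) if coefficients.get("round") else total
    return SeverityScore(name="meld_5v", value=value, components=components)
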