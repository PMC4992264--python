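"""Laboratory unit conversion to the canonical units used by severity scores.

Chinese hospital labs typically report bilirubin and creatinine in µmol/L and
albumin in g/L; the severity formulas expect mg/dL and g/dL. The conversion
table is deliberately small and explicit.
"""

from __future__ import annotations

# canonical unit per analyte
CANONICAL_UNITS: dict[str, str] = {
    "TBIL": "mg/dL",
    "CREA": "mg/dL",
    "ALB": "g/dL",
    "NA": "mmol/L",
    "INR": "",
    "PT": "s",
}

# (analyte, from_unit) -> multiplicative factor to the canonical unit
_FACTORS: dict[tuple[str, str], float] = {
    ("TBIL", "umol/L"): 1.0 / 17.1,
    ("CREA", "umol/L"): 1.0 / 88.4,
    ("ALB", "g/L"): 1.0 / 10.0,
}


def _norm_unit(unit: str) -> str:
    return unit.replace("µ", "u").replace("μ", "u").strip()


class UnitError(ValueError):
    pass


def supported_units(analyte: str) -> list[str]:
    analyte = analyte.upper()
    units = [CANONICAL_UNITS.get(analyte, "")]
    units += [u for (a, u) in _FACTORS if a == analyte]
    return units


def convert_units(value: float, analyte: str, from_unit: str) -> float:
    """Convert ``value`` of ``analyte`` from ``from_unit`` to the canonical unit.

    Raises :class:`UnitError` for an unknown unit, listing the supported ones.
    Converting to canonical and back is identity to 1e-9 relative.
    """
    analyte = analyte.strip().upper()
    unit = _norm_unit(from_unit)
    canonical = CANONICAL_UNITS.get(analyte)
    if canonical is not None and unit == _norm_unit(canonical):
        return value
    factor = _FACTORS.get((analyte, unit))
    if factor is None:
        raise UnitError(
            f"unknown unit {from_unit!r} for {analyte}; "
            f"supported: {supported_units(analyte)}"
        )
    return value * factor


def convert_from_canonical(value: float, analyte: str, to_unit: str) -> float:
    """Inverse of :func:`convert_units`."""
    analyte = analyte.strip().upper()
    unit = _norm_unit(to_unit)
    canonical = CANONICAL_UNITS.get(analyte)
    if canonical is not None and unit == _norm_unit(canonical):
        return value
    factor = _FACTORS.get((analyte, unit))
    if factor is None:
        raise UnitError(
            f"unknown unit {to_unit!r} for {analyte}; "
            f"supported: {supported_units(analyte)}"
        )
    return value / factor


def maybe_canonical(value: float, analyte: str, unit: str) -> float:
    """Best-effort conversion: unknown units pass the value through unchanged.

    Used by the extraction engine, where a lab clause should evaluate rather
    than fail when a site reports an unconverted unit.
    """
    try:
        return convert_units(value, analyte, unit)
    except UnitError:
        return value
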