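"""Charlson (CCI) and Elixhauser (ECI) comorbidity summaries.

Condition flags produced by the extraction engine are mapped to index
components through an editable table (``phenorule/data/comorbidity_map.tsv``).
The CCI is a weighted sum (weights 1/2/3/6); the ECI is a component count.
Hierarchy rules collapse mild/severe forms of the same disease (mild vs
moderate/severe liver disease, diabetes with vs without complications, any
malignancy vs metastatic solid tumor) so that only the severe form counts.

Age adjustment is not applied: the summaries reported here are comorbidity
counts and unadjusted weighted scores.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

logger = logging.getLogger(__name__)

CCI_WEIGHTS = frozenset({1, 2, 3, 6})

#: (mild component, severe component): when both are present only the severe
#: one counts.
HIERARCHY_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    "cci": (
        ("mild_liver_disease", "moderate_severe_liver_disease"),
        ("diabetes", "diabetes_with_complications"),
        ("any_malignancy", "metastatic_solid_tumor"),
    ),
    "eci": (
        ("diabetes_uncomplicated", "diabetes_complicated"),
        ("solid_tumor_without_metastasis", "metastatic_cancer"),
    ),
}

COUNT_CATEGORIES = ("0", "1", "2", "3 and more")


@dataclass
class ComorbidityMap:
    """condition → (component, weight) per index; loaded from a TSV table."""

    cci: dict[str, tuple[str, int]] = field(default_factory=dict)
    eci: dict[str, tuple[str, int]] = field(default_factory=dict)

    def for_index(self, index: str) -> dict[str, tuple[str, int]]:
        index = index.lower()
        if index not in ("cci", "eci"):
            raise ValueError(f"index must be 'cci' or 'eci', got {index!r}")
        return self.cci if index == "cci" else self.eci

    def unmapped(self, flags: dict[str, bool], index: str) -> list[str]:
        """Flag names that map to no component of the index (never ignored silently)."""
        mapped = self.for_index(index)
        return sorted(c for c in flags if c not in mapped)


def load_comorbidity_map(path: Optional[Union[str, Path]] = None) -> ComorbidityMap:
    """Load the condition→component table (the packaged default when path is None)."""
    if path is None:
        source = resources.files("phenorule.data").joinpath("comorbidity_map.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = [
        line for line in text.splitlines() if line.strip() and not line.startswith("#")
    ]
    reader = csv.DictReader(rows, delimiter="\t")
    cmap = ComorbidityMap()
    for row in reader:
        condition = row["condition"].strip()
        index = row["index"].strip().lower()
        component = row["component"].strip()
        weight = int(row["weight"])
        table = cmap.for_index(index)
        if index == "cci" and weight not in CCI_WEIGHTS:
            raise ValueError(
                f"CCI weight for {condition!r} must be one of {sorted(CCI_WEIGHTS)}, "
                f"got {weight}"
            )
        if condition in table:
            raise ValueError(
                f"condition {condition!r} maps to two components of {index}: "
                f"{table[condition][0]!r} and {component!r}"
            )
        table[condition] = (component, weight)
    return cmap


def _true_components(
    flags: dict[str, bool], mapping: dict[str, tuple[str, int]], index: str
) -> dict[str, int]:
    """Distinct true components with weights, after hierarchy collapsing."""
    components: dict[str, int] = {}
    for condition, (component, weight) in mapping.items():
        if flags.get(condition, False):
            components[component] = weight
    missing = [c for c in mapping if c not in flags]
    if missing:
        logger.warning("flags missing for mapped conditions (treated false): %s", missing)
    for mild, severe in HIERARCHY_PAIRS.get(index, ()):
        if mild in components and severe in components:
            del components[mild]
    return components


def cci_score(
    flags: dict[str, bool], cmap: Optional[ComorbidityMap] = None
) -> int:
    """Weighted Charlson score: sum of component weights over true flags.

    Monotone in the flags; the hierarchy rule ensures a mild and a severe form
    of the same disease never both contribute.
    """
    cmap = cmap or load_comorbidity_map()
    return sum(_true_components(flags, cmap.cci, "cci").values())


def comorbidity_count(
    flags: dict[str, bool], index: str, cmap: Optional[ComorbidityMap] = None
) -> tuple[int, str]:
    """Number of distinct true components and its reporting category.

    Categories band the count as 0 / 1 / 2 / "3 and more".
    """
    cmap = cmap or load_comorbidity_map()
    components = _true_components(flags, cmap.for_index(index), index.lower())
    count = len(components)
    category = COUNT_CATEGORIES[min(count, 3)]
    return count, category
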