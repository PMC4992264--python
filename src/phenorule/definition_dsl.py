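"""Declarative phenotype (case) definitions.

A case definition has three components, mirroring how rule-based EMR
phenotyping is constructed in hospitals without ICD coding:

1. **keyword groups** — lists of literal search terms (Chinese or Latin words,
   punctuation allowed); terms within a group are alternatives (OR), and a
   clause may require several groups jointly (AND);
2. **field locators** — which section and fields to search (the enumerated
   diagnosis fields, conclusive sentences of radiology/pathology reports,
   structured lab results, drug prescriptions);
3. **logic** — a boolean expression over named clauses; NOT encodes exclusion
   criteria.

Definitions come in three architectures: ``diagnosis_only`` (all clauses
target diagnosis fields of the front page / admission / discharge records),
``evidence_only`` (no clause does), and ``combined`` (at least one of each).

Definitions are authored as YAML (or equivalent JSON), one per file; the JSON
schema ships as ``schemas/definition.schema.json``.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from .emr_model import DIAGNOSIS_SECTIONS, FieldLocator, SectionKind

logger = logging.getLogger(__name__)

COMPARATORS = ("<", "<=", ">", ">=", "=", "between")
ARCHITECTURES = ("diagnosis_only", "evidence_only", "combined")


class DefinitionError(ValueError):
    """Base class for definition parsing/validation errors."""


class UnknownOperatorError(DefinitionError):
    pass


class DanglingClauseError(DefinitionError):
    pass


class EmptyKeywordGroupError(DefinitionError):
    pass


class ArchitectureMismatchError(DefinitionError):
    pass


class ClauseShapeError(DefinitionError):
    pass


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class KeywordGroup:
    """A group of alternative search terms; any term matching satisfies it.

    Terms are stored exactly as authored — no trimming inside terms, because
    punctuation and spacing can be part of a deliberate search phrase.
    """

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise EmptyKeywordGroupError("keyword group has no terms")
        if any(t == "" for t in self.terms):
            raise EmptyKeywordGroupError("keyword group contains an empty term")


@dataclass(frozen=True)
class NumericTest:
    """A comparison against the latest lab value of one analyte."""

    analyte: str
    comparator: str
    threshold: Union[float, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ClauseShapeError(
                f"unknown comparator {self.comparator!r}; allowed: {COMPARATORS}"
            )
        values = (
            self.threshold if isinstance(self.threshold, tuple) else (self.threshold,)
        )
        if self.comparator == "between" and len(values) != 2:
            raise ClauseShapeError("'between' requires two thresholds [low, high]")
        if self.comparator != "between" and len(values) != 1:
            raise ClauseShapeError(f"{self.comparator!r} requires one threshold")
        for v in values:
            if not (float("-inf") < float(v) < float("inf")):
                raise ClauseShapeError("thresholds must be finite")


@dataclass(frozen=True)
class SearchClause:
    """One test against one located region of the document.

    Exactly one of ``keyword_groups`` (text channel; every group must match
    within the located fields), ``numeric_test`` (lab channel) or
    ``presence_test`` (prescription channel: drug-name keywords) is set.
    """

    locator: FieldLocator
    keyword_groups: Optional[tuple[KeywordGroup, ...]] = None
    numeric_test: Optional[NumericTest] = None
    presence_test: Optional[KeywordGroup] = None

    def __post_init__(self) -> None:
        kinds = [
            self.keyword_groups is not None,
            self.numeric_test is not None,
            self.presence_test is not None,
        ]
        if sum(kinds) != 1:
            raise ClauseShapeError("exactly one test kind per clause")
        if self.numeric_test is not None and self.locator.channel != "lab":
            raise ClauseShapeError("numeric_test requires a lab-channel locator")
        if self.keyword_groups is not None and self.locator.channel != "text":
            raise ClauseShapeError("keyword_test requires a text-channel locator")
        if self.presence_test is not None and self.locator.channel != "prescription":
            raise ClauseShapeError(
                "presence_test requires a prescription-channel locator"
            )
        if self.keyword_groups is not None and not self.keyword_groups:
            raise EmptyKeywordGroupError("keyword_test requires at least one group")

    def is_diagnosis_clause(self) -> bool:
        """True when the clause targets enumerated diagnosis fields."""
        return (
            self.locator.channel == "text"
            and self.locator.section in DIAGNOSIS_SECTIONS
            and self.locator.literal_prefix().startswith("diagnosis")
        )


# ---------------------------------------------------------------------------
# logic expressions


@dataclass(frozen=True)
class Leaf:
    clause_id: str


@dataclass(frozen=True)
class Const:
    value: bool


@dataclass(frozen=True)
class Not:
    child: "LogicNode"


@dataclass(frozen=True)
class And:
    children: tuple["LogicNode", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["LogicNode", ...]


LogicNode = Union[Leaf, Const, Not, And, Or]


def logic_leaves(node: LogicNode) -> list[str]:
    if isinstance(node, Leaf):
        return [node.clause_id]
    if isinstance(node, Const):
        return []
    if isinstance(node, Not):
        return logic_leaves(node.child)
    out: list[str] = []
    for child in node.children:
        out.extend(logic_leaves(child))
    return out


def evaluate_logic(node: LogicNode, env: dict[str, bool]) -> bool:
    """Total evaluation: every leaf must resolve through ``env``."""
    if isinstance(node, Leaf):
        return env[node.clause_id]
    if isinstance(node, Const):
        return node.value
    if isinstance(node, Not):
        return not evaluate_logic(node.child, env)
    if isinstance(node, And):
        return all(evaluate_logic(c, env) for c in node.children)
    return any(evaluate_logic(c, env) for c in node.children)


def positive_leaves(node: LogicNode, under_not: bool = False) -> set[str]:
    """Leaves not under a NOT — the clauses whose matches count as evidence."""
    if isinstance(node, Leaf):
        return set() if under_not else {node.clause_id}
    if isinstance(node, Const):
        return set()
    if isinstance(node, Not):
        return positive_leaves(node.child, not under_not)
    out: set[str] = set()
    for child in node.children:
        out |= positive_leaves(child, under_not)
    return out


def negative_leaves(node: LogicNode, under_not: bool = False) -> set[str]:
    """Leaves that occur under a NOT (exclusion criteria)."""
    if isinstance(node, Leaf):
        return {node.clause_id} if under_not else set()
    if isinstance(node, Const):
        return set()
    if isinstance(node, Not):
        return negative_leaves(node.child, not under_not)
    out: set[str] = set()
    for child in node.children:
        out |= negative_leaves(child, under_not)
    return out


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_logic(text: str) -> LogicNode:
    """Parse a boolean expression over clause ids.

    Grammar (case-insensitive keywords, ``or`` binds loosest)::

        expr   := term (OR term)*
        term   := factor (AND factor)*
        factor := NOT factor | '(' expr ')' | TRUE | FALSE | identifier
    """
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def kw(tok: Optional[str]) -> str:
        return tok.lower() if tok is not None else ""

    def parse_expr() -> LogicNode:
        children = [parse_term()]
        while kw(peek()) == "or":
            take()
            children.append(parse_term())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def parse_term() -> LogicNode:
        children = [parse_factor()]
        while kw(peek()) == "and":
            take()
            children.append(parse_factor())
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_factor() -> LogicNode:
        tok = peek()
        if tok is None:
            raise UnknownOperatorError(f"unexpected end of logic expression: {text!r}")
        if kw(tok) == "not":
            take()
            return Not(parse_factor())
        if tok == "(":
            take()
            node = parse_expr()
            if peek() != ")":
                raise UnknownOperatorError(f"unbalanced parentheses in {text!r}")
            take()
            return node
        if kw(tok) in ("true", "false"):
            take()
            return Const(kw(tok) == "true")
        if tok == ")":
            raise UnknownOperatorError(f"unbalanced parentheses in {text!r}")
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", tok):
            raise UnknownOperatorError(f"unknown operator or token {tok!r} in {text!r}")
        take()
        return Leaf(tok)

    node = parse_expr()
    if pos != len(tokens):
        raise UnknownOperatorError(
            f"unknown operator or trailing token {tokens[pos]!r} in {text!r}"
        )
    return node


def logic_to_text(node: LogicNode) -> str:
    """Canonical textual form; ``parse_logic(logic_to_text(x))`` ≡ ``x``."""
    if isinstance(node, Leaf):
        return node.clause_id
    if isinstance(node, Const):
        return "TRUE" if node.value else "FALSE"
    if isinstance(node, Not):
        return f"NOT ({logic_to_text(node.child)})"
    op = " AND " if isinstance(node, And) else " OR "
    return "(" + op.join(logic_to_text(c) for c in node.children) + ")"


def simplify_logic(node: LogicNode) -> LogicNode:
    """Constant-fold TRUE/FALSE out of the tree."""
    if isinstance(node, (Leaf, Const)):
        return node
    if isinstance(node, Not):
        child = simplify_logic(node.child)
        if isinstance(child, Const):
            return Const(not child.value)
        return Not(child)
    children = [simplify_logic(c) for c in node.children]
    if isinstance(node, And):
        if any(isinstance(c, Const) and not c.value for c in children):
            return Const(False)
        children = [c for c in children if not isinstance(c, Const)]
        if not children:
            return Const(True)
        return children[0] if len(children) == 1 else And(tuple(children))
    if any(isinstance(c, Const) and c.value for c in children):
        return Const(True)
    children = [c for c in children if not isinstance(c, Const)]
    if not children:
        return Const(False)
    return children[0] if len(children) == 1 else Or(tuple(children))


# ---------------------------------------------------------------------------
# definitions


@dataclass
class PhenotypeDefinition:
    """A named, validated case definition."""

    name: str
    architecture: str
    clauses: dict[str, SearchClause]
    logic: LogicNode
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise DefinitionError(
                f"{self.name}: unknown architecture {self.architecture!r}; "
                f"allowed: {ARCHITECTURES}"
            )
        for leaf in logic_leaves(self.logic):
            if leaf not in self.clauses:
                raise DanglingClauseError(
                    f"{self.name}: logic references undeclared clause {leaf!r}"
                )
        self._check_architecture()

    def _check_architecture(self) -> None:
        diag = {cid for cid, c in self.clauses.items() if c.is_diagnosis_clause()}
        evid = set(self.clauses) - diag
        if self.architecture == "diagnosis_only" and evid:
            raise ArchitectureMismatchError(
                f"{self.name}: diagnosis_only definition has non-diagnosis "
                f"clauses {sorted(evid)}"
            )
        if self.architecture == "evidence_only" and diag:
            raise ArchitectureMismatchError(
                f"{self.name}: evidence_only definition has diagnosis "
                f"clauses {sorted(diag)}"
            )
        if self.architecture == "combined" and (not diag or not evid):
            raise ArchitectureMismatchError(
                f"{self.name}: combined definition requires at least one "
                f"diagnosis clause and one evidence clause"
            )


# --- parsing ---------------------------------------------------------------


def _clause_from_mapping(cid: str, raw: dict) -> SearchClause:
    try:
        section = SectionKind(raw["section"])
    except (KeyError, ValueError) as exc:
        raise ClauseShapeError(f"clause {cid!r}: bad or missing section: {exc}") from exc
    channel = raw.get("channel", "text")
    locator = FieldLocator(
        section=section, field_pattern=raw.get("fields", "*"), channel=channel
    )
    try:
        if channel == "lab":
            thr = raw["threshold"]
            threshold = tuple(float(v) for v in thr) if isinstance(thr, list) else float(thr)
            return SearchClause(
                locator=locator,
                numeric_test=NumericTest(
                    analyte=str(raw["analyte"]).upper(),
                    comparator=str(raw["comparator"]),
                    threshold=threshold,
                ),
            )
        if channel == "prescription":
            return SearchClause(
                locator=locator,
                presence_test=KeywordGroup(tuple(raw["drugs"])),
            )
        groups = tuple(KeywordGroup(tuple(g)) for g in raw.get("keywords", []))
        return SearchClause(locator=locator, keyword_groups=groups)
    except KeyError as exc:
        raise ClauseShapeError(f"clause {cid!r}: missing key {exc}") from exc
    except DefinitionError as exc:
        raise type(exc)(f"clause {cid!r}: {exc}") from exc


def definition_from_mapping(data: dict) -> PhenotypeDefinition:
    clauses = {
        str(cid): _clause_from_mapping(str(cid), raw)
        for cid, raw in (data.get("clauses") or {}).items()
    }
    logic = parse_logic(str(data.get("logic", "")))
    return PhenotypeDefinition(
        name=str(data["name"]),
        architecture=str(data.get("architecture", "combined")),
        clauses=clauses,
        logic=logic,
        provenance=str(data.get("provenance", "")),
    )


def parse_definition(spec_text: str) -> PhenotypeDefinition:
    """Parse a YAML/JSON definition document into a validated definition.

    parse → serialize → parse is idempotent: the second parse yields a
    definition whose serialization equals the first.
    """
    data = yaml.safe_load(spec_text)
    if not isinstance(data, dict):
        raise DefinitionError("definition document must be a mapping")
    return definition_from_mapping(data)


def load_definition(path) -> PhenotypeDefinition:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_definition(fh.read())


def definition_to_mapping(defn: PhenotypeDefinition) -> dict:
    clauses: dict[str, dict] = {}
    for cid, clause in defn.clauses.items():
        raw: dict = {
            "section": clause.locator.section.value,
            "fields": clause.locator.field_pattern,
            "channel": clause.locator.channel,
        }
        if clause.numeric_test is not None:
            t = clause.numeric_test
            raw["analyte"] = t.analyte
            raw["comparator"] = t.comparator
            raw["threshold"] = list(t.threshold) if isinstance(t.threshold, tuple) else t.threshold
        elif clause.presence_test is not None:
            raw["drugs"] = list(clause.presence_test.terms)
        else:
            raw["keywords"] = [list(g.terms) for g in clause.keyword_groups or ()]
        clauses[cid] = raw
    return {
        "name": defn.name,
        "architecture": defn.architecture,
        "provenance": defn.provenance,
        "clauses": clauses,
        "logic": logic_to_text(defn.logic),
    }


def serialize_definition(defn: PhenotypeDefinition) -> str:
    return yaml.safe_dump(
        definition_to_mapping(defn), allow_unicode=True, sort_keys=False
    )


# --- linting ---------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    code: str
    path: str
    message: str


#: Field names the lint pass knows to exist in each section, used to flag
#: locators that can never match anything.
KNOWN_FIELDS: dict[SectionKind, tuple[str, ...]] = {
    SectionKind.ADMISSION_RECORD: tuple(
        f"diagnosis_{i:02d}" for i in range(1, 41)
    ) + ("chief_complaint", "history_of_present_illness"),
    SectionKind.DISCHARGE_RECORD: tuple(
        f"diagnosis_{i:02d}" for i in range(1, 41)
    ) + ("discharge_summary",),
    SectionKind.FRONT_PAGE: tuple(f"diagnosis_{i:02d}" for i in range(1, 41)),
    SectionKind.RADIOLOGY: ("conclusion", "findings"),
    SectionKind.PATHOLOGY: ("conclusion", "findings"),
    SectionKind.PHYSICIAN_NOTES: ("note",),
    SectionKind.SURGERY_RECORD: ("procedure_name", "operative_note"),
    SectionKind.DEATH_RECORD: ("cause_of_death",),
}


def validate_definition(defn: PhenotypeDefinition) -> list[Issue]:
    """All invariant violations plus lint warnings; empty list means valid.

    This mechanizes the manual QA step of definition authoring: it flags
    duplicate terms, locators that match no known field (wrong search section
    or misspelt field name), unused clauses, and a NOT wrapping the whole
    logic tree (a definition that fires on absence of evidence).
    """
    issues: list[Issue] = []
    for cid, clause in defn.clauses.items():
        groups: list[KeywordGroup] = []
        if clause.keyword_groups:
            groups.extend(clause.keyword_groups)
        if clause.presence_test:
            groups.append(clause.presence_test)
        for gi, group in enumerate(groups):
            seen: set[str] = set()
            for term in group.terms:
                if term in seen:
                    issues.append(
                        Issue(
                            "warning",
                            "duplicate-term",
                            f"clauses.{cid}.keywords[{gi}]",
                            f"term {term!r} appears more than once in the group",
                        )
                    )
                seen.add(term)
        if clause.locator.channel == "text":
            known = KNOWN_FIELDS.get(clause.locator.section)
            if known and not any(clause.locator.matches_field(f) for f in known):
                issues.append(
                    Issue(
                        "warning",
                        "locator-matches-nothing",
                        f"clauses.{cid}.fields",
                        f"pattern {clause.locator.field_pattern!r} matches no "
                        f"known field of {clause.locator.section.value}",
                    )
                )
    used = set(logic_leaves(defn.logic))
    for cid in defn.clauses:
        if cid not in used:
            issues.append(
                Issue(
                    "warning",
                    "unused-clause",
                    f"clauses.{cid}",
                    "clause is declared but never referenced by the logic",
                )
            )
    if isinstance(defn.logic, Not):
        issues.append(
            Issue(
                "warning",
                "negated-root",
                "logic",
                "NOT applied to the whole tree: the definition fires on "
                "absence of evidence",
            )
        )
    return issues


# --- architecture variants -------------------------------------------------


def _prune(node: LogicNode, keep: set[str], context: str) -> LogicNode:
    """Replace leaves outside ``keep`` by the identity element of their context.

    ``context`` is 'and' or 'or': a removed leaf under AND becomes TRUE and
    under OR becomes FALSE, so the residual tree stays total. NOT flips the
    context of its child.
    """
    if isinstance(node, Leaf):
        if node.clause_id in keep:
            return node
        return Const(context == "and")
    if isinstance(node, Const):
        return node
    if isinstance(node, Not):
        flipped = "and" if context == "or" else "or"
        return Not(_prune(node.child, keep, flipped))
    ctx = "and" if isinstance(node, And) else "or"
    cls = And if isinstance(node, And) else Or
    return cls(tuple(_prune(c, keep, ctx) for c in node.children))


def derive_variants(defn: PhenotypeDefinition) -> list[PhenotypeDefinition]:
    """Derive the up-to-three architecture variants of a combined definition.

    Returns the diagnosis-only restriction, the evidence-only restriction and
    the original combined definition. A restriction whose pruned logic tree
    collapses to a constant is omitted with a warning.
    """
    if defn.architecture != "combined":
        raise DefinitionError(
            f"{defn.name}: variants are derived from combined definitions only"
        )
    diag = {cid for cid, c in defn.clauses.items() if c.is_diagnosis_clause()}
    evid = set(defn.clauses) - diag
    variants: list[PhenotypeDefinition] = []
    for arch, keep in (("diagnosis_only", diag), ("evidence_only", evid)):
        pruned = simplify_logic(_prune(defn.logic, keep, "or"))
        if isinstance(pruned, Const):
            logger.warning(
                "%s: %s variant omitted (logic collapses to %s)",
                defn.name,
                arch,
                pruned.value,
            )
            continue
        used = set(logic_leaves(pruned))
        variants.append(
            PhenotypeDefinition(
                name=f"{defn.name}__{arch}",
                architecture=arch,
                clauses={
                    cid: copy.deepcopy(c)
                    for cid, c in defn.clauses.items()
                    if cid in used
                },
                logic=pruned,
                provenance=defn.provenance,
            )
        )
    variants.append(defn)
    return variants
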