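"""RF2-dialect terminology loading and is-a reasoning services.

The terminology is a snapshot view: only active rows enter the is-a DAG and
the concept definitions; inactive rows are kept in a side index.  Ancestor
sets are computed over is-a edges only (attribute relationships are stored
separately as role-grouped definitions), are self-inclusive, and back both
subsumption checks and the shared-ancestor similarity measure.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

from . import ecl
from .expression import AttributePair
from .errors import (
    ConceptLookupError,
    TerminologyIntegrityError,
    TerminologyLoadError,
)
from .ids import is_well_formed

# Real SNOMED CT metadata identifiers; fixtures may override via LoadConfig.
IS_A = "116680003"
PRIMITIVE = "900000000000074008"
FULLY_DEFINED = "900000000000073002"
ROLE_GROUP = "609096000"
CONCEPT_MODEL_ATTRIBUTE = "410662002"


@dataclass(frozen=True)
class LoadConfig:
    """Knobs for reading an RF2-dialect snapshot."""

    isa_id: str = IS_A
    fully_defined_id: str = FULLY_DEFINED
    attribute_root: str = CONCEPT_MODEL_ATTRIBUTE
    check_digits: bool = False  # enable for real releases only


@dataclass(frozen=True)
class ConceptRecord:
    id: str
    fsn: str
    active: bool
    fully_defined: bool


@dataclass(frozen=True)
class RelationshipRecord:
    source_id: str
    type_id: str
    destination_id: str
    group: int
    active: bool


@dataclass(frozen=True)
class MrcmRule:
    """One declarative concept-model row for an attribute."""

    attribute_id: str
    domain_constraint: str
    range_constraint: str
    max_per_group: int | None = 1  # None = unbounded
    grouped_allowed: bool = True


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    element: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]


class Terminology:
    """A loaded snapshot: concepts, is-a DAG, role-grouped definitions."""

    def __init__(
        self,
        concepts: Mapping[str, ConceptRecord],
        relationships: Iterable[RelationshipRecord],
        config: LoadConfig = LoadConfig(),
    ):
        self.config = config
        self.concepts: dict[str, ConceptRecord] = {c.id: c for c in concepts.values() if c.active}
        self.inactive: dict[str, ConceptRecord] = {c.id: c for c in concepts.values() if not c.active}
        self.isa = nx.DiGraph()  # edge child -> parent
        self.isa.add_nodes_from(self.concepts)
        # definitions: id -> (ungrouped pairs, tuple of grouped pair-sets)
        ungrouped: dict[str, set[AttributePair]] = {}
        grouped: dict[str, dict[int, set[AttributePair]]] = {}
        for rel in relationships:
            if not rel.active:
                continue
            for cid, role in ((rel.source_id, "source"), (rel.destination_id, "destination"),
                              (rel.type_id, "type")):
                if cid not in self.concepts:
                    raise TerminologyIntegrityError(
                        f"relationship {role} id {cid} is not an active concept"
                    )
            if rel.type_id == config.isa_id:
                if rel.group != 0:
                    raise TerminologyIntegrityError(
                        f"is-a relationship {rel.source_id}->{rel.destination_id} "
                        f"has group {rel.group}, expected 0"
                    )
                self.isa.add_edge(rel.source_id, rel.destination_id)
            elif rel.group == 0:
                ungrouped.setdefault(rel.source_id, set()).add(
                    AttributePair(rel.type_id, rel.destination_id)
                )
            else:
                grouped.setdefault(rel.source_id, {}).setdefault(rel.group, set()).add(
                    AttributePair(rel.type_id, rel.destination_id)
                )
        if not nx.is_directed_acyclic_graph(self.isa):
            cycle = nx.find_cycle(self.isa)
            raise TerminologyIntegrityError(f"is-a cycle: {cycle}")
        roots = [n for n in self.isa.nodes if self.isa.out_degree(n) == 0]
        if len(roots) != 1:
            raise TerminologyIntegrityError(f"expected exactly one root, found {sorted(roots)}")
        self.root_id: str = roots[0]
        self.definitions: dict[str, tuple[frozenset, tuple]] = {}
        for cid in self.concepts:
            u = frozenset(ungrouped.get(cid, ()))
            g = tuple(
                frozenset(pairs)
                for _, pairs in sorted(grouped.get(cid, {}).items())
            )
            if u or g:
                self.definitions[cid] = (u, g)
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- lookups ---------------------------------------------------------

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def record(self, concept_id: str) -> ConceptRecord:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise ConceptLookupError(f"unknown or inactive concept {concept_id}") from None

    def fsn(self, concept_id: str) -> str:
        return self.record(concept_id).fsn

    def is_fully_defined(self, concept_id: str) -> bool:
        return self.record(concept_id).fully_defined

    def parents(self, concept_id: str) -> frozenset[str]:
        self.record(concept_id)
        return frozenset(self.isa.successors(concept_id))

    def children(self, concept_id: str) -> frozenset[str]:
        self.record(concept_id)
        return frozenset(self.isa.predecessors(concept_id))

    def definition(self, concept_id: str) -> tuple[frozenset, tuple]:
        """Ungrouped pairs and groups defining a concept (may be empty)."""
        self.record(concept_id)
        return self.definitions.get(concept_id, (frozenset(), ()))

    def attribute_ids(self) -> frozenset[str]:
        """Active concepts inside the attribute subtree."""
        root = self.config.attribute_root
        if root not in self.concepts:
            return frozenset()
        return frozenset(c for c in self.concepts if self.is_subtype(c, root))

    # -- is-a reasoning --------------------------------------------------

    def ancestors(self, concept_id: str) -> frozenset[str]:
        """Self-inclusive ancestor set of a concept (is-a edges only)."""
        self.record(concept_id)
        cached = self._ancestor_cache.get(concept_id)
        if cached is None:
            # isa edges point child -> parent, so reachable == ancestors
            cached = frozenset(nx.descendants(self.isa, concept_id)) | {concept_id}
            self._ancestor_cache[concept_id] = cached
        return cached

    def is_subtype(self, a: str, b: str) -> bool:
        """Reflexive is-a: true iff ``b`` is ``a`` itself or an ancestor."""
        self.record(b)
        return b in self.ancestors(a)

    # -- concept-model statistics ---------------------------------------

    def attribute_usage_counts(self, value: str) -> dict[str, int]:
        """How often each attribute takes a value at or below ``value``.

        Counts active defining pairs over all concept definitions whose
        value is a (reflexive) subtype of ``value``; the occurrence
        heuristic of the reverse-mapping disambiguation rules.
        """
        self.record(value)
        counts: dict[str, int] = {}
        for ungrouped, groups in self.definitions.values():
            for pairs in (ungrouped, *groups):
                for pair in pairs:
                    if isinstance(pair.value, str) and self.is_subtype(pair.value, value):
                        counts[pair.attribute] = counts.get(pair.attribute, 0) + 1
        return counts


# -- RF2 loading ---------------------------------------------------------

def _find_file(directory: str, stem: str) -> str:
    patterns = [f"*{stem}*", f"*{stem.lower()}*", f"*{stem.capitalize()}*"]
    for pat in patterns:
        hits = sorted(glob.glob(os.path.join(directory, pat)))
        hits = [h for h in hits if os.path.isfile(h)]
        if hits:
            return hits[0]
    raise TerminologyLoadError(f"no {stem} file found in {directory}")


def _read_tsv(path: str, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TerminologyLoadError(f"{path} lacks columns {missing}")
    return frame


def load_rf2(directory: str, config: LoadConfig = LoadConfig()) -> Terminology:
    """Load a snapshot terminology from RF2-dialect TSV files.

    The directory must contain a concept and a relationship file
    (filenames containing "Concept" / "Relationship"); a description file
    ("Description") supplies FSNs and is optional — concepts without a
    description fall back to their identifier as display string.
    """
    if not os.path.isdir(directory):
        raise TerminologyLoadError(f"not a directory: {directory}")
    concept_path = _find_file(directory, "Concept")
    rel_path = _find_file(directory, "Relationship")
    concepts_df = _read_tsv(concept_path, ["id", "active", "definitionStatusId"])
    rel_df = _read_tsv(
        rel_path, ["sourceId", "destinationId", "relationshipGroup", "typeId", "active"]
    )
    fsns: dict[str, str] = {}
    try:
        desc_path = _find_file(directory, "Description")
    except TerminologyLoadError:
        desc_path = None
    if desc_path:
        desc_df = _read_tsv(desc_path, ["conceptId", "term", "active"])
        for row in desc_df.itertuples(index=False):
            if row.active == "1" and row.conceptId not in fsns:
                fsns[row.conceptId] = row.term

    concepts: dict[str, ConceptRecord] = {}
    for row in concepts_df.itertuples(index=False):
        if not is_well_formed(row.id, check_digit=config.check_digits):
            raise TerminologyIntegrityError(f"malformed concept id {row.id!r} in {concept_path}")
        if row.id in concepts:
            raise TerminologyIntegrityError(f"duplicate concept id {row.id}")
        concepts[row.id] = ConceptRecord(
            id=row.id,
            fsn=fsns.get(row.id, row.id),
            active=row.active == "1",
            fully_defined=row.definitionStatusId == config.fully_defined_id,
        )
    relationships = [
        RelationshipRecord(
            source_id=row.sourceId,
            type_id=row.typeId,
            destination_id=row.destinationId,
            group=int(row.relationshipGroup),
            active=row.active == "1",
        )
        for row in rel_df.itertuples(index=False)
    ]
    return Terminology(concepts, relationships, config)


# -- MRCM table ----------------------------------------------------------

def load_mrcm(path: str) -> list[MrcmRule]:
    """Read the declarative concept-model table (YAML list or TSV)."""
    if path.endswith((".yaml", ".yml")):
        with open(path, "r", encoding="utf-8") as fh:
            rows = yaml.safe_load(fh) or []
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        rows = frame.to_dict("records")
    rules = []
    for row in rows:
        raw_max = row.get("maxPerGroup", 1)
        max_per_group = None if raw_max in (None, "", "unbounded", "*") else int(raw_max)
        grouped = row.get("groupedAllowed", True)
        if isinstance(grouped, str):
            grouped = grouped.strip().lower() in ("1", "true", "yes")
        rules.append(
            MrcmRule(
                attribute_id=str(row["attributeId"]),
                domain_constraint=str(row["domainConstraint"]),
                range_constraint=str(row["rangeConstraint"]),
                max_per_group=max_per_group,
                grouped_allowed=bool(grouped),
            )
        )
    for rule in rules:  # constraints must parse under the ECL-lite grammar
        ecl.parse_constraint(rule.domain_constraint)
        ecl.parse_constraint(rule.range_constraint)
    return rules


# -- semantic validation -------------------------------------------------

def validate_semantics(term: Terminology, rules: list[MrcmRule], expr) -> ValidationReport:
    """Check a parsed expression against the concept model.

    Reports issues for unknown/inactive ids, attributes without a
    concept-model rule, domain and range violations, per-group cardinality
    overruns, and grouped use of ungroupable attributes.  All findings are
    report issues; nothing raises.
    """
    by_attr = {r.attribute_id: r for r in rules}
    issues: list[ValidationIssue] = []

    def check_id(cid: str, where: str) -> bool:
        if cid in term.concepts:
            return True
        kind = "inactive" if cid in term.inactive else "unknown"
        issues.append(ValidationIssue("error", f"{kind}-concept", f"{kind} concept {cid}", where))
        return False

    def check_pairs(pairs, focus_ids: list[str], where: str, grouped: bool) -> None:
        seen: dict[str, int] = {}
        for pair in pairs:
            attr = pair.attribute
            seen[attr] = seen.get(attr, 0) + 1
            if not check_id(attr, f"{where} attribute"):
                continue
            rule = by_attr.get(attr)
            if rule is None:
                issues.append(
                    ValidationIssue(
                        "error", "no-mrcm-rule", f"attribute {attr} has no concept-model rule", where
                    )
                )
                continue
            if grouped and not rule.grouped_allowed:
                issues.append(
                    ValidationIssue(
                        "error", "ungroupable-attribute",
                        f"attribute {attr} may not appear inside a role group", where,
                    )
                )
            known_focus = [f for f in focus_ids if f in term.concepts]
            if known_focus and not any(
                ecl.eval_ecl_lite(term, rule.domain_constraint, f) for f in known_focus
            ):
                issues.append(
                    ValidationIssue(
                        "error", "domain-violation",
                        f"focus concepts {known_focus} are outside the domain "
                        f"{rule.domain_constraint!r} of attribute {attr}", where,
                    )
                )
            value = pair.value
            if isinstance(value, str):
                if check_id(value, f"{where} value") and not ecl.eval_ecl_lite(
                    term, rule.range_constraint, value
                ):
                    issues.append(
                        ValidationIssue(
                            "error", "range-violation",
                            f"value {value} is outside the range "
                            f"{rule.range_constraint!r} of attribute {attr}", where,
                        )
                    )
            else:  # nested sub-expression: validate recursively, range-check its foci
                nested = validate_semantics(term, rules, value)
                issues.extend(nested.issues)
                for f in value.focus_concepts:
                    if f in term.concepts and not ecl.eval_ecl_lite(term, rule.range_constraint, f):
                        issues.append(
                            ValidationIssue(
                                "error", "range-violation",
                                f"nested focus {f} is outside the range "
                                f"{rule.range_constraint!r} of attribute {attr}", where,
                            )
                        )
        if grouped:
            for attr, count in seen.items():
                rule = by_attr.get(attr)
                if rule and rule.max_per_group is not None and count > rule.max_per_group:
                    issues.append(
                        ValidationIssue(
                            "error", "cardinality-violation",
                            f"attribute {attr} occurs {count}x in one group "
                            f"(max {rule.max_per_group})", where,
                        )
                    )

    focus_ids = list(expr.focus_concepts)
    for fid in focus_ids:
        check_id(fid, "focus")
    check_pairs(expr.ungrouped, focus_ids, "ungrouped refinement", grouped=False)
    for i, group in enumerate(expr.groups, start=1):
        check_pairs(group, focus_ids, f"group {i}", grouped=True)
    return ValidationReport(tuple(issues))
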