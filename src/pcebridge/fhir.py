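"""Category assignment, StructureMap rules, FHIR resource emission and the
reverse recomposition of an expression from stored resources.

A StructureMap (FHIR R4 JSON, group/rule shape) binds the Superconcept and
each relevant SNOMED attribute to a FHIRPath inside profiled resources.
The path dialect is deliberately small — dotted element names, optional
``:sliceName`` suffixes and ``extension(<url>)`` steps — because the maps
only ever address elements by simple traversal.

The reverse direction reads SNOMED codings back out of resources and
resolves many-to-one paths with three successive disambiguation rules:
value-range filtering, most-general-in-hierarchy, and the attribute-usage
occurrence heuristic.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import yaml

from . import ecl
from .errors import (
    CategoryError,
    DisjointnessError,
    EmissionError,
    RecompositionError,
    ReverseMappingError,
    StructureMapSchemaError,
)
from .expression import AttributePair, Expression
from .superdelta import Delta
from .terminology import MrcmRule, Terminology

SNOMED_SYSTEM = "http://snomed.info/sct"
ORIGINAL_PCE_TAG = "http://example.org/pcebridge/original-expression"
CATEGORY_TAG = "http://example.org/pcebridge/category"
SUPERCONCEPT_SOURCE = "Superconcept"

# Elements traversed as arrays while navigating a path.
_ARRAY_STEPS = {
    "reaction",
    "manifestation",
    "evidence",
    "extension",
    "tag",
    "usedReference",
    "focalDevice",
}


# -- FHIRPath-lite -------------------------------------------------------


@dataclass(frozen=True)
class PathStep:
    name: str
    slice: Optional[str] = None
    url: Optional[str] = None  # extension(<url>) steps only


def parse_path(path: str) -> tuple[PathStep, ...]:
    """Split a path into steps; the first step names the resource type."""
    steps: list[PathStep] = []
    depth = 0
    current = ""
    parts: list[str] = []
    for ch in path:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise StructureMapSchemaError(f"unbalanced parentheses in path {path!r}")
        if ch == "." and depth == 0:
            parts.append(current)
            current = ""
        else:
            current += ch
    parts.append(current)
    if depth != 0:
        raise StructureMapSchemaError(f"unbalanced parentheses in path {path!r}")
    for part in parts:
        part = part.strip()
        if not part:
            raise StructureMapSchemaError(f"empty step in path {path!r}")
        if part.startswith("extension(") and part.endswith(")"):
            steps.append(PathStep("extension", url=part[len("extension("):-1].strip()))
            continue
        slice_name = None
        if ":" in part:
            part, slice_name = part.split(":", 1)
        if not part.replace("-", "").isalnum():
            raise StructureMapSchemaError(f"bad element name {part!r} in path {path!r}")
        steps.append(PathStep(part, slice=slice_name))
    if not steps:
        raise StructureMapSchemaError(f"empty path {path!r}")
    return tuple(steps)


# -- content categories --------------------------------------------------


@dataclass(frozen=True)
class CategoryDef:
    id: str
    name: str
    constraint: str
    profile_sets: tuple[str, ...]
    attributes: tuple[str, ...] = ()  # relevant attributes (element accounting)

    @property
    def total_elements(self) -> int:
        return 1 + len(self.attributes)  # Superconcept + attributes


def load_categories(path: str, term: Terminology | None = None) -> list[CategoryDef]:
    """Read the category configuration (YAML/JSON list).

    When a terminology is given, pairwise disjointness of the constraints
    is checked over all of its active concepts.
    """
    with open(path, "r", encoding="utf-8") as fh:
        rows = yaml.safe_load(fh) or []
    categories = [
        CategoryDef(
            id=str(row["id"]),
            name=str(row.get("name", row["id"])),
            constraint=str(row["constraint"]),
            profile_sets=tuple(row.get("profileSets", ())),
            attributes=tuple(str(a) for a in row.get("attributes", ())),
        )
        for row in rows
    ]
    for cat in categories:
        ecl.parse_constraint(cat.constraint)
    if term is not None:
        check_disjoint(term, categories)
    return categories


def check_disjoint(term: Terminology, categories: list[CategoryDef]) -> None:
    """Raise when two category constraints share a concept."""
    parsed = [(c, ecl.parse_constraint(c.constraint)) for c in categories]
    for concept_id in term.concepts:
        hits = [c.id for c, node in parsed if ecl.eval_constraint(term, node, concept_id)]
        if len(hits) > 1:
            raise DisjointnessError(
                f"concept {concept_id} matches categories {hits}; constraints must be disjoint"
            )


def assign_category(
    term: Terminology,
    expr: Expression,
    categories: list[CategoryDef],
    superconcept: str | None = None,
) -> CategoryDef:
    """Assign an expression to its unique content category.

    Membership is decided on the focus concepts (every focus concept must
    satisfy the constraint); if no category matches, the Superconcept is
    tried as a fallback.  Zero matches raise; multiple matches indicate a
    non-disjoint configuration and also raise.
    """

    def matches_all(cat: CategoryDef, ids: Iterable[str]) -> bool:
        node = ecl.parse_constraint(cat.constraint)
        return all(ecl.eval_constraint(term, node, cid) for cid in ids)

    hits = [c for c in categories if matches_all(c, expr.focus_concepts)]
    if not hits and superconcept is not None:
        hits = [c for c in categories if matches_all(c, [superconcept])]
    if not hits:
        raise CategoryError(
            f"expression with focus {list(expr.focus_concepts)} matches no content category"
        )
    if len(hits) > 1:
        raise DisjointnessError(
            f"expression matches several categories: {[c.id for c in hits]}"
        )
    return hits[0]


# -- StructureMap model --------------------------------------------------


@dataclass(frozen=True)
class MappingRule:
    source: str  # "Superconcept" or an attribute concept id
    target_path: str
    via_extension: bool = False

    @property
    def resource_type(self) -> str:
        return parse_path(self.target_path)[0].name


@dataclass(frozen=True)
class StructureMapModel:
    category_id: str
    profile_set_id: str
    name: str
    rules: tuple[MappingRule, ...]
    references: tuple[tuple[str, str], ...]  # (fromPath, toResourceType)
    profile_bindings: dict[str, str] = field(default_factory=dict)

    @property
    def superconcept_rule(self) -> MappingRule:
        return next(r for r in self.rules if r.source == SUPERCONCEPT_SOURCE)

    def attribute_rules(self) -> list[MappingRule]:
        return [r for r in self.rules if r.source != SUPERCONCEPT_SOURCE]

    def rules_for_path(self, path: str) -> list[MappingRule]:
        return [r for r in self.rules if r.target_path == path]


def _usecontext_value(doc: dict, code: str) -> str | None:
    for ctx in doc.get("useContext", ()):
        if ctx.get("code", {}).get("code") == code:
            return ctx.get("valueString")
    return None


def load_structuremap(doc: dict) -> StructureMapModel:
    """Build the rule model from a FHIR R4 StructureMap JSON document.

    Mapping rules live in the group named ``mapping``; each rule's
    ``source[0].value`` is the string ``Superconcept`` or an attribute id
    and ``target[0].element`` the FHIRPath.  Rules marked with
    ``documentation: "via extension"`` denote attributes representable only
    through foreign extensions.  Reference entries and profile-name
    bindings come from the ``references`` and ``profiles`` groups.
    """
    if doc.get("resourceType") != "StructureMap":
        raise StructureMapSchemaError("document is not a StructureMap")
    category = _usecontext_value(doc, "category")
    profile_set = _usecontext_value(doc, "profile-set")
    if not category or not profile_set:
        raise StructureMapSchemaError(
            "StructureMap lacks category / profile-set useContext entries"
        )
    groups = {g.get("name"): g.get("rule", []) for g in doc.get("group", ())}
    if "mapping" not in groups:
        raise StructureMapSchemaError("StructureMap has no 'mapping' group")

    rules: list[MappingRule] = []
    seen_sources: set[str] = set()
    for entry in groups["mapping"]:
        try:
            source = entry["source"][0]["value"]
            target = entry["target"][0]["element"]
        except (KeyError, IndexError) as exc:
            raise StructureMapSchemaError(f"malformed rule entry {entry!r}") from exc
        if source in seen_sources:
            raise StructureMapSchemaError(f"duplicate rule source {source!r}")
        seen_sources.add(source)
        parse_path(target)  # validates
        rules.append(
            MappingRule(
                source=source,
                target_path=target,
                via_extension=entry.get("documentation") == "via extension",
            )
        )
    if sum(1 for r in rules if r.source == SUPERCONCEPT_SOURCE) != 1:
        raise StructureMapSchemaError("exactly one Superconcept rule is required")

    references = []
    for entry in groups.get("references", []):
        references.append((entry["source"][0]["value"], entry["target"][0]["element"]))
        parse_path(references[-1][0])
    profiles = {}
    for entry in groups.get("profiles", []):
        profiles[entry["source"][0]["value"]] = entry["target"][0]["element"]

    return StructureMapModel(
        category_id=category,
        profile_set_id=profile_set,
        name=doc.get("name", f"{category}-{profile_set}"),
        rules=tuple(rules),
        references=tuple(references),
        profile_bindings=profiles,
    )


def load_structuremap_dir(directory: str) -> list[StructureMapModel]:
    """Load every ``*.json`` StructureMap in a directory."""
    paths = sorted(
        os.path.join(directory, f) for f in os.listdir(directory) if f.endswith(".json")
    )
    if not paths:
        raise StructureMapSchemaError(f"no StructureMap documents in {directory}")
    maps = []
    for path in paths:
        with open(path, "r", encoding="utf-8") as fh:
            maps.append(load_structuremap(json.load(fh)))
    return maps


def select_map(
    maps: list[StructureMapModel], category_id: str, profile_set_id: str
) -> StructureMapModel:
    for m in maps:
        if m.category_id == category_id and m.profile_set_id == profile_set_id:
            return m
    raise StructureMapSchemaError(
        f"no StructureMap for category {category_id!r} and profile set {profile_set_id!r}"
    )


# -- forward mapping -----------------------------------------------------


@dataclass(frozen=True)
class Binding:
    path: str
    code: str
    display: str = ""
    system: str = SNOMED_SYSTEM
    source: str = ""  # rule source that produced / received this binding


@dataclass(frozen=True)
class MappingResult:
    bindings: tuple[Binding, ...]
    unmapped: frozenset[tuple[str, str]]
    references_used: tuple[tuple[str, str], ...]
    profiles: dict[str, str]
    map_name: str = ""


def _nearest_rule(term: Terminology, attribute: str, rules: list[MappingRule]) -> MappingRule | None:
    """The rule for the attribute itself, else the most specific rule whose
    source is an ancestor of the attribute in the attribute hierarchy."""
    by_source = {r.source: r for r in rules}
    if attribute in by_source:
        return by_source[attribute]
    ancestors = [s for s in by_source if s.isdigit() and term.is_subtype(attribute, s)]
    if not ancestors:
        return None
    nearest = [
        s for s in ancestors if not any(o != s and term.is_subtype(o, s) for o in ancestors)
    ]
    return by_source[min(nearest, key=int)]


def apply_mapping(
    smap: StructureMapModel, superconcept: str, delta: Delta, term: Terminology
) -> MappingResult:
    """Bind the Superconcept and every Delta edge to FHIRPaths.

    Edges without an applicable rule (including nested-expression values,
    which cannot be stored as a single coding) are reported as unmapped —
    an accounted outcome, never an error.
    """
    term.record(superconcept)
    bindings = [
        Binding(
            path=smap.superconcept_rule.target_path,
            code=superconcept,
            display=term.fsn(superconcept),
            source=SUPERCONCEPT_SOURCE,
        )
    ]
    unmapped: set[tuple[str, str]] = set()
    attr_rules = smap.attribute_rules()
    for attribute, value in sorted(delta.edges):
        rule = _nearest_rule(term, attribute, attr_rules)
        if rule is None or not value.isdigit():
            unmapped.add((attribute, value))
            continue
        bindings.append(
            Binding(
                path=rule.target_path,
                code=value,
                display=term.fsn(value) if value in term.concepts else value,
                source=rule.source,
            )
        )
    used_types = {parse_path(b.path)[0].name for b in bindings}
    references = tuple(
        (frm, to)
        for frm, to in smap.references
        if parse_path(frm)[0].name in used_types and to in used_types
    )
    profiles = {t: p for t, p in smap.profile_bindings.items() if t in used_types}
    return MappingResult(
        bindings=tuple(bindings),
        unmapped=frozenset(unmapped),
        references_used=references,
        profiles=profiles,
        map_name=f"{smap.category_id}|{smap.profile_set_id}",
    )


# -- resource emission ---------------------------------------------------


def _descend(node: dict, step: PathStep) -> dict:
    """Navigate one intermediate step, creating objects/arrays as needed."""
    if step.name == "extension":
        entries = node.setdefault("extension", [])
        for entry in entries:
            if entry.get("url") == step.url:
                return entry
        entry = {"url": step.url}
        entries.append(entry)
        return entry
    if step.name in _ARRAY_STEPS:
        entries = node.setdefault(step.name, [])
        if not entries:
            entries.append({})
        return entries[0]
    return node.setdefault(step.name, {})


def _write_terminal(node: dict, step: PathStep, coding: dict) -> None:
    if step.name == "coding":
        node.setdefault("coding", []).append(coding)
    elif step.name == "extension":
        entries = node.setdefault("extension", [])
        entry = next((e for e in entries if e.get("url") == step.url), None)
        if entry is None:
            entry = {"url": step.url}
            entries.append(entry)
        entry.setdefault("valueCodeableConcept", {}).setdefault("coding", []).append(coding)
    else:
        current = node.get(step.name)
        if current is None:
            node[step.name] = {"coding": [coding]}
        elif isinstance(current, dict):
            current.setdefault("coding", []).append(coding)
        else:
            raise EmissionError(
                f"cannot write a coding at {step.name!r}: element already holds {type(current).__name__}"
            )


def _write_reference(node: dict, step: PathStep, reference: str) -> None:
    current = node.get(step.name)
    if current is None:
        node[step.name] = {"reference": reference}
    elif isinstance(current, dict):
        current["reference"] = reference
    elif isinstance(current, list):
        current.append({"reference": reference})
    else:
        raise EmissionError(f"cannot write a reference at {step.name!r}")


def emit_resources(
    result: MappingResult,
    context: dict | None = None,
    original_expression: str | None = None,
) -> list[dict]:
    """Materialize one resource JSON document per bound resource type.

    Codings are written at their paths (intermediate objects and arrays are
    created on demand); references between the emitted documents are
    populated from the map's reference entries; the original expression and
    the category are preserved in ``meta.tag`` of every document.
    ``context`` may carry prefill stubs, e.g. ``{"patient": "Patient/123"}``.
    """
    if not result.bindings:
        raise EmissionError("no bindings: every mapping carries at least the Superconcept")
    docs: dict[str, dict] = {}
    for binding in result.bindings:
        steps = parse_path(binding.path)
        rtype = steps[0].name
        doc = docs.setdefault(rtype, {"resourceType": rtype, "id": rtype.lower() + "-pce"})
        node = doc
        for step in steps[1:-1]:
            node = _descend(node, step)
        coding = {"system": binding.system, "code": binding.code}
        if binding.display:
            coding["display"] = binding.display
        _write_terminal(node, steps[-1], coding)

    for rtype, doc in docs.items():
        tags = []
        if original_expression is not None:
            tags.append({"system": ORIGINAL_PCE_TAG, "code": original_expression})
        if result.map_name:
            tags.append({"system": CATEGORY_TAG, "code": result.map_name})
        if tags:
            doc.setdefault("meta", {})["tag"] = tags
        if result.profiles.get(rtype):
            doc.setdefault("meta", {})["profile"] = [result.profiles[rtype]]
        if context and context.get("patient"):
            key = "patient" if rtype == "AllergyIntolerance" else "subject"
            doc[key] = {"reference": context["patient"]}

    for from_path, to_type in result.references_used:
        steps = parse_path(from_path)
        src_doc = docs.get(steps[0].name)
        dst_doc = docs.get(to_type)
        if src_doc is None or dst_doc is None:
            continue
        node = src_doc
        for step in steps[1:-1]:
            node = _descend(node, step)
        _write_reference(node, steps[-1], f"{to_type}/{dst_doc['id']}")

    return [docs[t] for t in sorted(docs)]


# -- extraction ----------------------------------------------------------


def _collect_nodes(node, step: PathStep) -> list:
    """All child nodes one step down (arrays fan out)."""
    if isinstance(node, list):
        out = []
        for item in node:
            out.extend(_collect_nodes(item, step))
        return out
    if not isinstance(node, dict):
        return []
    if step.name == "extension":
        return [e for e in node.get("extension", []) if e.get("url") == step.url]
    child = node.get(step.name)
    if child is None:
        return []
    return child if isinstance(child, list) else [child]


def _codings_at(node) -> list[dict]:
    """SNOMED codings held by a terminal node (CodeableConcept, coding list
    entry, or extension with a valueCodeableConcept)."""
    nodes = node if isinstance(node, list) else [node]
    codings: list[dict] = []
    for item in nodes:
        if not isinstance(item, dict):
            continue
        if "code" in item and "system" in item:  # already a Coding
            codings.append(item)
            continue
        if "valueCodeableConcept" in item:
            codings.extend(item["valueCodeableConcept"].get("coding", []))
            continue
        codings.extend(item.get("coding", []))
    return [c for c in codings if c.get("system") == SNOMED_SYSTEM]


def extract_bindings(resources: list[dict], smap: StructureMapModel) -> list[Binding]:
    """Read every SNOMED coding stored at any rule's target path.

    Non-SNOMED codings are ignored; each distinct (path, code) yields one
    binding.  Paths are searched once even when several rules share them.
    """
    by_type: dict[str, list[dict]] = {}
    for doc in resources:
        by_type.setdefault(doc.get("resourceType", ""), []).append(doc)
    bindings: list[Binding] = []
    seen: set[tuple[str, str]] = set()
    for path in sorted({r.target_path for r in smap.rules}):
        steps = parse_path(path)
        for doc in by_type.get(steps[0].name, []):
            nodes: list = [doc]
            for step in steps[1:]:
                nodes = [child for n in nodes for child in _collect_nodes(n, step)]
            for coding in _codings_at(nodes):
                key = (path, coding["code"])
                if key in seen:
                    continue
                seen.add(key)
                bindings.append(
                    Binding(path=path, code=coding["code"], display=coding.get("display", ""))
                )
    return bindings


# -- reverse mapping -----------------------------------------------------


def reverse_attribute(
    binding: Binding,
    smap: StructureMapModel,
    term: Terminology,
    mrcm_rules: list[MrcmRule],
) -> str:
    """Recover the SNOMED attribute behind a stored coding.

    Candidate attributes are all rule sources sharing the binding's path,
    filtered successively: (1) keep those whose concept-model range admits
    the code — a unique survivor wins; (2) if the survivors form a chain in
    the attribute hierarchy, the most general is selected; (3) otherwise
    the attribute with the highest usage count for the code wins.  Final
    ties break to the lowest numeric id.
    """
    candidates = [
        r.source for r in smap.rules_for_path(binding.path) if r.source != SUPERCONCEPT_SOURCE
    ]
    if not candidates:
        raise ReverseMappingError(f"no attribute rule maps to path {binding.path!r}")
    if len(candidates) == 1:
        return candidates[0]

    by_attr = {r.attribute_id: r for r in mrcm_rules}

    def range_admits(attr: str) -> bool:
        rule = by_attr.get(attr)
        if rule is None or binding.code not in term.concepts:
            return False
        return ecl.eval_ecl_lite(term, rule.range_constraint, binding.code)

    filtered = [a for a in candidates if range_admits(a)]
    if len(filtered) == 1:
        return filtered[0]
    if filtered:
        candidates = filtered

    def is_chain(attrs: list[str]) -> bool:
        return all(
            term.is_subtype(a, b) or term.is_subtype(b, a) for a in attrs for b in attrs
        )

    if all(a in term.concepts for a in candidates) and is_chain(candidates):
        # most general: the one every other candidate descends from
        for a in candidates:
            if all(term.is_subtype(b, a) for b in candidates):
                return a

    counts = (
        term.attribute_usage_counts(binding.code) if binding.code in term.concepts else {}
    )
    best = max(counts.get(a, 0) for a in candidates) if candidates else 0
    top = [a for a in candidates if counts.get(a, 0) == best]
    return min(top, key=int)


def recompose(
    bindings: list[Binding],
    smap: StructureMapModel,
    term: Terminology,
    mrcm_rules: list[MrcmRule],
) -> Expression:
    """Rebuild an expression from extracted bindings.

    The Superconcept becomes the focus concept; every other binding becomes
    an ungrouped ``attribute = value`` pair with the attribute recovered by
    :func:`reverse_attribute`.
    """
    super_path = smap.superconcept_rule.target_path
    superconcepts = [b for b in bindings if b.path == super_path]
    if not superconcepts:
        raise RecompositionError(
            f"no Superconcept element found at {super_path!r} in the stored resources"
        )
    superconcept = superconcepts[0]
    pairs = set()
    for binding in bindings:
        if binding is superconcept:
            continue
        attribute = reverse_attribute(binding, smap, term, mrcm_rules)
        pairs.add(AttributePair(attribute, binding.code))
    return Expression(
        focus_concepts=(superconcept.code,),
        ungrouped=frozenset(pairs),
    )


# -- coverage accounting -------------------------------------------------


@dataclass(frozen=True)
class CoverageRow:
    category_id: str
    profile_set_id: str
    total_elements: int
    mappable: int
    unmappable: int
    via_extension: int

    @property
    def direct_pct(self) -> int:
        return round(100 * self.mappable / self.total_elements)

    @property
    def with_extension_pct(self) -> int:
        return round(100 * (self.mappable + self.via_extension) / self.total_elements)


@dataclass(frozen=True)
class CoverageStats:
    rows: tuple[CoverageRow, ...]
    direct_pct: float
    with_extension_pct: float
    min_direct_pct: int
    max_direct_pct: int
    min_with_extension_pct: int
    max_with_extension_pct: int


def coverage_report(
    maps: list[StructureMapModel], element_counts: dict[str, list[str]]
) -> CoverageStats:
    """Element coverage per (category, profile set) and in aggregate.

    ``element_counts`` lists each category's relevant attributes; a map's
    mappable count is its Superconcept rule plus its direct attribute rules,
    via-extension rules stay in the unmappable column but are reported as
    extension-coverable.  Aggregates are element-weighted (sum over sum).
    """
    rows = []
    for smap in sorted(maps, key=lambda m: (m.category_id, m.profile_set_id)):
        if smap.category_id not in element_counts:
            raise StructureMapSchemaError(
                f"no element list for category {smap.category_id!r}"
            )
        attributes = element_counts[smap.category_id]
        total = 1 + len(attributes)
        direct = [r for r in smap.rules if not r.via_extension]
        via = [r for r in smap.rules if r.via_extension]
        for rule in smap.attribute_rules():
            if rule.source not in attributes:
                raise StructureMapSchemaError(
                    f"rule source {rule.source} is not a listed element of "
                    f"category {smap.category_id!r}"
                )
        mappable = len(direct)
        if mappable > total or len(via) > total - mappable:
            raise StructureMapSchemaError(
                f"inconsistent coverage annotation in map {smap.name!r}"
            )
        rows.append(
            CoverageRow(
                category_id=smap.category_id,
                profile_set_id=smap.profile_set_id,
                total_elements=total,
                mappable=mappable,
                unmappable=total - mappable,
                via_extension=len(via),
            )
        )
    total_elements = sum(r.total_elements for r in rows)
    total_mappable = sum(r.mappable for r in rows)
    total_with_ext = total_mappable + sum(r.via_extension for r in rows)
    return CoverageStats(
        rows=tuple(rows),
        direct_pct=round(100 * total_mappable / total_elements, 1),
        with_extension_pct=round(100 * total_with_ext / total_elements, 1),
        min_direct_pct=min(r.direct_pct for r in rows),
        max_direct_pct=max(r.direct_pct for r in rows),
        min_with_extension_pct=min(r.with_extension_pct for r in rows),
        max_with_extension_pct=max(r.with_extension_pct for r in rows),
    )
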