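"""Synthetic terminologies, concept-model tables, category configurations,
StructureMaps and expression corpora.

Everything every pipeline stage needs is generated here at desk scale, so
the package is fully testable without a licensed terminology release.  Two
entry points:

* :func:`generate_terminology` — a seeded random polyhierarchy with
  primitive and fully defined concepts, role-grouped definitions, an
  attribute subtree containing a three-level chain, and a consistent
  concept-model table plus category configuration;
* :func:`build_allergy_mini` — the static bundled fixture: an
  allergy-flavoured finding hierarchy whose flagship expression yields two
  incomparable Superconcept candidates, a procedure subtree exercising the
  reverse-mapping disambiguation rules, and ten StructureMaps (five content
  categories x two profile sets) with coverage annotations.

Fixture content concepts use synthetic 1000xx identifiers; the attribute
subtree and RF2 metadata reuse the real SNOMED CT identifiers so the
shipped StructureMaps can carry the published rule tables verbatim.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field

import yaml

from .errors import CorpusError, FixtureSpecError
from .expression import AttributePair, Expression, serialize
from .terminology import (
    FULLY_DEFINED,
    IS_A,
    PRIMITIVE,
    LoadConfig,
    MrcmRule,
    Terminology,
    load_mrcm,
    load_rf2,
    validate_semantics,
)

_EFFECTIVE_TIME = "20230430"
_MODULE = "900000000000207008"
_FSN_TYPE = "900000000000003001"


def _write_rf2(
    directory: str,
    concepts: list[tuple[str, str, bool, bool]],  # id, fsn, active, fully_defined
    relationships: list[tuple[str, str, str, int, bool]],  # src, type, dst, group, active
) -> None:
    os.makedirs(directory, exist_ok=True)
    concept_rows = [
        "\t".join(
            (
                cid,
                _EFFECTIVE_TIME,
                "1" if active else "0",
                _MODULE,
                FULLY_DEFINED if fully_defined else PRIMITIVE,
            )
        )
        for cid, _, active, fully_defined in sorted(concepts)
    ]
    rel_rows = []
    for i, (src, typ, dst, group, active) in enumerate(sorted(relationships), start=1):
        rel_rows.append(
            "\t".join(
                (
                    str(1_000_000 + i),
                    _EFFECTIVE_TIME,
                    "1" if active else "0",
                    _MODULE,
                    src,
                    dst,
                    str(group),
                    typ,
                )
            )
        )
    desc_rows = [
        "\t".join((str(2_000_000 + i), "1" if active else "0", cid, _FSN_TYPE, fsn))
        for i, (cid, fsn, active, _) in enumerate(sorted(concepts), start=1)
    ]
    with open(os.path.join(directory, "sct2_Concept_Snapshot.txt"), "w", encoding="utf-8") as fh:
        fh.write("id\teffectiveTime\tactive\tmoduleId\tdefinitionStatusId\n")
        fh.write("\n".join(concept_rows) + "\n")
    with open(
        os.path.join(directory, "sct2_Relationship_Snapshot.txt"), "w", encoding="utf-8"
    ) as fh:
        fh.write(
            "id\teffectiveTime\tactive\tmoduleId\tsourceId\tdestinationId\t"
            "relationshipGroup\ttypeId\n"
        )
        fh.write("\n".join(rel_rows) + "\n")
    with open(
        os.path.join(directory, "sct2_Description_Snapshot.txt"), "w", encoding="utf-8"
    ) as fh:
        fh.write("id\tactive\tconceptId\ttypeId\tterm\n")
        fh.write("\n".join(desc_rows) + "\n")


# -- random fixture generator -------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    concept_count: int = 120
    max_parents: int = 3
    attribute_count: int = 6
    defined_fraction: float = 0.3
    group_probability: float = 0.4
    category_layout: tuple[tuple[str, int], ...] = (
        ("finding-like", 3),
        ("procedure-like", 2),
    )  # (category id, relative subtree weight)


@dataclass
class GeneratedFixture:
    directory: str
    terminology: Terminology
    mrcm_rules: list[MrcmRule]
    mrcm_path: str
    categories_path: str
    category_roots: dict[str, str]
    value_root: str
    attribute_ids: list[str]


def generate_terminology(spec: FixtureSpec, out: str) -> GeneratedFixture:
    """Write a reproducible random RF2 fixture and its config tables.

    Equal specs (seed included) produce byte-identical directories.  The
    attribute subtree always contains a three-level chain so the
    most-general-in-hierarchy disambiguation rule is exercisable.
    """
    if spec.concept_count < 8:
        raise FixtureSpecError("concept_count must be at least 8")
    if spec.max_parents < 1:
        raise FixtureSpecError("max_parents must be >= 1 to keep the hierarchy connected")
    if spec.attribute_count < 3:
        raise FixtureSpecError("attribute_count must be >= 3 (a chain is required)")
    if not spec.category_layout:
        raise FixtureSpecError("at least one category subtree is required")
    if not 0.0 <= spec.defined_fraction <= 1.0 or not 0.0 <= spec.group_probability <= 1.0:
        raise FixtureSpecError("fractions must lie in [0, 1]")

    rng = random.Random(spec.seed)
    next_id = [500_000]

    def new_id() -> str:
        next_id[0] += 1
        return str(next_id[0])

    root = new_id()
    attr_root = new_id()
    value_root = new_id()
    concepts: list[tuple[str, str, bool, bool]] = [
        (root, "Synthetic root concept", True, False),
        (attr_root, "Synthetic attribute root", True, False),
        (value_root, "Synthetic value root", True, False),
        (IS_A, "Is a (attribute)", True, False),
    ]
    relationships: list[tuple[str, str, str, int, bool]] = [
        (attr_root, IS_A, root, 0, True),
        (value_root, IS_A, root, 0, True),
        (IS_A, IS_A, attr_root, 0, True),
    ]

    # attribute subtree: a 3-level chain plus flat siblings
    chain = [new_id() for _ in range(3)]
    concepts += [(chain[i], f"Chained attribute level {i + 1}", True, False) for i in range(3)]
    relationships.append((chain[0], IS_A, attr_root, 0, True))
    relationships.append((chain[1], IS_A, chain[0], 0, True))
    relationships.append((chain[2], IS_A, chain[1], 0, True))
    attributes = list(chain)
    for i in range(spec.attribute_count - 3):
        aid = new_id()
        concepts.append((aid, f"Flat attribute {i + 1}", True, False))
        relationships.append((aid, IS_A, attr_root, 0, True))
        attributes.append(aid)

    # content budget: a third of the remaining concepts are values
    budget = spec.concept_count - len(concepts)
    value_count = max(3, budget // 3)
    values = []
    for i in range(value_count):
        vid = new_id()
        concepts.append((vid, f"Value concept {i + 1}", True, False))
        parent = value_root if not values or rng.random() < 0.5 else rng.choice(values)
        relationships.append((vid, IS_A, parent, 0, True))
        values.append(vid)

    weights = [w for _, w in spec.category_layout]
    remaining = budget - value_count
    if remaining < len(spec.category_layout):
        raise FixtureSpecError("concept_count too small for the requested category layout")
    category_roots: dict[str, str] = {}
    subtree_members: dict[str, list[str]] = {}
    for cat_id, _ in spec.category_layout:
        cid = new_id()
        concepts.append((cid, f"Category root {cat_id}", True, False))
        relationships.append((cid, IS_A, root, 0, True))
        category_roots[cat_id] = cid
        subtree_members[cat_id] = [cid]
        remaining -= 1
    definitions: list[tuple[str, list[tuple[str, str]], bool]] = []
    cat_ids = [c for c, _ in spec.category_layout]
    total_weight = sum(weights)
    for i in range(remaining):
        cat = rng.choices(cat_ids, weights=weights, k=1)[0]
        cid = new_id()
        members = subtree_members[cat]
        n_parents = min(len(members), 1 + rng.randrange(spec.max_parents))
        parents = rng.sample(members, n_parents)
        fully_defined = rng.random() < spec.defined_fraction
        pairs: list[tuple[str, str]] = []
        if fully_defined:
            for attr in rng.sample(attributes, min(len(attributes), rng.randrange(1, 3))):
                pairs.append((attr, rng.choice(values)))
        concepts.append((cid, f"Content concept {i + 1} ({cat})", True, fully_defined))
        for p in parents:
            relationships.append((cid, IS_A, p, 0, True))
        if pairs:
            grouped = rng.random() < spec.group_probability
            for attr, val in pairs:
                relationships.append((cid, attr, val, 1 if grouped else 0, True))
        members.append(cid)
    _ = total_weight, definitions

    _write_rf2(out, concepts, relationships)

    content_domain = f"<< {root} MINUS << {value_root} MINUS << {attr_root}"
    mrcm_rows = [
        {
            "attributeId": aid,
            "domainConstraint": content_domain,
            "rangeConstraint": f"<< {value_root}",
            "maxPerGroup": 1,
            "groupedAllowed": True,
        }
        for aid in attributes
    ]
    mrcm_path = os.path.join(out, "mrcm.yaml")
    with open(mrcm_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(mrcm_rows, fh, sort_keys=True)

    categories = [
        {
            "id": cat_id,
            "name": f"Synthetic category {cat_id}",
            "constraint": f"<< {category_roots[cat_id]}",
            "profileSets": ["default"],
            "attributes": attributes,
        }
        for cat_id, _ in spec.category_layout
    ]
    categories_path = os.path.join(out, "categories.yaml")
    with open(categories_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(categories, fh, sort_keys=True)

    term = load_rf2(out, LoadConfig())
    return GeneratedFixture(
        directory=out,
        terminology=term,
        mrcm_rules=load_mrcm(mrcm_path),
        mrcm_path=mrcm_path,
        categories_path=categories_path,
        category_roots=category_roots,
        value_root=value_root,
        attribute_ids=attributes,
    )


def generate_pce_corpus(
    term: Terminology,
    n: int,
    seed: int,
    mrcm_rules: list[MrcmRule],
    group_probability: float = 0.0,
    focus_pool: list[str] | None = None,
) -> list[Expression]:
    """Generate ``n`` semantically valid expressions, reproducibly.

    Each expression refines a randomly chosen focus concept with one or two
    attributes drawn from its concept-model-admissible set and values from
    the admissible ranges.  Every returned expression passes the semantic
    validation; raises when no focus concept admits any attribute.
    """
    from . import ecl  # local import: avoids cycle at module load

    rng = random.Random(seed)
    attribute_ids = term.attribute_ids()
    candidates = sorted(
        (focus_pool if focus_pool is not None else term.concepts),
        key=int,
    )
    admissible: dict[str, list[MrcmRule]] = {}
    for cid in candidates:
        if cid in attribute_ids or cid == term.root_id:
            continue
        rules = [
            r for r in mrcm_rules if ecl.eval_ecl_lite(term, r.domain_constraint, cid)
        ]
        if rules:
            admissible[cid] = rules
    if n > 0 and not admissible:
        raise CorpusError("no focus concept admits any attribute under the concept model")

    range_members: dict[str, list[str]] = {}

    def members_of(constraint: str) -> list[str]:
        if constraint not in range_members:
            node = ecl.parse_constraint(constraint)
            range_members[constraint] = sorted(
                (c for c in term.concepts if ecl.eval_constraint(term, node, c)),
                key=int,
            )
        return range_members[constraint]

    corpus: list[Expression] = []
    foci = sorted(admissible, key=int)
    attempts = 0
    while len(corpus) < n:
        attempts += 1
        if attempts > 50 * max(n, 1):
            raise CorpusError("could not generate a valid corpus within the attempt budget")
        focus = rng.choice(foci)
        rules = admissible[focus]
        chosen = rng.sample(rules, min(len(rules), rng.randrange(1, 3)))
        pairs = []
        ok = True
        for rule in chosen:
            values = members_of(rule.range_constraint)
            if not values:
                ok = False
                break
            pairs.append(AttributePair(rule.attribute_id, rng.choice(values)))
        if not ok or not pairs:
            continue
        grouped = rng.random() < group_probability and all(
            r.grouped_allowed for r in chosen
        )
        expr = Expression(
            focus_concepts=(focus,),
            ungrouped=frozenset() if grouped else frozenset(pairs),
            groups=(frozenset(pairs),) if grouped else (),
        )
        if validate_semantics(term, mrcm_rules, expr).ok:
            corpus.append(expr)
    return corpus


# -- the bundled allergy-mini fixture -----------------------------------

# attribute identifiers (real SCTIDs, as printed in the shipped rule tables)
CAUSATIVE_AGENT = "246075003"
FINDING_SITE = "363698007"
ASSOCIATED_MORPHOLOGY = "116676008"
PATHOLOGICAL_PROCESS = "370135005"
CLINICAL_COURSE = "263502005"
HAS_REALIZATION = "719722006"
OCCURRENCE = "246454002"
DUE_TO = "42752001"
METHOD = "260686004"
PROCEDURE_SITE = "363704007"
PROCEDURE_SITE_DIRECT = "405813007"
PROCEDURE_SITE_INDIRECT = "405814001"
DIRECT_SUBSTANCE = "363701004"
DIRECT_MORPHOLOGY = "363700009"
USING_SUBSTANCE = "424361007"
PROCEDURE_DEVICE = "405815000"
USING_DEVICE = "424226004"
USING_ACCESS_DEVICE = "425391005"
HAS_INTENT = "363703001"
ACCESS = "260507000"
SURGICAL_APPROACH = "424876005"
CONCEPT_MODEL_ATTRIBUTE = "410662002"
ROLE_GROUP = "609096000"

# synthetic content concepts
ROOT = "100001"
CLINICAL_FINDING = "100002"
PROCEDURE = "100003"
BODY_STRUCTURE = "100004"
SUBSTANCE = "100005"
MORPHOLOGY = "100006"
QUALIFIER = "100007"
DEVICE = "100008"
ALLERGIC_DISPOSITION = "100010"
DISEASE_DUE_TO_ALLERGY = "100011"
ALLERGIC_REACTION = "100012"
EDEMA_FINDING = "100013"
ALLERGIC_REACTION_TREE_NUT = "100014"
SWELLING_FINDING = "100015"
NUT_ALLERGY = "100016"
TREE_NUT_ALLERGY = "100017"
ALLERGIC_SKIN_DISEASE = "100018"
NUT_SUBSTANCE = "100030"
TREE_NUT_SUBSTANCE = "100031"
DRUG_SUBSTANCE = "100032"
POLLEN = "100033"
SKIN_STRUCTURE = "100040"
EYELID_STRUCTURE = "100041"
LIMB_STRUCTURE = "100042"
SWELLING_MORPHOLOGY = "100050"
INFLAMMATION_MORPHOLOGY = "100051"
EVALUATION_ACTION = "100060"
ACUTE = "100061"
CHRONIC = "100062"
CATHETER = "100070"
ACCESS_CATHETER = "100071"
ALLERGY_TESTING = "100080"
SKIN_PRICK_TEST = "100081"
NUT_CHALLENGE_TEST = "100082"
DRUG_INJECTION = "100083"
IRRIGATION = "100084"
LIMB_PROCEDURE = "100085"

ALLERGY_ATTRIBUTES = [
    CAUSATIVE_AGENT,
    FINDING_SITE,
    ASSOCIATED_MORPHOLOGY,
    PATHOLOGICAL_PROCESS,
    CLINICAL_COURSE,
    HAS_REALIZATION,
    OCCURRENCE,
    DUE_TO,
]
CLINICAL_FINDING_ATTRIBUTES = [
    CAUSATIVE_AGENT,
    FINDING_SITE,
    ASSOCIATED_MORPHOLOGY,
    PATHOLOGICAL_PROCESS,
    CLINICAL_COURSE,
]
PROCEDURE_ATTRIBUTES = [
    METHOD,
    PROCEDURE_SITE_DIRECT,
    PROCEDURE_SITE_INDIRECT,
    DIRECT_SUBSTANCE,
    DIRECT_MORPHOLOGY,
    USING_SUBSTANCE,
    USING_DEVICE,
    USING_ACCESS_DEVICE,
    HAS_INTENT,
    ACCESS,
    SURGICAL_APPROACH,
    "363702006",  # Has focus
]
HAS_FOCUS = "363702006"

_EXT_DISEASE_COURSE = "http://hl7.org/fhir/StructureDefinition/condition-diseaseCourse"
_EXT_DUE_TO = "http://hl7.org/fhir/StructureDefinition/condition-dueTo"
_EXT_ABATEMENT = "https://fhir.kbv.de/StructureDefinition/abatement-lebensphase-von"
_EXT_OCCURRED_FOLLOWING = "http://hl7.org/fhir/StructureDefinition/condition-occurredFollowing"
_EXT_CAUSATIVE = "http://example.org/fhir/StructureDefinition/causative-agent"
_EXT_PATH_PROCESS = "http://example.org/fhir/StructureDefinition/pathological-process"
_EXT_HAS_FOCUS = "http://example.org/fhir/StructureDefinition/has-focus"
_EXT_ACCESS = "https://fhir.kbv.de/StructureDefinition/access"
_EXT_SURGICAL_APPROACH = "https://fhir.kbv.de/StructureDefinition/surgical-approach"

_MANIFESTATION = "AllergyIntolerance.reaction.manifestation.coding:snomed"


def _allergy_mini_concepts() -> tuple[list, list]:
    """Concept and relationship rows of the bundled fixture."""
    prim: list[tuple[str, str, str | None]] = [  # id, fsn, parent (single)
        (ROOT, "Synthetic clinical root", None),
        (CLINICAL_FINDING, "Clinical finding (finding)", ROOT),
        (PROCEDURE, "Procedure (procedure)", ROOT),
        (BODY_STRUCTURE, "Body structure (body structure)", ROOT),
        (SUBSTANCE, "Substance (substance)", ROOT),
        (MORPHOLOGY, "Morphologically abnormal structure (morphologic abnormality)", ROOT),
        (QUALIFIER, "Qualifier value (qualifier value)", ROOT),
        (DEVICE, "Device (physical object)", ROOT),
        (ALLERGIC_DISPOSITION, "Allergic disposition (finding)", CLINICAL_FINDING),
        (DISEASE_DUE_TO_ALLERGY, "Disease due to allergy (disorder)", CLINICAL_FINDING),
        (ALLERGIC_REACTION, "Allergic reaction (disorder)", CLINICAL_FINDING),
        (EDEMA_FINDING, "Edema (finding)", CLINICAL_FINDING),
        (ALLERGIC_SKIN_DISEASE, "Allergic disease of skin (disorder)", DISEASE_DUE_TO_ALLERGY),
        (NUT_SUBSTANCE, "Nut substance (substance)", SUBSTANCE),
        (TREE_NUT_SUBSTANCE, "Tree nut substance (substance)", NUT_SUBSTANCE),
        (DRUG_SUBSTANCE, "Drug substance (substance)", SUBSTANCE),
        (POLLEN, "Pollen (substance)", SUBSTANCE),
        (SKIN_STRUCTURE, "Skin structure (body structure)", BODY_STRUCTURE),
        (EYELID_STRUCTURE, "Eyelid structure (body structure)", SKIN_STRUCTURE),
        (LIMB_STRUCTURE, "Limb structure (body structure)", BODY_STRUCTURE),
        (SWELLING_MORPHOLOGY, "Swelling (morphologic abnormality)", MORPHOLOGY),
        (INFLAMMATION_MORPHOLOGY, "Inflammation (morphologic abnormality)", MORPHOLOGY),
        (EVALUATION_ACTION, "Evaluation - action (qualifier value)", QUALIFIER),
        (ACUTE, "Acute (qualifier value)", QUALIFIER),
        (CHRONIC, "Chronic (qualifier value)", QUALIFIER),
        (CATHETER, "Catheter (physical object)", DEVICE),
        (ACCESS_CATHETER, "Access catheter (physical object)", CATHETER),
        (ALLERGY_TESTING, "Allergy testing procedure (procedure)", PROCEDURE),
        # attribute subtree (real identifiers)
        (CONCEPT_MODEL_ATTRIBUTE, "Concept model attribute (attribute)", ROOT),
        ("116680003", "Is a (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (ROLE_GROUP, "Role group (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (CAUSATIVE_AGENT, "Causative agent (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (FINDING_SITE, "Finding site (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (ASSOCIATED_MORPHOLOGY, "Associated morphology (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (PATHOLOGICAL_PROCESS, "Pathological process (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (CLINICAL_COURSE, "Clinical course (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (HAS_REALIZATION, "Has realization (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (OCCURRENCE, "Occurrence (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (DUE_TO, "Due to (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (METHOD, "Method (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (PROCEDURE_SITE, "Procedure site (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (PROCEDURE_SITE_DIRECT, "Procedure site - Direct (attribute)", PROCEDURE_SITE),
        (PROCEDURE_SITE_INDIRECT, "Procedure site - Indirect (attribute)", PROCEDURE_SITE),
        (DIRECT_SUBSTANCE, "Direct substance (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (DIRECT_MORPHOLOGY, "Direct morphology (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (USING_SUBSTANCE, "Using substance (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (PROCEDURE_DEVICE, "Procedure device (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (USING_DEVICE, "Using device (attribute)", PROCEDURE_DEVICE),
        (USING_ACCESS_DEVICE, "Using access device (attribute)", USING_DEVICE),
        (HAS_INTENT, "Has intent (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (ACCESS, "Access (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (SURGICAL_APPROACH, "Surgical approach (attribute)", CONCEPT_MODEL_ATTRIBUTE),
        (HAS_FOCUS, "Has focus (attribute)", CONCEPT_MODEL_ATTRIBUTE),
    ]
    defined: list[tuple[str, str, list[str], list[tuple[str, str, int]]]] = [
        # id, fsn, parents, defining pairs (attr, value, group)
        (
            ALLERGIC_REACTION_TREE_NUT,
            "Allergic reaction caused by tree nut (disorder)",
            [ALLERGIC_REACTION],
            [(CAUSATIVE_AGENT, TREE_NUT_SUBSTANCE, 1)],
        ),
        (
            SWELLING_FINDING,
            "Swelling (finding)",
            [CLINICAL_FINDING],
            [(ASSOCIATED_MORPHOLOGY, SWELLING_MORPHOLOGY, 0)],
        ),
        (
            NUT_ALLERGY,
            "Allergy to nut (finding)",
            [ALLERGIC_DISPOSITION],
            [(CAUSATIVE_AGENT, NUT_SUBSTANCE, 1)],
        ),
        (
            TREE_NUT_ALLERGY,
            "Allergy to tree nut (finding)",
            [NUT_ALLERGY],
            [(CAUSATIVE_AGENT, TREE_NUT_SUBSTANCE, 1)],
        ),
        (
            SKIN_PRICK_TEST,
            "Skin prick test (procedure)",
            [ALLERGY_TESTING],
            [(METHOD, EVALUATION_ACTION, 1), (DIRECT_SUBSTANCE, TREE_NUT_SUBSTANCE, 1)],
        ),
        (
            NUT_CHALLENGE_TEST,
            "Nut challenge test (procedure)",
            [ALLERGY_TESTING],
            [(DIRECT_SUBSTANCE, TREE_NUT_SUBSTANCE, 1)],
        ),
        (
            DRUG_INJECTION,
            "Drug injection (procedure)",
            [PROCEDURE],
            [(DIRECT_SUBSTANCE, DRUG_SUBSTANCE, 1)],
        ),
        (
            IRRIGATION,
            "Irrigation procedure (procedure)",
            [PROCEDURE],
            [(USING_SUBSTANCE, DRUG_SUBSTANCE, 1)],
        ),
        (
            LIMB_PROCEDURE,
            "Procedure on limb (procedure)",
            [PROCEDURE],
            [(PROCEDURE_SITE_DIRECT, LIMB_STRUCTURE, 1)],
        ),
    ]
    concepts: list[tuple[str, str, bool, bool]] = []
    relationships: list[tuple[str, str, str, int, bool]] = []
    for cid, fsn, parent in prim:
        concepts.append((cid, fsn, True, False))
        if parent is not None:
            relationships.append((cid, IS_A, parent, 0, True))
    for cid, fsn, parents, pairs in defined:
        concepts.append((cid, fsn, True, True))
        for p in parents:
            relationships.append((cid, IS_A, p, 0, True))
        for attr, value, group in pairs:
            relationships.append((cid, attr, value, group, True))
    return concepts, relationships


def allergy_mini_mrcm() -> list[dict]:
    finding = f"<< {CLINICAL_FINDING}"
    procedure = f"<< {PROCEDURE}"
    rows = [
        (CAUSATIVE_AGENT, finding, f"<< {SUBSTANCE}", True),
        (FINDING_SITE, finding, f"<< {BODY_STRUCTURE}", True),
        (ASSOCIATED_MORPHOLOGY, finding, f"<< {MORPHOLOGY}", True),
        (PATHOLOGICAL_PROCESS, finding, f"<< {QUALIFIER}", True),
        (CLINICAL_COURSE, finding, f"<< {QUALIFIER}", False),
        (HAS_REALIZATION, finding, f"<< {ALLERGIC_REACTION}", True),
        (OCCURRENCE, finding, f"<< {QUALIFIER}", True),
        (DUE_TO, finding, f"<< {ALLERGIC_DISPOSITION}", True),
        (METHOD, procedure, f"<< {QUALIFIER}", True),
        (PROCEDURE_SITE_DIRECT, procedure, f"<< {BODY_STRUCTURE}", True),
        (PROCEDURE_SITE_INDIRECT, procedure, f"<< {BODY_STRUCTURE}", True),
        (DIRECT_SUBSTANCE, procedure, f"<< {SUBSTANCE}", True),
        (DIRECT_MORPHOLOGY, procedure, f"<< {MORPHOLOGY}", True),
        (USING_SUBSTANCE, procedure, f"<< {SUBSTANCE}", True),
        (PROCEDURE_DEVICE, procedure, f"<< {DEVICE}", True),
        (USING_DEVICE, procedure, f"<< {DEVICE}", True),
        (USING_ACCESS_DEVICE, procedure, f"<< {DEVICE}", True),
        (HAS_INTENT, procedure, f"<< {QUALIFIER}", True),
        (ACCESS, procedure, f"<< {QUALIFIER}", True),
        (SURGICAL_APPROACH, procedure, f"<< {QUALIFIER}", True),
        (HAS_FOCUS, procedure, f"<< {CLINICAL_FINDING}", True),
    ]
    return [
        {
            "attributeId": attr,
            "domainConstraint": domain,
            "rangeConstraint": rng,
            "maxPerGroup": 1,
            "groupedAllowed": grouped,
        }
        for attr, domain, rng, grouped in rows
    ]


def allergy_mini_categories() -> list[dict]:
    return [
        {
            "id": "allergies",
            "name": "Allergies",
            "constraint": f"<< {ALLERGIC_DISPOSITION}",
            "profileSets": ["nashp-like", "mii-like"],
            "attributes": ALLERGY_ATTRIBUTES,
        },
        {
            "id": "disease-due-to-allergy",
            "name": "Disease due to allergies",
            "constraint": f"<< {DISEASE_DUE_TO_ALLERGY}",
            "profileSets": ["nashp-like", "mii-like"],
            "attributes": ALLERGY_ATTRIBUTES,
        },
        {
            "id": "allergic-reaction",
            "name": "Allergic reaction",
            "constraint": f"<< {ALLERGIC_REACTION}",
            "profileSets": ["nashp-like", "mii-like"],
            "attributes": ALLERGY_ATTRIBUTES,
        },
        {
            "id": "clinical-finding",
            "name": "Clinical finding (general)",
            "constraint": (
                f"<< {CLINICAL_FINDING} MINUS << {ALLERGIC_DISPOSITION} "
                f"MINUS << {DISEASE_DUE_TO_ALLERGY} MINUS << {ALLERGIC_REACTION}"
            ),
            "profileSets": ["nashp-like", "mii-like"],
            "attributes": CLINICAL_FINDING_ATTRIBUTES,
        },
        {
            "id": "procedure",
            "name": "Procedure",
            "constraint": f"<< {PROCEDURE}",
            "profileSets": ["nashp-like", "mii-like"],
            "attributes": PROCEDURE_ATTRIBUTES,
        },
    ]


def _map_doc(
    category: str,
    profile_set: str,
    rules: list[tuple[str, str, bool]],
    references: list[tuple[str, str]],
    profiles: dict[str, str],
) -> dict:
    def rule_entry(source: str, path: str, via: bool) -> dict:
        entry = {
            "name": f"map-{source.lower()}",
            "source": [{"context": "pce", "value": source}],
            "target": [{"context": "fhir", "element": path}],
        }
        if via:
            entry["documentation"] = "via extension"
        return entry

    groups = [{"name": "mapping", "rule": [rule_entry(*r) for r in rules]}]
    if references:
        groups.append(
            {
                "name": "references",
                "rule": [
                    {
                        "name": f"ref-{i}",
                        "source": [{"context": "fhir", "value": frm}],
                        "target": [{"context": "fhir", "element": to}],
                    }
                    for i, (frm, to) in enumerate(references, start=1)
                ],
            }
        )
    if profiles:
        groups.append(
            {
                "name": "profiles",
                "rule": [
                    {
                        "name": f"profile-{rtype.lower()}",
                        "source": [{"context": "fhir", "value": rtype}],
                        "target": [{"context": "fhir", "element": profile}],
                    }
                    for rtype, profile in sorted(profiles.items())
                ],
            }
        )
    return {
        "resourceType": "StructureMap",
        "id": f"{category}-{profile_set}",
        "url": f"http://example.org/StructureMap/{category}-{profile_set}",
        "name": f"{category}-{profile_set}",
        "status": "active",
        "useContext": [
            {"code": {"code": "category"}, "valueString": category},
            {"code": {"code": "profile-set"}, "valueString": profile_set},
        ],
        "group": groups,
    }


def allergy_mini_structuremaps() -> list[dict]:
    """The ten bundled StructureMaps (five categories x two profile sets)."""
    kbv = {
        "AllergyIntolerance": "KBV_PR_Base_AllergyIntolerance",
        "Condition": "KBV_PR_Base_Condition",
        "Procedure": "KBV_PR_Base_Procedure",
    }
    mii = {
        "Condition": "MII_PR_Diagnose_Condition",
        "Observation": "MII_PR_Befund_Observation",
        "Procedure": "MII_PR_Prozedur_Procedure",
    }
    evidence_ref = [("Condition.evidence.detail", "AllergyIntolerance")]
    evidence_ref_obs = [("Condition.evidence.detail", "Observation")]
    docs = [
        _map_doc(
            "allergies",
            "nashp-like",
            [
                ("Superconcept", "AllergyIntolerance.code", False),
                (CAUSATIVE_AGENT, "AllergyIntolerance.reaction.substance", False),
                (ASSOCIATED_MORPHOLOGY, _MANIFESTATION, False),
                (PATHOLOGICAL_PROCESS, _MANIFESTATION, False),
                (HAS_REALIZATION, _MANIFESTATION, False),
                (CLINICAL_COURSE, f"AllergyIntolerance.extension({_EXT_DISEASE_COURSE})", True),
            ],
            [],
            {"AllergyIntolerance": kbv["AllergyIntolerance"]},
        ),
        _map_doc(
            "allergies",
            "mii-like",
            [
                ("Superconcept", "Condition.code", False),
                (CAUSATIVE_AGENT, "Observation.valueCodeableConcept", False),
                (FINDING_SITE, "Condition.bodySite", False),
                (ASSOCIATED_MORPHOLOGY, "Condition.evidence.code", False),
                (PATHOLOGICAL_PROCESS, "Condition.evidence.code", False),
                (CLINICAL_COURSE, f"Condition.extension({_EXT_DISEASE_COURSE})", True),
                (DUE_TO, f"Condition.extension({_EXT_DUE_TO})", True),
            ],
            evidence_ref_obs,
            {"Condition": mii["Condition"], "Observation": mii["Observation"]},
        ),
        _map_doc(
            "disease-due-to-allergy",
            "nashp-like",
            [
                ("Superconcept", "Condition.code", False),
                (CAUSATIVE_AGENT, "AllergyIntolerance.code", False),
                (FINDING_SITE, "Condition.bodySite", False),
                (ASSOCIATED_MORPHOLOGY, "Condition.evidence.code", False),
                (PATHOLOGICAL_PROCESS, "Condition.evidence.code", False),
                (HAS_REALIZATION, "Condition.evidence.code", False),
                (OCCURRENCE, f"AllergyIntolerance.extension({_EXT_ABATEMENT})", False),
                (CLINICAL_COURSE, f"Condition.extension({_EXT_DISEASE_COURSE})", True),
                (DUE_TO, f"Condition.extension({_EXT_DUE_TO})", True),
            ],
            evidence_ref,
            {"AllergyIntolerance": kbv["AllergyIntolerance"], "Condition": kbv["Condition"]},
        ),
        _map_doc(
            "disease-due-to-allergy",
            "mii-like",
            [
                ("Superconcept", "Condition.code", False),
                (CAUSATIVE_AGENT, "Observation.valueCodeableConcept", False),
                (FINDING_SITE, "Condition.bodySite", False),
                (ASSOCIATED_MORPHOLOGY, "Condition.evidence.code", False),
                (PATHOLOGICAL_PROCESS, "Condition.evidence.code", False),
                (HAS_REALIZATION, "Condition.evidence.code", False),
                (DUE_TO, "Condition.evidence.code", False),
                (CLINICAL_COURSE, f"Condition.extension({_EXT_DISEASE_COURSE})", True),
                (OCCURRENCE, f"Condition.extension({_EXT_OCCURRED_FOLLOWING})", True),
            ],
            evidence_ref_obs,
            {"Condition": mii["Condition"], "Observation": mii["Observation"]},
        ),
        _map_doc(
            "allergic-reaction",
            "nashp-like",
            [
                ("Superconcept", "Condition.code", False),
                (CAUSATIVE_AGENT, "AllergyIntolerance.code", False),
                (FINDING_SITE, "Condition.bodySite", False),
                (ASSOCIATED_MORPHOLOGY, _MANIFESTATION, False),
                (PATHOLOGICAL_PROCESS, _MANIFESTATION, False),
                (HAS_REALIZATION, _MANIFESTATION, False),
                (OCCURRENCE, f"AllergyIntolerance.extension({_EXT_ABATEMENT})", False),
                (CLINICAL_COURSE, f"Condition.extension({_EXT_DISEASE_COURSE})", True),
                (DUE_TO, f"Condition.extension({_EXT_DUE_TO})", True),
            ],
            evidence_ref,
            {"AllergyIntolerance": kbv["AllergyIntolerance"], "Condition": kbv["Condition"]},
        ),
        _map_doc(
            "allergic-reaction",
            "mii-like",
            [
                ("Superconcept", "Condition.code", False),
                (CAUSATIVE_AGENT, "Observation.valueCodeableConcept", False),
                (FINDING_SITE, "Condition.bodySite", False),
                (ASSOCIATED_MORPHOLOGY, "Condition.evidence.code", False),
                (PATHOLOGICAL_PROCESS, "Condition.evidence.code", False),
                (HAS_REALIZATION, "Condition.evidence.code", False),
                (DUE_TO, "Condition.evidence.code", False),
                (CLINICAL_COURSE, f"Condition.extension({_EXT_DISEASE_COURSE})", True),
            ],
            evidence_ref_obs,
            {"Condition": mii["Condition"], "Observation": mii["Observation"]},
        ),
        _map_doc(
            "clinical-finding",
            "nashp-like",
            [
                ("Superconcept", "Condition.code", False),
                (FINDING_SITE, "Condition.bodySite", False),
                (ASSOCIATED_MORPHOLOGY, "Condition.evidence.code", False),
                (PATHOLOGICAL_PROCESS, "Condition.evidence.code", False),
                (CLINICAL_COURSE, f"Condition.extension({_EXT_DISEASE_COURSE})", True),
                (CAUSATIVE_AGENT, f"Condition.extension({_EXT_CAUSATIVE})", True),
            ],
            [],
            {"Condition": kbv["Condition"]},
        ),
        _map_doc(
            "clinical-finding",
            "mii-like",
            [
                ("Superconcept", "Condition.code", False),
                (FINDING_SITE, "Condition.bodySite", False),
                (ASSOCIATED_MORPHOLOGY, "Condition.evidence.code", False),
                (CAUSATIVE_AGENT, "Observation.valueCodeableConcept", False),
                (CLINICAL_COURSE, f"Condition.extension({_EXT_DISEASE_COURSE})", True),
                (PATHOLOGICAL_PROCESS, f"Condition.extension({_EXT_PATH_PROCESS})", True),
            ],
            evidence_ref_obs,
            {"Condition": mii["Condition"], "Observation": mii["Observation"]},
        ),
    ]
    for profile_set, profile in (("nashp-like", kbv["Procedure"]), ("mii-like", mii["Procedure"])):
        docs.append(
            _map_doc(
                "procedure",
                profile_set,
                [
                    ("Superconcept", "Procedure.code", False),
                    (METHOD, "Procedure.category", False),
                    (PROCEDURE_SITE_DIRECT, "Procedure.bodySite", False),
                    (PROCEDURE_SITE_INDIRECT, "Procedure.bodySite", False),
                    (DIRECT_SUBSTANCE, "Procedure.usedCode", False),
                    (USING_SUBSTANCE, "Procedure.usedCode", False),
                    (DIRECT_MORPHOLOGY, "Procedure.reasonCode", False),
                    (HAS_INTENT, "Procedure.reasonCode", False),
                    (USING_DEVICE, "Procedure.usedReference.type", False),
                    (USING_ACCESS_DEVICE, "Procedure.usedReference.type", False),
                    (ACCESS, f"Procedure.extension({_EXT_ACCESS})", False),
                    (SURGICAL_APPROACH, f"Procedure.extension({_EXT_SURGICAL_APPROACH})", False),
                    (HAS_FOCUS, f"Procedure.extension({_EXT_HAS_FOCUS})", True),
                ],
                [],
                {"Procedure": profile},
            )
        )
    return docs


@dataclass
class AllergyMini:
    """Handle to the bundled fixture, written under ``directory``."""

    directory: str
    terminology: Terminology
    mrcm_rules: list[MrcmRule]
    mrcm_path: str
    categories_path: str
    maps_dir: str
    flagship_pce: str = field(default="")
    equivalent_pce: str = field(default="")
    manifest: dict = field(default_factory=dict)


def build_allergy_mini(out_dir: str) -> AllergyMini:
    """Write the bundled fixture into ``out_dir`` and load it back.

    The flagship expression refines *Allergic reaction caused by tree nut*
    with a morphology and a finding site; classifying it yields exactly two
    incomparable candidates (the tree-nut reaction and the fully defined
    swelling finding), of which the former shares more ancestors and wins.
    """
    concepts, relationships = _allergy_mini_concepts()
    rf2_dir = os.path.join(out_dir, "rf2")
    _write_rf2(rf2_dir, concepts, relationships)

    mrcm_path = os.path.join(out_dir, "mrcm.yaml")
    with open(mrcm_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(allergy_mini_mrcm(), fh, sort_keys=True)
    categories_path = os.path.join(out_dir, "categories.yaml")
    with open(categories_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(allergy_mini_categories(), fh, sort_keys=True)
    maps_dir = os.path.join(out_dir, "maps")
    os.makedirs(maps_dir, exist_ok=True)
    for doc in allergy_mini_structuremaps():
        with open(os.path.join(maps_dir, doc["id"] + ".json"), "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    term = load_rf2(rf2_dir, LoadConfig())
    flagship = Expression(
        focus_concepts=(ALLERGIC_REACTION_TREE_NUT,),
        ungrouped=frozenset(
            {
                AttributePair(ASSOCIATED_MORPHOLOGY, SWELLING_MORPHOLOGY),
                AttributePair(FINDING_SITE, EYELID_STRUCTURE),
            }
        ),
    )
    equivalent = Expression(
        focus_concepts=(ALLERGIC_DISPOSITION,),
        groups=(frozenset({AttributePair(CAUSATIVE_AGENT, NUT_SUBSTANCE)}),),
    )
    return AllergyMini(
        directory=out_dir,
        terminology=term,
        mrcm_rules=load_mrcm(mrcm_path),
        mrcm_path=mrcm_path,
        categories_path=categories_path,
        maps_dir=maps_dir,
        flagship_pce=serialize(flagship),
        equivalent_pce=serialize(equivalent),
        manifest={
            "concept_count": len(concepts),
            "active_concept_count": sum(1 for c in concepts if c[2]),
            "map_count": 10,
            "flagship_candidates": [ALLERGIC_REACTION_TREE_NUT, SWELLING_FINDING],
            "flagship_superconcept": ALLERGIC_REACTION_TREE_NUT,
            "equivalent_concept": NUT_ALLERGY,
        },
    )
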