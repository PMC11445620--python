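"""Expression constraints, StructureMaps, resource emission, reverse
mapping and coverage accounting."""

from __future__ import annotations

import copy
import json

import pytest

from pcebridge import fixtures as fx
from pcebridge.ecl import eval_ecl_lite
from pcebridge.errors import (
    CategoryError,
    DisjointnessError,
    EclSyntaxError,
    RecompositionError,
    ReverseMappingError,
    StructureMapSchemaError,
)
from pcebridge.expression import parse, serialize
from pcebridge.fhir import (
    Binding,
    apply_mapping,
    assign_category,
    check_disjoint,
    coverage_report,
    emit_resources,
    extract_bindings,
    load_categories,
    load_structuremap,
    load_structuremap_dir,
    recompose,
    reverse_attribute,
    select_map,
)
from pcebridge.superdelta import Delta


@pytest.fixture(scope="module")
def maps(mini):
    return load_structuremap_dir(mini.maps_dir)


@pytest.fixture(scope="module")
def categories(mini, term):
    return load_categories(mini.categories_path, term)


@pytest.fixture(scope="module")
def ar_nashp(maps):
    return select_map(maps, "allergic-reaction", "nashp-like")


class TestEclLite:
    def test_universal_constraint_matches_every_concept(self, term):
        assert all(eval_ecl_lite(term, f"<< {term.root_id}", c) for c in term.concepts)

    def test_minus_excludes_shared_descendants(self, term):
        constraint = f"<< {fx.SUBSTANCE} MINUS << {fx.NUT_SUBSTANCE}"
        assert eval_ecl_lite(term, constraint, fx.DRUG_SUBSTANCE)
        assert not eval_ecl_lite(term, constraint, fx.TREE_NUT_SUBSTANCE)

    def test_strict_descendant_excludes_self(self, term):
        assert not eval_ecl_lite(term, f"< {fx.SUBSTANCE}", fx.SUBSTANCE)
        assert eval_ecl_lite(term, f"< {fx.SUBSTANCE}", fx.POLLEN)

    def test_and_conjunction(self, term):
        constraint = f"<< {fx.NUT_SUBSTANCE} AND << {fx.SUBSTANCE}"
        assert eval_ecl_lite(term, constraint, fx.TREE_NUT_SUBSTANCE)
        assert not eval_ecl_lite(term, constraint, fx.POLLEN)

    def test_parentheses_grouping(self, term):
        constraint = f"<< {fx.SUBSTANCE} MINUS (<< {fx.NUT_SUBSTANCE} AND << {fx.SUBSTANCE})"
        assert eval_ecl_lite(term, constraint, fx.POLLEN)
        assert not eval_ecl_lite(term, constraint, fx.NUT_SUBSTANCE)

    @pytest.mark.parametrize("bad", ["<<", "<< abc", "<< 1 AND", "(<< 100001", "100001"])
    def test_grammar_violations_raise(self, term, bad):
        with pytest.raises(EclSyntaxError):
            eval_ecl_lite(term, bad, term.root_id)


class TestCategories:
    def test_procedure_expression_lands_in_procedure_category(self, term, categories):
        expr = parse(f"{fx.ALLERGY_TESTING}:{fx.METHOD}={fx.EVALUATION_ACTION}")
        assert assign_category(term, expr, categories).id == "procedure"

    def test_flagship_is_allergic_reaction(self, term, categories, mini):
        expr = parse(mini.flagship_pce)
        assert assign_category(term, expr, categories).id == "allergic-reaction"

    def test_expression_outside_all_constraints_raises(self, term, categories):
        expr = parse(fx.POLLEN)  # a substance belongs to no content category
        with pytest.raises(CategoryError):
            assign_category(term, expr, categories)

    def test_superconcept_fallback(self, term, categories):
        # substance focus, but the superconcept places it
        expr = parse(fx.POLLEN)
        cat = assign_category(term, expr, categories, superconcept=fx.EDEMA_FINDING)
        assert cat.id == "clinical-finding"

    def test_overlapping_configuration_detected(self, term, categories):
        overlapping = list(categories) + [
            type(categories[0])(
                id="dup",
                name="overlap",
                constraint=f"<< {fx.CLINICAL_FINDING}",
                profile_sets=("nashp-like",),
            )
        ]
        with pytest.raises(DisjointnessError):
            check_disjoint(term, overlapping)


class TestStructureMapLoading:
    def test_bundle_has_five_categories_times_two_profile_sets(self, maps):
        assert len(maps) == 10
        combos = {(m.category_id, m.profile_set_id) for m in maps}
        assert len(combos) == 10
        assert len({c for c, _ in combos}) == 5
        assert {p for _, p in combos} == {"nashp-like", "mii-like"}

    def test_allergic_reaction_map_binds_causative_agent_to_code(self, ar_nashp):
        rule = next(r for r in ar_nashp.rules if r.source == fx.CAUSATIVE_AGENT)
        assert rule.target_path == "AllergyIntolerance.code"

    def test_superconcept_rule_path(self, ar_nashp):
        assert ar_nashp.superconcept_rule.target_path == "Condition.code"

    def test_duplicate_superconcept_rule_rejected(self, mini):
        doc = fx.allergy_mini_structuremaps()[0]
        doc = copy.deepcopy(doc)
        doc["group"][0]["rule"].append(copy.deepcopy(doc["group"][0]["rule"][0]))
        doc["group"][0]["rule"][-1]["name"] = "second"
        with pytest.raises(StructureMapSchemaError):
            load_structuremap(doc)

    def test_unparseable_path_rejected(self):
        doc = copy.deepcopy(fx.allergy_mini_structuremaps()[0])
        doc["group"][0]["rule"][1]["target"][0]["element"] = "Condition..code("
        with pytest.raises(StructureMapSchemaError):
            load_structuremap(doc)


class TestApplyMapping:
    def test_paper_rule_table_bindings(self, term, ar_nashp):
        delta = Delta(
            frozenset(
                {
                    (fx.CAUSATIVE_AGENT, fx.POLLEN),
                    (fx.FINDING_SITE, fx.SKIN_STRUCTURE),
                }
            )
        )
        result = apply_mapping(ar_nashp, fx.ALLERGIC_REACTION, delta, term)
        by_source = {b.source: b for b in result.bindings}
        assert by_source[fx.CAUSATIVE_AGENT].path == "AllergyIntolerance.code"
        assert by_source[fx.FINDING_SITE].path == "Condition.bodySite"
        assert by_source["Superconcept"].path == "Condition.code"
        assert result.unmapped == frozenset()

    def test_unmatched_attribute_lands_in_unmapped(self, term, ar_nashp):
        delta = Delta(frozenset({(fx.METHOD, fx.EVALUATION_ACTION)}))
        result = apply_mapping(ar_nashp, fx.ALLERGIC_REACTION, delta, term)
        assert result.unmapped == {(fx.METHOD, fx.EVALUATION_ACTION)}
        assert len(result.bindings) == 1  # superconcept only

    def test_every_delta_edge_is_bound_or_unmapped(self, term, ar_nashp):
        delta = Delta(
            frozenset(
                {
                    (fx.CAUSATIVE_AGENT, fx.POLLEN),
                    (fx.METHOD, fx.EVALUATION_ACTION),
                    (fx.CLINICAL_COURSE, fx.CHRONIC),
                }
            )
        )
        result = apply_mapping(ar_nashp, fx.ALLERGIC_REACTION, delta, term)
        bound = {(b.source, b.code) for b in result.bindings if b.source != "Superconcept"}
        assert bound | result.unmapped == delta.edges
        assert len(result.bindings) == 1 + len(delta.edges) - len(result.unmapped)

    def test_ancestor_rule_source_catches_descendant_attribute(self, term):
        # a map binding only Using device must still catch a Using access
        # device edge via the nearest ancestor rule source
        doc = fx._map_doc(
            "procedure",
            "custom",
            [
                ("Superconcept", "Procedure.code", False),
                (fx.PROCEDURE_DEVICE, "Procedure.focalDevice.manipulated", False),
                (fx.USING_DEVICE, "Procedure.usedReference.type", False),
            ],
            [],
            {},
        )
        smap = load_structuremap(doc)
        delta = Delta(frozenset({(fx.USING_ACCESS_DEVICE, fx.ACCESS_CATHETER)}))
        result = apply_mapping(smap, fx.ALLERGY_TESTING, delta, term)
        (binding,) = [b for b in result.bindings if b.source != "Superconcept"]
        # Using device is the nearest ancestor, Procedure device is farther
        assert binding.source == fx.USING_DEVICE
        assert binding.path == "Procedure.usedReference.type"


class TestEmitExtract:
    def _flagship_result(self, term, ar_nashp, mini):
        expr = parse(mini.flagship_pce)
        delta = Delta(
            frozenset(
                {
                    (fx.ASSOCIATED_MORPHOLOGY, fx.SWELLING_MORPHOLOGY),
                    (fx.FINDING_SITE, fx.EYELID_STRUCTURE),
                }
            )
        )
        return apply_mapping(ar_nashp, fx.ALLERGIC_REACTION_TREE_NUT, delta, term)

    def test_one_document_per_resource_type_with_reference(self, term, ar_nashp, mini):
        result = self._flagship_result(term, ar_nashp, mini)
        docs = emit_resources(result, context={"patient": "Patient/p1"})
        types = {d["resourceType"] for d in docs}
        assert types == {"Condition", "AllergyIntolerance"}
        condition = next(d for d in docs if d["resourceType"] == "Condition")
        assert condition["code"]["coding"][0]["code"] == fx.ALLERGIC_REACTION_TREE_NUT
        assert condition["bodySite"]["coding"][0]["code"] == fx.EYELID_STRUCTURE
        detail = condition["evidence"][0]["detail"]
        assert detail["reference"].startswith("AllergyIntolerance/")
        assert condition["subject"]["reference"] == "Patient/p1"

    def test_original_expression_preserved_in_meta_tag(self, term, ar_nashp, mini):
        result = self._flagship_result(term, ar_nashp, mini)
        docs = emit_resources(result, original_expression=mini.flagship_pce)
        for doc in docs:
            tags = {t["system"]: t["code"] for t in doc["meta"]["tag"]}
            assert tags["http://example.org/pcebridge/original-expression"] == mini.flagship_pce

    def test_extract_round_trips_bindings(self, term, ar_nashp, mini):
        result = self._flagship_result(term, ar_nashp, mini)
        docs = emit_resources(result)
        extracted = extract_bindings(docs, ar_nashp)
        assert {(b.path, b.code) for b in extracted} == {
            (b.path, b.code) for b in result.bindings
        }

    def test_non_snomed_codings_are_skipped(self, term, ar_nashp, mini):
        result = self._flagship_result(term, ar_nashp, mini)
        docs = emit_resources(result)
        condition = next(d for d in docs if d["resourceType"] == "Condition")
        condition["code"]["coding"].append(
            {"system": "http://hl7.org/fhir/sid/icd-10", "code": "T78.1"}
        )
        extracted = extract_bindings(docs, ar_nashp)
        assert all(b.code != "T78.1" for b in extracted)

    def test_missing_superconcept_element_blocks_recomposition(
        self, term, ar_nashp, mini
    ):
        result = self._flagship_result(term, ar_nashp, mini)
        docs = emit_resources(result)
        condition = next(d for d in docs if d["resourceType"] == "Condition")
        del condition["code"]
        bindings = extract_bindings(docs, ar_nashp)
        with pytest.raises(RecompositionError):
            recompose(bindings, ar_nashp, term, [])

    def test_extension_path_emission_and_extraction(self, term, maps):
        ar = select_map(maps, "allergic-reaction", "nashp-like")
        delta = Delta(frozenset({(fx.OCCURRENCE, fx.ACUTE)}))
        result = apply_mapping(ar, fx.ALLERGIC_REACTION, delta, term)
        docs = emit_resources(result)
        ai = next(d for d in docs if d["resourceType"] == "AllergyIntolerance")
        (ext,) = ai["extension"]
        assert ext["url"].endswith("abatement-lebensphase-von")
        assert ext["valueCodeableConcept"]["coding"][0]["code"] == fx.ACUTE
        extracted = extract_bindings(docs, ar)
        assert any(b.code == fx.ACUTE for b in extracted)


class TestReverseAttribute:
    def test_single_candidate_path_needs_no_rules(self, term, ar_nashp):
        binding = Binding(path="Condition.bodySite", code=fx.EYELID_STRUCTURE)
        assert reverse_attribute(binding, ar_nashp, term, []) == fx.FINDING_SITE

    def test_rule1_value_range_disambiguates(self, term, ar_nashp, mini):
        # three attributes share the manifestation path; only associated
        # morphology admits a morphology value
        binding = Binding(
            path="AllergyIntolerance.reaction.manifestation.coding:snomed",
            code=fx.SWELLING_MORPHOLOGY,
        )
        assert (
            reverse_attribute(binding, ar_nashp, term, mini.mrcm_rules)
            == fx.ASSOCIATED_MORPHOLOGY
        )

    def test_rule2_most_general_in_chain(self, term, mini):
        # three device attributes in one chain share a path: the most
        # general (Procedure device) is selected
        doc = fx._map_doc(
            "procedure",
            "custom",
            [
                ("Superconcept", "Procedure.code", False),
                (fx.PROCEDURE_DEVICE, "Procedure.usedReference.type", False),
                (fx.USING_DEVICE, "Procedure.usedReference.type", False),
                (fx.USING_ACCESS_DEVICE, "Procedure.usedReference.type", False),
            ],
            [],
            {},
        )
        smap = load_structuremap(doc)
        binding = Binding(path="Procedure.usedReference.type", code=fx.CATHETER)
        assert (
            reverse_attribute(binding, smap, term, mini.mrcm_rules) == fx.PROCEDURE_DEVICE
        )

    def test_rule3_occurrence_heuristic(self, term, maps, mini):
        # direct substance and using substance share Procedure.usedCode and
        # both ranges admit; usage counts favour direct substance
        pmap = select_map(maps, "procedure", "nashp-like")
        binding = Binding(path="Procedure.usedCode", code=fx.TREE_NUT_SUBSTANCE)
        assert (
            reverse_attribute(binding, pmap, term, mini.mrcm_rules) == fx.DIRECT_SUBSTANCE
        )

    def test_unmapped_path_raises(self, term, ar_nashp, mini):
        binding = Binding(path="Condition.note", code=fx.ACUTE)
        with pytest.raises(ReverseMappingError):
            reverse_attribute(binding, ar_nashp, term, mini.mrcm_rules)


class TestRecompose:
    def test_superconcept_only_gives_bare_focus(self, term, ar_nashp, mini):
        bindings = [Binding(path="Condition.code", code=fx.ALLERGIC_REACTION_TREE_NUT)]
        expr = recompose(bindings, ar_nashp, term, mini.mrcm_rules)
        assert serialize(expr) == fx.ALLERGIC_REACTION_TREE_NUT

    def test_full_bindings_rebuild_refinement(self, term, ar_nashp, mini):
        bindings = [
            Binding(path="Condition.code", code=fx.ALLERGIC_REACTION_TREE_NUT),
            Binding(
                path="AllergyIntolerance.reaction.manifestation.coding:snomed",
                code=fx.SWELLING_MORPHOLOGY,
            ),
            Binding(path="Condition.bodySite", code=fx.EYELID_STRUCTURE),
        ]
        expr = recompose(bindings, ar_nashp, term, mini.mrcm_rules)
        assert serialize(expr) == mini.flagship_pce


class TestCoverage:
    def _element_counts(self, categories):
        return {c.id: list(c.attributes) for c in categories}

    def test_printed_rows(self, maps, categories):
        stats = coverage_report(maps, self._element_counts(categories))
        rows = {(r.category_id, r.profile_set_id): r for r in stats.rows}
        nashp_allergies = rows[("allergies", "nashp-like")]
        assert (nashp_allergies.mappable, nashp_allergies.unmappable,
                nashp_allergies.via_extension) == (5, 4, 1)
        assert rows[("procedure", "nashp-like")].mappable == 12

    def test_aggregates_and_extremes(self, maps, categories):
        stats = coverage_report(maps, self._element_counts(categories))
        assert stats.direct_pct == 76.1
        assert stats.with_extension_pct == 93.5
        assert stats.min_direct_pct == 56
        assert stats.max_direct_pct == 92
        assert stats.min_with_extension_pct == 67
        assert stats.max_with_extension_pct == 100

    def test_inconsistent_annotation_raises(self, maps, categories):
        counts = self._element_counts(categories)
        counts["procedure"] = counts["procedure"][:2]  # fewer elements than rules
        with pytest.raises(StructureMapSchemaError):
            coverage_report(maps, counts)
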