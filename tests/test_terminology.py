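"""Terminology loading, is-a reasoning and concept-model validation."""

from __future__ import annotations

import random

import pandas as pd
import pytest

from pcebridge import fixtures as fx
from pcebridge.errors import (
    ConceptLookupError,
    TerminologyIntegrityError,
    TerminologyLoadError,
)
from pcebridge.expression import parse
from pcebridge.ids import is_well_formed, verhoeff_check_digit, verhoeff_valid
from pcebridge.terminology import load_rf2, validate_semantics

from conftest import build_term


class TestIdentifiers:
    def test_verhoeff_classic_example(self):
        assert verhoeff_check_digit("236") == 3
        assert verhoeff_valid("2363")
        assert not verhoeff_valid("2364")

    @pytest.mark.parametrize(
        "sctid", ["71620000", "363698007", "722738000", "252512005", "246075003"]
    )
    def test_real_release_ids_carry_valid_check_digits(self, sctid):
        assert is_well_formed(sctid, check_digit=True)

    @pytest.mark.parametrize("bad", ["12345", "012345678", "1" * 19, "12a456"])
    def test_malformed_ids_rejected(self, bad):
        assert not is_well_formed(bad)

    def test_synthetic_fixture_ids_pass_without_checksum(self):
        assert is_well_formed("100014")
        assert is_well_formed("100014", check_digit=True) in (True, False)  # opt-in only


class TestLoading:
    def test_allergy_mini_declared_concept_count(self, mini, term):
        assert len(term.concepts) == mini.manifest["active_concept_count"]

    def test_missing_file_names_the_file(self, tmp_path):
        with pytest.raises(TerminologyLoadError, match="Concept"):
            load_rf2(str(tmp_path))

    def test_dangling_destination_is_integrity_error(self, tmp_path):
        out = tmp_path / "rf2"
        fx._write_rf2(
            str(out),
            [("100001", "root", True, False), ("100002", "child", True, False),
             (fx.IS_A, "Is a", True, False)],
            [("100002", fx.IS_A, "100001", 0, True),
             (fx.IS_A, fx.IS_A, "100001", 0, True),
             ("100002", fx.IS_A, "999999", 0, True)],
        )
        with pytest.raises(TerminologyIntegrityError, match="999999"):
            load_rf2(str(out))

    def test_isa_cycle_is_detected(self, tmp_path):
        out = tmp_path / "rf2"
        fx._write_rf2(
            str(out),
            [("100001", "root", True, False), ("100002", "a", True, False),
             ("100003", "b", True, False), (fx.IS_A, "Is a", True, False)],
            [("100002", fx.IS_A, "100001", 0, True),
             (fx.IS_A, fx.IS_A, "100001", 0, True),
             ("100002", fx.IS_A, "100003", 0, True),
             ("100003", fx.IS_A, "100002", 0, True)],
        )
        with pytest.raises(TerminologyIntegrityError, match="cycle"):
            load_rf2(str(out))

    def test_inactive_concept_excluded_from_dag_but_indexed(self, tmp_path):
        out = tmp_path / "rf2"
        fx._write_rf2(
            str(out),
            [("100001", "root", True, False), ("100002", "a", True, False),
             ("100003", "gone", False, False), (fx.IS_A, "Is a", True, False)],
            [("100002", fx.IS_A, "100001", 0, True),
             (fx.IS_A, fx.IS_A, "100001", 0, True),
             ("100003", fx.IS_A, "100001", 0, False)],
        )
        term = load_rf2(str(out))
        # count rows by flag in the fixture file: 3 active, 1 inactive
        frame = pd.read_csv(out / "sct2_Concept_Snapshot.txt", sep="\t", dtype=str)
        assert (frame["active"] == "1").sum() == 3
        assert len(term.concepts) == 3
        assert "100003" in term.inactive
        assert "100003" not in term.isa


class TestAncestors:
    def test_root_is_its_only_ancestor(self, chain_term):
        assert chain_term.ancestors("100001") == {"100001"}

    def test_linear_chain(self, chain_term):
        assert chain_term.ancestors("100003") == {"100003", "100002", "100001"}

    def test_diamond_has_four_ancestors(self, diamond_term):
        assert len(diamond_term.ancestors("100004")) == 4

    def test_unknown_id_raises(self, chain_term):
        with pytest.raises(ConceptLookupError):
            chain_term.ancestors("999999")

    def test_subtype_reflexive_and_chain(self, chain_term):
        assert chain_term.is_subtype("100002", "100002")
        assert chain_term.is_subtype("100003", "100001")
        assert not chain_term.is_subtype("100001", "100003")

    def test_diamond_subtype_both_parents(self, diamond_term):
        assert diamond_term.is_subtype("100004", "100002")
        assert diamond_term.is_subtype("100004", "100003")

    def test_agrees_with_brute_force_closure_oracle(self, term):
        # independent oracle: recursive parent walk, memoised
        memo: dict[str, frozenset[str]] = {}

        def closure(cid: str) -> frozenset[str]:
            if cid not in memo:
                members = {cid}
                for p in term.isa.successors(cid):
                    members |= closure(p)
                memo[cid] = frozenset(members)
            return memo[cid]

        for cid in term.concepts:
            assert term.ancestors(cid) == closure(cid)

    def test_ancestor_monotonicity(self, term):
        rng = random.Random(7)
        ids = sorted(term.concepts, key=int)
        for a in rng.sample(ids, 25):
            for b in term.ancestors(a):
                assert term.ancestors(b) <= term.ancestors(a)


class TestValidateSemantics:
    def test_conforming_expression_ok(self, term, mini):
        expr = parse(f"{fx.ALLERGIC_REACTION}:{{{fx.CAUSATIVE_AGENT}={fx.POLLEN}}}")
        assert validate_semantics(term, mini.mrcm_rules, expr).ok

    def test_value_outside_range_is_error(self, term, mini):
        # a body structure is no causative agent
        expr = parse(f"{fx.ALLERGIC_REACTION}:{{{fx.CAUSATIVE_AGENT}={fx.SKIN_STRUCTURE}}}")
        report = validate_semantics(term, mini.mrcm_rules, expr)
        assert not report.ok
        assert any(i.code == "range-violation" for i in report.errors())

    def test_cardinality_violation_in_one_group(self, term, mini):
        expr = parse(
            f"{fx.ALLERGIC_REACTION}:{{{fx.CAUSATIVE_AGENT}={fx.POLLEN},"
            f"{fx.CAUSATIVE_AGENT}={fx.DRUG_SUBSTANCE}}}"
        )
        report = validate_semantics(term, mini.mrcm_rules, expr)
        assert any(i.code == "cardinality-violation" for i in report.errors())

    def test_domain_violation(self, term, mini):
        # procedure attribute on a finding focus
        expr = parse(f"{fx.ALLERGIC_REACTION}:{fx.METHOD}={fx.EVALUATION_ACTION}")
        report = validate_semantics(term, mini.mrcm_rules, expr)
        assert any(i.code == "domain-violation" for i in report.errors())

    def test_unknown_attribute_and_concept(self, term, mini):
        expr = parse("100012:999999=100033")
        report = validate_semantics(term, mini.mrcm_rules, expr)
        codes = {i.code for i in report.errors()}
        assert "unknown-concept" in codes

    def test_ungroupable_attribute_flagged_when_grouped(self, term, mini):
        expr = parse(f"{fx.ALLERGIC_REACTION}:{{{fx.CLINICAL_COURSE}={fx.ACUTE}}}")
        report = validate_semantics(term, mini.mrcm_rules, expr)
        assert any(i.code == "ungroupable-attribute" for i in report.errors())


class TestAttributeUsageCounts:
    def test_counts_match_manual_fixture_tally(self, term):
        # causative agent used 3x for substances, using substance once
        counts = term.attribute_usage_counts(fx.SUBSTANCE)
        assert counts[fx.CAUSATIVE_AGENT] == 3
        assert counts[fx.USING_SUBSTANCE] == 1
        assert counts[fx.DIRECT_SUBSTANCE] == 3

    def test_value_with_no_occurrences_gives_empty_map(self, term):
        assert term.attribute_usage_counts(fx.CATHETER) == {}

    def test_counts_restrict_to_value_subtree(self, term):
        counts = term.attribute_usage_counts(fx.TREE_NUT_SUBSTANCE)
        assert counts == {fx.CAUSATIVE_AGENT: 2, fx.DIRECT_SUBSTANCE: 2}


def test_dag_has_topological_order(term):
    import networkx as nx

    assert nx.is_directed_acyclic_graph(term.isa)
    assert len(list(nx.topological_sort(term.isa))) == len(term.concepts)
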