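"""Structural subsumption, Superconcept candidates, expression equivalence."""

from __future__ import annotations

import random

import pytest

from pcebridge import fixtures as fx
from pcebridge.classify import (
    expr_equivalent,
    expr_subsumed_by,
    subsumption_verdict,
    superconcept_candidates,
)
from pcebridge.expression import normalize, parse
from pcebridge.fixtures import FixtureSpec, generate_pce_corpus, generate_terminology

from conftest import build_term


@pytest.fixture()
def five_concept_term():
    # P primitive; D below P; attr; V and V' (V' below V);
    # C fully defined as P + group {(attr, V)}
    return build_term(
        {
            "100001": [],
            "100002": ["100001"],  # P
            "100003": ["100002"],  # D
            "100004": ["100001"],  # attr
            "100005": ["100001"],  # V
            "100006": ["100005"],  # V'
            "100007": ["100002"],  # C
        },
        fully_defined={"100007"},
        definitions={"100007": [("100004", "100005", 1)]},
    )


class TestExprSubsumedBy:
    def test_root_subsumes_everything(self, term):
        norm = normalize(term, parse(f"{fx.ALLERGIC_REACTION}:{{{fx.CAUSATIVE_AGENT}={fx.POLLEN}}}"))
        assert expr_subsumed_by(term, norm, term.root_id)

    def test_defined_concept_subsumes_refined_expression(self, five_concept_term):
        norm = normalize(five_concept_term, parse("100003:{100004=100006}"))
        assert expr_subsumed_by(five_concept_term, norm, "100007")

    def test_missing_group_pair_blocks_subsumption(self):
        term = build_term(
            {
                "100001": [],
                "100002": ["100001"],
                "100003": ["100002"],
                "100004": ["100001"],
                "100005": ["100001"],
                "100006": ["100005"],
                "100008": ["100001"],  # second attribute
                "100009": ["100001"],  # second value
                "100007": ["100002"],
            },
            fully_defined={"100007"},
            definitions={"100007": [("100004", "100005", 1), ("100008", "100009", 1)]},
        )
        norm = normalize(term, parse("100003:{100004=100006}"))
        assert not expr_subsumed_by(term, norm, "100007")

    def test_grouped_definition_needs_grouped_expression(self, five_concept_term):
        # same pair ungrouped does not satisfy the group requirement
        norm = normalize(five_concept_term, parse("100003:100004=100006"))
        assert not expr_subsumed_by(five_concept_term, norm, "100007")


class TestSuperconceptCandidates:
    def test_bare_precoordinated_concept_is_self_equivalent(self, term):
        result = superconcept_candidates(term, parse(fx.ALLERGIC_REACTION))
        assert result.equivalent_to == fx.ALLERGIC_REACTION
        assert result.candidates == {fx.ALLERGIC_REACTION}

    def test_expression_equivalent_to_defined_concept(self, term, mini):
        result = superconcept_candidates(term, parse(mini.equivalent_pce))
        assert result.equivalent_to == fx.NUT_ALLERGY

    def test_flagship_yields_two_incomparable_candidates(self, term, mini):
        result = superconcept_candidates(term, parse(mini.flagship_pce))
        assert result.equivalent_to is None
        assert result.candidates == set(mini.manifest["flagship_candidates"])
        a, b = sorted(result.candidates)
        assert not term.is_subtype(a, b) and not term.is_subtype(b, a)

    def test_minimality_filter(self, five_concept_term):
        # subsumers are {D, P, root} with D below P below root; only the
        # most specific element remains
        result = superconcept_candidates(five_concept_term, parse("100003:100004=100006"))
        assert result.equivalent_to is None
        assert result.candidates == {"100003"}

    def test_incomparable_candidates_kept(self, five_concept_term):
        # the grouped refinement is additionally subsumed by the defined
        # concept C, incomparable with the focus concept D
        result = superconcept_candidates(five_concept_term, parse("100003:{100004=100006}"))
        assert result.candidates == {"100003", "100007"}

    def test_candidates_are_sound_and_minimal_on_random_fixtures(self, tmp_path):
        """Classifier output equals the minimal elements of brute-force
        subsumer enumeration, and no candidate's strict descendant subsumes."""
        for seed in range(5):
            fixture = generate_terminology(
                FixtureSpec(seed=seed, concept_count=60, defined_fraction=0.4),
                str(tmp_path / f"f{seed}"),
            )
            term = fixture.terminology
            corpus = generate_pce_corpus(term, 3, seed, fixture.mrcm_rules, group_probability=0.5)
            for expr in corpus:
                norm = normalize(term, expr)
                subsumers = {c for c in term.concepts if expr_subsumed_by(term, norm, c)}
                result = superconcept_candidates(term, expr)
                if result.equivalent_to is not None:
                    assert result.equivalent_to in subsumers
                    continue
                brute_minimal = {
                    c
                    for c in subsumers
                    if not any(d != c and term.is_subtype(d, c) for d in subsumers)
                }
                assert result.candidates == brute_minimal
                for c in result.candidates:  # soundness
                    assert expr_subsumed_by(term, norm, c)

    def test_monotonicity_refinement_never_enlarges_subsumers(self, term):
        base = parse(f"{fx.ALLERGIC_REACTION_TREE_NUT}")
        refined = parse(f"{fx.ALLERGIC_REACTION_TREE_NUT}:{fx.FINDING_SITE}={fx.EYELID_STRUCTURE}")
        s_base = {c for c in term.concepts if expr_subsumed_by(term, normalize(term, base), c)}
        s_ref = {c for c in term.concepts if expr_subsumed_by(term, normalize(term, refined), c)}
        assert s_ref <= s_base


class TestExprEquivalent:
    def test_reflexive(self, term, mini):
        expr = parse(mini.flagship_pce)
        assert expr_equivalent(term, expr, expr)

    def test_grouping_is_significant(self):
        term = build_term(
            {"100001": [], "71620000": ["100001"], "363698007": ["100001"],
             "722738000": ["100001"]}
        )
        grouped = parse("71620000:{363698007=722738000}")
        ungrouped = parse("71620000:363698007=722738000")
        assert not expr_equivalent(term, grouped, ungrouped)
        # one direction still holds: grouped is subsumed by ungrouped form
        assert subsumption_verdict(term, grouped, ungrouped) == "recomposed-subsumes-original"

    def test_generalized_value_gives_one_directional_subsumption(self, term):
        specific = parse(f"{fx.ALLERGIC_REACTION}:{fx.CAUSATIVE_AGENT}={fx.TREE_NUT_SUBSTANCE}")
        general = parse(f"{fx.ALLERGIC_REACTION}:{fx.CAUSATIVE_AGENT}={fx.NUT_SUBSTANCE}")
        assert not expr_equivalent(term, specific, general)
        assert subsumption_verdict(term, specific, general) == "recomposed-subsumes-original"
        assert subsumption_verdict(term, general, specific) == "original-subsumes-recomposed"
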