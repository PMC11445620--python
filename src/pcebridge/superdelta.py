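"""Superconcept selection by shared-ancestor similarity, and the Delta.

The expression is temporarily inserted into the is-a DAG as a ``pce`` node
below its focus concepts and every Superconcept candidate, with side edges
to its attribute values.  For each candidate c the similarity is

    sim(pce, c) = -log2( (|T(pce) \\ T(c)| - 1) / |T(pce) ∪ T(c)| )

where T(·) is the self-inclusive ancestor set on the augmented graph (the
transient pce node included in the counts).  The subtracted 1 removes the
pce node itself from the nonshared count; when nothing else is nonshared
the candidate is equivalent and scores +inf.  Larger shared-ancestor
overlap gives a larger score, and the argmax is chosen as Superconcept.

The Delta is pure edge subtraction between two dummy-rooted attribute
graphs: the expression's flattened (attribute, value) pairs minus the
Superconcept's flattened defining pairs, under exact pair equality —
imprecisely covered pairs deliberately stay in the Delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .classify import CandidateSet
from .errors import SimilarityDomainError
from .expression import Expression
from .terminology import Terminology

PCE_NODE = "pce"
DUMMY_ROOT = "root"


@dataclass(frozen=True)
class SimilarityScore:
    candidate_id: str
    nonshared: int
    union: int
    value: float  # may be math.inf

    def rounded(self) -> float:
        return float("inf") if math.isinf(self.value) else round(self.value, 2)


@dataclass(frozen=True)
class SuperconceptResult:
    scores: tuple[SimilarityScore, ...]
    chosen: str
    tie_break_used: bool


@dataclass(frozen=True)
class Delta:
    """Residual attribute-value edges not covered by the Superconcept."""

    edges: frozenset[tuple[str, str]]
    dummy_root: str = DUMMY_ROOT


class AugmentedGraph:
    """Transient view of the DAG with the pce node inserted.

    The underlying terminology is never mutated; the handle only derives
    the pce node's is-a parents (focus concepts plus candidates,
    deduplicated) and its attribute edges.
    """

    def __init__(self, term: Terminology, expr: Expression, candidates: CandidateSet):
        self.term = term
        parents = set(expr.focus_concepts) | set(candidates.candidates)
        for cid in parents:
            term.record(cid)
        self.isa_parents: frozenset[str] = frozenset(parents)
        self.attribute_edges: tuple[tuple[str, str], ...] = tuple(
            sorted((p.attribute, p.value_key()) for p in expr.all_pairs())
        )

    def pce_ancestors(self) -> frozenset[str]:
        """Self-inclusive ancestor set of the pce node (is-a edges only)."""
        members: set[str] = {PCE_NODE}
        for parent in self.isa_parents:
            members |= self.term.ancestors(parent)
        return frozenset(members)


def insert_pce_node(
    term: Terminology, expr: Expression, candidates: CandidateSet
) -> AugmentedGraph:
    """Insert the transient pce node; returns the augmented-graph handle."""
    return AugmentedGraph(term, expr, candidates)


def similarity_from_counts(nonshared: int, union: int) -> float:
    """The count-based similarity; +inf when only the pce node is nonshared."""
    if union < 1 or nonshared < 1 or nonshared > union:
        raise SimilarityDomainError(
            f"counts outside domain: nonshared={nonshared}, union={union}"
        )
    if nonshared == 1:
        return math.inf
    return -math.log2((nonshared - 1) / union)


def score_candidates(
    term: Terminology, expr: Expression, candidates: CandidateSet
) -> SuperconceptResult:
    """Score every candidate and choose the Superconcept.

    Ties on the similarity value break toward the candidate with the larger
    ancestor set (more specific), then the lower numeric id.  An
    equivalence short-circuit scores the equivalent concept +inf.
    """
    if not candidates.candidates:
        raise SimilarityDomainError("candidate set is empty")
    if candidates.equivalent_to is not None:
        cid = candidates.equivalent_to
        t_c = term.ancestors(cid)
        score = SimilarityScore(cid, 1, len(t_c) + 1, math.inf)
        return SuperconceptResult((score,), cid, tie_break_used=False)

    graph = insert_pce_node(term, expr, candidates)
    t_pce = graph.pce_ancestors()
    scores = []
    for cid in sorted(candidates.candidates, key=int):
        t_c = term.ancestors(cid)
        nonshared = len(t_pce - t_c)
        union = len(t_pce | t_c)
        scores.append(SimilarityScore(cid, nonshared, union, similarity_from_counts(nonshared, union)))

    def preference(s: SimilarityScore) -> tuple:
        return (s.value, len(term.ancestors(s.candidate_id)), -int(s.candidate_id))

    best = max(scores, key=preference)
    tie = sum(1 for s in scores if s.value == best.value) > 1
    return SuperconceptResult(tuple(scores), best.candidate_id, tie_break_used=tie)


def flattened_defining_pairs(term: Terminology, concept_id: str) -> frozenset[tuple[str, str]]:
    """The concept's defining attribute pairs with role groups flattened."""
    ungrouped, groups = term.definition(concept_id)
    pairs = set(ungrouped)
    for group in groups:
        pairs |= group
    return frozenset((p.attribute, p.value_key()) for p in pairs)


def compute_delta(term: Terminology, expr: Expression, superconcept: str) -> Delta:
    """Edge subtraction of the Superconcept graph from the expression graph."""
    term.record(superconcept)
    pce_edges = {(p.attribute, p.value_key()) for p in expr.all_pairs()}
    super_edges = set(flattened_defining_pairs(term, superconcept))
    return Delta(frozenset(pce_edges - super_edges))


def matched_pairs(term: Terminology, expr: Expression, superconcept: str) -> frozenset[tuple[str, str]]:
    """The expression pairs covered verbatim by the Superconcept definition."""
    pce_edges = {(p.attribute, p.value_key()) for p in expr.all_pairs()}
    super_edges = set(flattened_defining_pairs(term, superconcept))
    return frozenset(pce_edges & super_edges)
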