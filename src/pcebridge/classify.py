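"""Structural EL subsumption between expressions and precoordinated
concepts, and Superconcept candidate computation.

This is the desk-scale replacement for an external description-logic
reasoner: subsumption is decided structurally on normal forms (proximal
primitives plus role-grouped existential restrictions).  The procedure is
sound but deliberately incomplete with respect to full OWL semantics — no
property chains or transitive attributes other than is-a — which suffices
for EL-with-role-groups terminologies.

Matching conventions:

* a definition-side proximal primitive must subsume some proximal
  primitive of the expression;
* an ungrouped definition pair may be matched by any expression pair,
  grouped or ungrouped;
* a definition group must be matched wholly inside a single expression
  group (grouping is significant);
* a pair matches when the expression's attribute is a subtype of the
  definition's attribute and the expression's value is subsumed by the
  definition's value, recursing structurally for nested expression values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .expression import (
    AttributePair,
    Expression,
    NormalizedExpression,
    normalize,
)
from .terminology import Terminology


@dataclass(frozen=True)
class CandidateSet:
    """Minimal precoordinated subsumers of an expression.

    ``equivalent_to`` is set when the expression is logically equivalent to
    a precoordinated concept, in which case it is the sole candidate.
    """

    candidates: frozenset[str]
    equivalent_to: Optional[str] = None


def _concept_normal_form(term: Terminology, concept_id: str) -> NormalizedExpression:
    cache = getattr(term, "_normal_form_cache", None)
    if cache is None:
        cache = {}
        term._normal_form_cache = cache
    cached = cache.get(concept_id)
    if cached is None:
        cached = normalize(term, Expression(focus_concepts=(concept_id,)))
        cache[concept_id] = cached
    return cached


def _value_subsumed(term: Terminology, specific, general) -> bool:
    """Value subsumption: concept-vs-concept by is-a, otherwise structural."""
    if isinstance(specific, str) and isinstance(general, str):
        return term.is_subtype(specific, general)
    spec_norm = (
        normalize(term, specific)
        if isinstance(specific, Expression)
        else _concept_normal_form(term, specific)
    )
    gen_norm = (
        normalize(term, general)
        if isinstance(general, Expression)
        else _concept_normal_form(term, general)
    )
    return _norm_subsumed(term, spec_norm, gen_norm)


def _pair_matches(term: Terminology, expr_pair: AttributePair, def_pair: AttributePair) -> bool:
    if not term.is_subtype(expr_pair.attribute, def_pair.attribute):
        return False
    return _value_subsumed(term, expr_pair.value, def_pair.value)


def _norm_subsumed(
    term: Terminology, e: NormalizedExpression, d: NormalizedExpression
) -> bool:
    """True iff normal form ``e`` is subsumed by normal form ``d``."""
    for p in d.proximal_primitives:
        if not any(p in term.ancestors(q) for q in e.proximal_primitives):
            return False
    all_pairs = set(e.ungrouped)
    for group in e.groups:
        all_pairs |= group
    for def_pair in d.ungrouped:
        if not any(_pair_matches(term, ep, def_pair) for ep in all_pairs):
            return False
    for def_group in d.groups:
        if not any(
            all(any(_pair_matches(term, ep, dp) for ep in expr_group) for dp in def_group)
            for expr_group in e.groups
        ):
            return False
    return True


def expr_subsumed_by(term: Terminology, e: NormalizedExpression, concept_id: str) -> bool:
    """Is the normalized expression subsumed by the precoordinated concept?

    For a primitive concept this reduces to is-a ancestry of a proximal
    primitive; for a fully defined concept the concept's own normal form is
    matched structurally against the expression.
    """
    term.record(concept_id)
    return _norm_subsumed(term, e, _concept_normal_form(term, concept_id))


def superconcept_candidates(term: Terminology, expr: Expression) -> CandidateSet:
    """Direct precoordinated ancestors of an expression.

    Enumerates all active concepts subsuming the expression and keeps the
    minimal (most specific) ones under is-a.  When one of them is also
    subsumed by the expression, the expression is equivalent to it and that
    concept is returned alone.
    """
    e_norm = normalize(term, expr)
    subsumers = [c for c in term.concepts if expr_subsumed_by(term, e_norm, c)]
    for c in sorted(subsumers, key=int):
        if _norm_subsumed(term, _concept_normal_form(term, c), e_norm):
            return CandidateSet(frozenset({c}), equivalent_to=c)
    minimal = [
        c
        for c in subsumers
        if not any(d != c and term.is_subtype(d, c) for d in subsumers)
    ]
    return CandidateSet(frozenset(minimal))


def expr_subsumes_expr(term: Terminology, general: Expression, specific: Expression) -> bool:
    """True iff ``specific`` is structurally subsumed by ``general``."""
    return _norm_subsumed(term, normalize(term, specific), normalize(term, general))


def expr_equivalent(term: Terminology, e1: Expression, e2: Expression) -> bool:
    """Mutual structural subsumption of two expressions."""
    n1, n2 = normalize(term, e1), normalize(term, e2)
    return _norm_subsumed(term, n1, n2) and _norm_subsumed(term, n2, n1)


def subsumption_verdict(term: Terminology, original: Expression, other: Expression) -> str:
    """One of ``equivalent``, ``original-subsumes-recomposed``,
    ``recomposed-subsumes-original``, ``incomparable``."""
    n_orig, n_other = normalize(term, original), normalize(term, other)
    fwd = _norm_subsumed(term, n_other, n_orig)  # other ⊑ original
    bwd = _norm_subsumed(term, n_orig, n_other)  # original ⊑ other
    if fwd and bwd:
        return "equivalent"
    if fwd:
        return "original-subsumes-recomposed"
    if bwd:
        return "recomposed-subsumes-original"
    return "incomparable"
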