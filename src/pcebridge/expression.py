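"""SNOMED Compositional Grammar expressions: parse, serialize, normalize.

The grammar fragment covers the constructs postcoordination actually uses
for clinical content: one or more focus concepts joined with ``+``, an
optional refinement after ``:`` consisting of ungrouped ``attribute=value``
pairs and ``{...}`` role groups, optional ``|term|`` annotations (accepted
and discarded), the ``===`` / ``<<<`` definition-status prefixes, and
parenthesised sub-expressions in value position.  Concrete (numeric/string)
values are out of scope.

Canonical serialization sorts focus concepts and pairs numerically so that
structurally equal expressions render to identical text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import total_ordering
from typing import Union

from .errors import ConceptLookupError, ExpressionSyntaxError, NormalizationError

EQUIVALENT_TO = "equivalentTo"
SUBTYPE_OF = "subtypeOf"

DEFAULT_MAX_NESTING = 2


@dataclass(frozen=True)
class AttributePair:
    """One ``attribute = value`` refinement; value is a concept id or a
    nested :class:`Expression`."""

    attribute: str
    value: Union[str, "Expression"]

    def value_key(self) -> str:
        """Stable sort/equality key for the value (nested values serialize)."""
        return self.value if isinstance(self.value, str) else "(" + serialize(self.value) + ")"

    def sort_key(self) -> tuple:
        return (int(self.attribute), isinstance(self.value, Expression), self.value_key())


@dataclass(frozen=True)
class Expression:
    definition_status: str = EQUIVALENT_TO
    focus_concepts: tuple[str, ...] = ()
    ungrouped: frozenset[AttributePair] = frozenset()
    groups: tuple[frozenset[AttributePair], ...] = ()

    def __post_init__(self):
        if not self.focus_concepts:
            raise ValueError("an expression needs at least one focus concept")
        if len(set(self.focus_concepts)) != len(self.focus_concepts):
            raise ValueError(f"duplicate focus concepts in {self.focus_concepts}")
        if any(not g for g in self.groups):
            raise ValueError("role groups must be non-empty")

    def all_pairs(self) -> frozenset[AttributePair]:
        """Flattened refinement: ungrouped pairs plus every grouped pair."""
        pairs = set(self.ungrouped)
        for group in self.groups:
            pairs |= group
        return frozenset(pairs)

    def has_refinement(self) -> bool:
        return bool(self.ungrouped or self.groups)


@dataclass(frozen=True)
class NormalizedExpression:
    """Normal form: proximal primitive supertypes plus merged refinements."""

    proximal_primitives: frozenset[str]
    ungrouped: frozenset[AttributePair]
    groups: tuple[frozenset[AttributePair], ...]


# -- parsing -------------------------------------------------------------


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def _line_col(self) -> tuple[int, int]:
        consumed = self.text[: self.pos]
        line = consumed.count("\n") + 1
        column = self.pos - (consumed.rfind("\n") + 1)
        return line, column

    def error(self, message: str, expected: str | None = None):
        line, col = self._line_col()
        raise ExpressionSyntaxError(message, line, col, expected)

    def skip_ws(self):
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, literal: str) -> bool:
        self.skip_ws()
        if self.text.startswith(literal, self.pos):
            self.pos += len(literal)
            return True
        return False

    def expect(self, literal: str):
        if not self.take(literal):
            self.error(f"unexpected input {self.text[self.pos:self.pos + 10]!r}", repr(literal))

    def concept_id(self) -> str:
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos].isdigit():
            self.pos += 1
        if self.pos == start:
            self.error("concept identifier expected", "digits")
        cid = self.text[start: self.pos]
        # optional |term| annotation, discarded
        self.skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == "|":
            end = self.text.find("|", self.pos + 1)
            if end < 0:
                self.error("unterminated |term|", "'|'")
            self.pos = end + 1
        return cid


def parse(text: str, max_nesting: int = DEFAULT_MAX_NESTING) -> Expression:
    """Parse compositional-grammar text into an :class:`Expression`.

    Whitespace-insensitive; pipe-delimited terms are discarded; the
    definition status defaults to ``equivalentTo`` when no ``===``/``<<<``
    prefix is present.  Malformed input raises
    :class:`~pcebridge.errors.ExpressionSyntaxError` with line/column.
    """
    scanner = _Scanner(text)
    status = EQUIVALENT_TO
    if scanner.take("==="):
        status = EQUIVALENT_TO
    elif scanner.take("<<<"):
        status = SUBTYPE_OF
    expr = _parse_subexpression(scanner, status, depth=0, max_nesting=max_nesting)
    scanner.skip_ws()
    if scanner.pos != len(scanner.text):
        scanner.error(f"trailing input {scanner.text[scanner.pos:]!r}", "end of expression")
    return expr


def _parse_subexpression(scanner: _Scanner, status: str, depth: int, max_nesting: int) -> Expression:
    focus = [scanner.concept_id()]
    while scanner.take("+"):
        focus.append(scanner.concept_id())
    ungrouped: set[AttributePair] = set()
    groups: list[frozenset[AttributePair]] = []
    if scanner.take(":"):
        first = True
        while True:
            if not first and not scanner.take(","):
                if scanner.peek() != "{":
                    break
            if scanner.peek() == "{":
                scanner.expect("{")
                group = {_parse_pair(scanner, depth, max_nesting)}
                while scanner.take(","):
                    group.add(_parse_pair(scanner, depth, max_nesting))
                scanner.expect("}")
                groups.append(frozenset(group))
            elif scanner.peek().isdigit():
                ungrouped.add(_parse_pair(scanner, depth, max_nesting))
            else:
                if first:
                    scanner.error("refinement expected after ':'", "attribute or '{'")
                break
            first = False
    try:
        return Expression(status, tuple(focus), frozenset(ungrouped), tuple(groups))
    except ValueError as exc:
        scanner.error(str(exc))


def _parse_pair(scanner: _Scanner, depth: int, max_nesting: int) -> AttributePair:
    attribute = scanner.concept_id()
    scanner.expect("=")
    if scanner.peek() == "(":
        if depth + 1 > max_nesting:
            scanner.error(f"nested sub-expression exceeds depth {max_nesting}")
        scanner.expect("(")
        value: Union[str, Expression] = _parse_subexpression(
            scanner, EQUIVALENT_TO, depth + 1, max_nesting
        )
        scanner.expect(")")
    else:
        value = scanner.concept_id()
    return AttributePair(attribute, value)


# -- serialization -------------------------------------------------------


def _serialize_pair(pair: AttributePair) -> str:
    return f"{pair.attribute}={pair.value_key()}"


def _serialize_group(group: frozenset[AttributePair]) -> str:
    return "{" + ",".join(_serialize_pair(p) for p in sorted(group, key=AttributePair.sort_key)) + "}"


def serialize(expr: Expression) -> str:
    """Canonical compositional-grammar text; ``parse(serialize(e))`` equals
    ``e`` up to canonical ordering."""
    prefix = "<<<" if expr.definition_status == SUBTYPE_OF else ""
    text = prefix + "+".join(sorted(expr.focus_concepts, key=int))
    items = [_serialize_pair(p) for p in sorted(expr.ungrouped, key=AttributePair.sort_key)]
    items += sorted(_serialize_group(g) for g in expr.groups)
    if items:
        text += ":" + ",".join(items)
    return text


def canonical(expr: Expression) -> Expression:
    """Re-parse the canonical text: normalizes focus order for equality."""
    return parse(serialize(expr), max_nesting=1_000)


# -- normalization -------------------------------------------------------


def _pair_subsumes(term, general: AttributePair, specific: AttributePair) -> bool:
    """True iff ``specific`` refines ``general`` (attribute and value each
    subsumed).  Nested-expression values are compared only for identity
    here; full structural subsumption lives in the classification module."""
    if not term.is_subtype(specific.attribute, general.attribute):
        return False
    if isinstance(general.value, str) and isinstance(specific.value, str):
        return term.is_subtype(specific.value, general.value)
    return general.value_key() == specific.value_key()


def _prune_redundant(term, pairs: frozenset[AttributePair]) -> frozenset[AttributePair]:
    """Drop any pair subsumed by a strictly more specific sibling."""
    kept = []
    for p in pairs:
        dominated = any(
            q is not p and _pair_subsumes(term, p, q) and not _pair_subsumes(term, q, p)
            for q in pairs
        )
        if not dominated:
            kept.append(p)
    return frozenset(kept)


def _merge_groups(term, refinement: list[frozenset], definitional: list[frozenset]) -> list[frozenset]:
    """Merge definitional groups into refinement groups.

    A definitional group folds into a refinement group when the refinement
    group contains a pair whose attribute and value are each subsumed by
    some pair of the definitional group; otherwise it is kept side by side.
    """
    merged = [set(g) for g in refinement]
    for dgroup in definitional:
        target = None
        for group in merged:
            if any(_pair_subsumes(term, dpair, rpair) for dpair in dgroup for rpair in group):
                target = group
                break
        if target is None:
            merged.append(set(dgroup))
        else:
            target |= dgroup
    pruned = [_prune_redundant(term, frozenset(g)) for g in merged]
    # drop subset-match duplicates: a group every pair of which is matched by
    # some pair of another group is redundant; of two mutual duplicates only
    # the first occurrence survives
    result: list[frozenset] = []
    for i, g in enumerate(pruned):
        duplicate = False
        for j, h in enumerate(pruned):
            if i == j:
                continue
            g_in_h = all(any(_pair_subsumes(term, gp, hp) for hp in h) for gp in g)
            if not g_in_h:
                continue
            h_in_g = all(any(_pair_subsumes(term, hp, gp) for gp in g) for hp in h)
            if not h_in_g or j < i:
                duplicate = True
                break
        if not duplicate:
            result.append(g)
    return result


def normalize(term, expr: Expression, max_depth: int = 20) -> NormalizedExpression:
    """Rewrite an expression to its normal form.

    Fully defined focus concepts are replaced (recursively) by their
    proximal primitive supertypes, with their definitional refinements
    merged into the expression's own; nested expression values are
    normalized in place; redundant pairs are pruned by subsumption.
    """
    if max_depth <= 0:
        raise NormalizationError("normalization recursion limit exceeded")
    proximal: set[str] = set()
    ungrouped: set[AttributePair] = set()
    def_groups: list[frozenset[AttributePair]] = []

    def normalize_value(pair: AttributePair) -> AttributePair:
        if isinstance(pair.value, Expression):
            inner = normalize(term, pair.value, max_depth - 1)
            return AttributePair(pair.attribute, _as_expression(inner))
        term.record(pair.value)
        return pair

    for fid in expr.focus_concepts:
        term.record(fid)
        if term.is_fully_defined(fid):
            parents = term.parents(fid)
            d_ungrouped, d_groups = term.definition(fid)
            inner = normalize(
                term,
                Expression(
                    focus_concepts=tuple(sorted(parents, key=int)),
                    ungrouped=d_ungrouped,
                    groups=d_groups,
                ),
                max_depth - 1,
            )
            proximal |= inner.proximal_primitives
            ungrouped |= inner.ungrouped
            def_groups.extend(inner.groups)
        else:
            proximal.add(fid)

    refinement_groups = [frozenset(normalize_value(p) for p in g) for g in expr.groups]
    ungrouped |= {normalize_value(p) for p in expr.ungrouped}
    groups = _merge_groups(term, refinement_groups, def_groups)
    return NormalizedExpression(
        proximal_primitives=frozenset(proximal),
        ungrouped=_prune_redundant(term, frozenset(ungrouped)),
        groups=tuple(sorted((frozenset(g) for g in groups), key=_serialize_group)),
    )


def _as_expression(norm: NormalizedExpression) -> Expression:
    return Expression(
        focus_concepts=tuple(sorted(norm.proximal_primitives, key=int)),
        ungrouped=norm.ungrouped,
        groups=norm.groups,
    )


def normalized_as_expression(norm: NormalizedExpression) -> Expression:
    """Embed a normal form back into an ordinary expression."""
    return _as_expression(norm)
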