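"""ECL-lite: the expression-constraint fragment used for MRCM ranges and
content-category scopes.

Supported syntax::

    constraint := term (("AND" | "MINUS") term)*
    term       := "<<" id | "<" id | "(" constraint ")"

``<< id`` matches the concept itself and all descendants; ``< id`` matches
strict descendants only.  ``AND`` and ``MINUS`` associate left.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import EclSyntaxError

_TOKEN = re.compile(r"\s*(<<|<|\(|\)|AND\b|MINUS\b|\d+)")


@dataclass(frozen=True)
class _Node:
    kind: str  # "dd" (<<), "d" (<), "and", "minus"
    a: object = None
    b: object = None


def parse_constraint(text: str) -> _Node:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise EclSyntaxError(f"unexpected input at {pos!r} in {text!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    tokens.reverse()  # pop() from the front

    def expect_term() -> _Node:
        if not tokens:
            raise EclSyntaxError(f"unexpected end of constraint: {text!r}")
        tok = tokens.pop()
        if tok == "(":
            node = expect_expr()
            if not tokens or tokens.pop() != ")":
                raise EclSyntaxError(f"unbalanced parentheses in {text!r}")
            return node
        if tok in ("<<", "<"):
            if not tokens or not tokens[-1].isdigit():
                raise EclSyntaxError(f"concept id expected after {tok!r} in {text!r}")
            return _Node("dd" if tok == "<<" else "d", tokens.pop())
        raise EclSyntaxError(f"unexpected token {tok!r} in {text!r}")

    def expect_expr() -> _Node:
        node = expect_term()
        while tokens and tokens[-1] in ("AND", "MINUS"):
            op = tokens.pop()
            rhs = expect_term()
            node = _Node("and" if op == "AND" else "minus", node, rhs)
        return node

    node = expect_expr()
    if tokens:
        raise EclSyntaxError(f"trailing tokens {tokens[::-1]} in {text!r}")
    return node


def eval_constraint(term, node: _Node, concept_id: str) -> bool:
    """Evaluate a parsed constraint against one concept.

    ``term`` is any object exposing ``is_subtype(child, parent)`` — in
    practice a :class:`~pcebridge.terminology.Terminology`.
    """
    if node.kind == "dd":
        return term.is_subtype(concept_id, node.a)
    if node.kind == "d":
        return concept_id != node.a and term.is_subtype(concept_id, node.a)
    if node.kind == "and":
        return eval_constraint(term, node.a, concept_id) and eval_constraint(term, node.b, concept_id)
    if node.kind == "minus":
        return eval_constraint(term, node.a, concept_id) and not eval_constraint(term, node.b, concept_id)
    raise AssertionError(node.kind)


def eval_ecl_lite(term, constraint: str, concept_id: str) -> bool:
    """True iff ``concept_id`` is a member of ``constraint`` on ``term``."""
    return eval_constraint(term, parse_constraint(constraint), concept_id)
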