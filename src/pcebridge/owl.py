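"""OWL functional-syntax export of expressions and concept definitions.

Expressions and role-grouped concept definitions translate into class
expressions over three node kinds — ``Class``, ``ObjectSomeValuesFrom`` and
``ObjectIntersectionOf`` — mirroring how a terminology's native OWL
distribution encodes EL-with-role-groups content: each role group becomes an
existential restriction over the role-group property whose filler conjoins
the group's attribute restrictions; ungrouped pairs become direct
existential conjuncts.

A small functional-syntax reader is included so exports can be round-trip
checked structurally; it covers exactly the constructs the writer emits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .errors import PcebridgeError
from .expression import Expression
from .terminology import ROLE_GROUP, Terminology

DEFAULT_NAMESPACE = "http://snomed.info/id/"


@dataclass(frozen=True)
class OwlClass:
    iri: str


@dataclass(frozen=True)
class OwlSomeValuesFrom:
    property_iri: str
    filler: "OwlNode"


@dataclass(frozen=True)
class OwlIntersection:
    operands: tuple["OwlNode", ...]

    def __post_init__(self):
        if len(self.operands) < 2:
            raise ValueError("ObjectIntersectionOf needs at least 2 operands")


OwlNode = Union[OwlClass, OwlSomeValuesFrom, OwlIntersection]


@dataclass(frozen=True)
class OwlAxiom:
    kind: str  # "SubClassOf" | "EquivalentClasses"
    subject: str  # concept id
    expression: OwlNode


def _leading_id(node: OwlNode) -> int:
    """Numeric sort key: the first concept id mentioned in the node."""
    if isinstance(node, OwlClass):
        return int(node.iri.rsplit("/", 1)[-1])
    if isinstance(node, OwlSomeValuesFrom):
        return int(node.property_iri.rsplit("/", 1)[-1])
    return _leading_id(node.operands[0])


def _intersection_or_single(nodes: list[OwlNode]) -> OwlNode:
    nodes = sorted(nodes, key=lambda n: (isinstance(n, OwlSomeValuesFrom), _leading_id(n)))
    if len(nodes) == 1:
        return nodes[0]
    return OwlIntersection(tuple(nodes))


def to_owl(
    expr: Expression,
    namespace: str = DEFAULT_NAMESPACE,
    role_group_property: str = ROLE_GROUP,
) -> OwlNode:
    """Translate an expression to an OWL class expression.

    A bare focus concept stays a plain class; anything richer becomes an
    intersection of the focus classes, one existential per ungrouped pair,
    and one role-group existential per group (single-pair groups omit the
    inner intersection).
    """

    def restriction(pair) -> OwlSomeValuesFrom:
        if isinstance(pair.value, Expression):
            filler: OwlNode = to_owl(pair.value, namespace, role_group_property)
        else:
            filler = OwlClass(namespace + pair.value)
        return OwlSomeValuesFrom(namespace + pair.attribute, filler)

    conjuncts: list[OwlNode] = [OwlClass(namespace + f) for f in expr.focus_concepts]
    conjuncts += [restriction(p) for p in expr.ungrouped]
    for group in expr.groups:
        inner = _intersection_or_single([restriction(p) for p in group])
        conjuncts.append(OwlSomeValuesFrom(namespace + role_group_property, inner))
    return _intersection_or_single(conjuncts)


def ontology_axioms(
    term: Terminology,
    namespace: str = DEFAULT_NAMESPACE,
    role_group_property: str = ROLE_GROUP,
) -> list[OwlAxiom]:
    """One axiom per active non-root concept.

    The right-hand side is built from the concept's parents and defining
    pairs by the same construction rules as :func:`to_owl`; fully defined
    concepts yield ``EquivalentClasses``, primitive ones ``SubClassOf``.
    """
    axioms = []
    for cid in sorted(term.concepts, key=int):
        if cid == term.root_id:
            continue
        ungrouped, groups = term.definition(cid)
        rhs = to_owl(
            Expression(
                focus_concepts=tuple(sorted(term.parents(cid), key=int)),
                ungrouped=ungrouped,
                groups=groups,
            ),
            namespace,
            role_group_property,
        )
        kind = "EquivalentClasses" if term.is_fully_defined(cid) else "SubClassOf"
        axioms.append(OwlAxiom(kind, cid, rhs))
    return axioms


# -- rendering -----------------------------------------------------------


def render(node: OwlNode, namespace: str = DEFAULT_NAMESPACE) -> str:
    """Functional-syntax text with the namespace abbreviated to ``:``."""

    def short(iri: str) -> str:
        return ":" + iri[len(namespace):] if iri.startswith(namespace) else "<" + iri + ">"

    if isinstance(node, OwlClass):
        return short(node.iri)
    if isinstance(node, OwlSomeValuesFrom):
        return f"ObjectSomeValuesFrom({short(node.property_iri)} {render(node.filler, namespace)})"
    return "ObjectIntersectionOf(" + " ".join(render(o, namespace) for o in node.operands) + ")"


def render_axiom(axiom: OwlAxiom, namespace: str = DEFAULT_NAMESPACE) -> str:
    subject = ":" + axiom.subject
    return f"{axiom.kind}({subject} {render(axiom.expression, namespace)})"


def write_functional_syntax(
    axioms: list[OwlAxiom],
    out_path: str,
    namespace: str = DEFAULT_NAMESPACE,
    ontology_iri: str = "http://example.org/terminology",
) -> None:
    """Write a parseable OWL 2 functional-syntax document."""
    lines = [
        f"Prefix(:=<{namespace}>)",
        f"Ontology(<{ontology_iri}>",
        *(render_axiom(a, namespace) for a in axioms),
        ")",
    ]
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# -- reading back (structural round-trip checks) -------------------------


class _OwlScanner:
    def __init__(self, text: str):
        self.tokens = (
            text.replace("(", " ( ").replace(")", " ) ").split()
        )
        self.pos = 0

    def peek(self) -> str:
        if self.pos >= len(self.tokens):
            raise PcebridgeError("unexpected end of OWL document")
        return self.tokens[self.pos]

    def pop(self) -> str:
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, tok: str):
        got = self.pop()
        if got != tok:
            raise PcebridgeError(f"expected {tok!r}, got {got!r}")


def _parse_iri(token: str, namespace: str) -> str:
    if token.startswith(":"):
        return namespace + token[1:]
    if token.startswith("<") and token.endswith(">"):
        return token[1:-1]
    raise PcebridgeError(f"not an IRI token: {token!r}")


def _parse_class_expression(scanner: _OwlScanner, namespace: str) -> OwlNode:
    tok = scanner.pop()
    if tok == "ObjectSomeValuesFrom":
        scanner.expect("(")
        prop = _parse_iri(scanner.pop(), namespace)
        filler = _parse_class_expression(scanner, namespace)
        scanner.expect(")")
        return OwlSomeValuesFrom(prop, filler)
    if tok == "ObjectIntersectionOf":
        scanner.expect("(")
        operands = []
        while scanner.peek() != ")":
            operands.append(_parse_class_expression(scanner, namespace))
        scanner.expect(")")
        return OwlIntersection(tuple(operands))
    return OwlClass(_parse_iri(tok, namespace))


def parse_functional_syntax(path: str) -> tuple[str, list[OwlAxiom]]:
    """Read a document written by :func:`write_functional_syntax`.

    Returns the namespace and the axioms; used for structural round-trip
    verification of the export.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    scanner = _OwlScanner(text)
    scanner.expect("Prefix")
    scanner.expect("(")
    prefix_decl = scanner.pop()
    if not prefix_decl.startswith(":=<") or not prefix_decl.endswith(">"):
        raise PcebridgeError(f"unexpected prefix declaration {prefix_decl!r}")
    namespace = prefix_decl[3:-1]
    scanner.expect(")")
    scanner.expect("Ontology")
    scanner.expect("(")
    _ = _parse_iri(scanner.pop(), namespace)  # ontology IRI
    axioms = []
    while scanner.peek() != ")":
        kind = scanner.pop()
        if kind not in ("SubClassOf", "EquivalentClasses"):
            raise PcebridgeError(f"unexpected axiom kind {kind!r}")
        scanner.expect("(")
        subject_iri = _parse_iri(scanner.pop(), namespace)
        expression = _parse_class_expression(scanner, namespace)
        scanner.expect(")")
        axioms.append(OwlAxiom(kind, subject_iri[len(namespace):], expression))
    scanner.expect(")")
    return namespace, axioms
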