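"""Boolean formulas over gene identifiers.

One grammar serves two places: gene-protein-reaction (GPR) strings attached to
reactions, and the rule bodies of the Boolean transcription-factor network.
GPRs use only AND/OR (genome-scale reconstructions encode isozymes with OR and
enzyme complexes with AND); regulatory rules additionally allow NOT.

Operators are case-insensitive keywords; everything else that matches
``[A-Za-z0-9_.:\\-]+`` is an identifier. An identifier may therefore contain a
namespace prefix such as ``env:o2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator


class GPRSyntaxError(ValueError):
    """Malformed Boolean formula; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Not:
    operand: "Node"


@dataclass(frozen=True)
class And:
    operands: tuple


@dataclass(frozen=True)
class Or:
    operands: tuple


Node = Var | Not | And | Or

_TOKEN = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[A-Za-z0-9_.:\-]+))")


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    pos = 0
    n = len(text)
    while pos < n:
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                bad = text[pos:].strip()[0]
                raise GPRSyntaxError(f"unexpected character {bad!r}", pos)
            break
        yield m.lastgroup, m.group(m.lastgroup), m.start(m.lastgroup)
        pos = m.end()


class _Parser:
    """Recursive descent over ``or_expr -> and_expr (OR and_expr)*`` etc.

    Precedence: NOT > AND > OR, the convention of both GPR strings and
    regulatory-rule files.
    """

    def __init__(self, text: str, allow_not: bool):
        self.text = text
        self.allow_not = allow_not
        self.tokens = list(_tokenize(text))
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of formula", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> Node:
        node = self._or_expr()
        tok = self._peek()
        if tok is not None:
            raise GPRSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def _or_expr(self) -> Node:
        parts = [self._and_expr()]
        while True:
            tok = self._peek()
            if tok and tok[0] == "word" and tok[1].lower() == "or":
                self._next()
                parts.append(self._and_expr())
            else:
                break
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def _and_expr(self) -> Node:
        parts = [self._atom()]
        while True:
            tok = self._peek()
            if tok and tok[0] == "word" and tok[1].lower() == "and":
                self._next()
                parts.append(self._atom())
            else:
                break
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def _atom(self) -> Node:
        kind, value, pos = self._next()
        if kind == "lpar":
            node = self._or_expr()
            tok = self._next()
            if tok[0] != "rpar":
                raise GPRSyntaxError("expected ')'", tok[2])
            return node
        if kind == "rpar":
            raise GPRSyntaxError("unexpected ')'", pos)
        low = value.lower()
        if low == "not":
            if not self.allow_not:
                raise GPRSyntaxError("NOT is not allowed in this formula dialect", pos)
            return Not(self._atom())
        if low in ("and", "or"):
            raise GPRSyntaxError(f"operand expected, found {value!r}", pos)
        return Var(value)


def parse_formula(text: str, allow_not: bool = False) -> Node | None:
    """Parse a Boolean formula; ``None`` for an empty/blank string."""
    if text is None or not text.strip():
        return None
    return _Parser(text, allow_not).parse()


def evaluate(node: Node | None, lookup: Callable[[str], bool]) -> bool:
    """Evaluate an AST; an empty formula (None) is vacuously true."""
    if node is None:
        return True
    if isinstance(node, Var):
        return bool(lookup(node.name))
    if isinstance(node, Not):
        return not evaluate(node.operand, lookup)
    if isinstance(node, And):
        return all(evaluate(o, lookup) for o in node.operands)
    if isinstance(node, Or):
        return any(evaluate(o, lookup) for o in node.operands)
    raise TypeError(f"not a formula node: {node!r}")


def variables(node: Node | None) -> frozenset[str]:
    """All identifiers referenced by a formula."""
    if node is None:
        return frozenset()
    if isinstance(node, Var):
        return frozenset((node.name,))
    if isinstance(node, Not):
        return variables(node.operand)
    out: set[str] = set()
    for o in node.operands:
        out |= variables(o)
    return frozenset(out)


def evaluate_gpr(gpr: str, states) -> bool:
    """Evaluate a GPR string against a gene-state mapping.

    ``states`` is any mapping gene -> bool; genes absent from the mapping
    default to ON (the regulatory layer only restricts genes it reaches).
    An empty GPR means the reaction needs no gene product and is always
    available.
    """
    node = parse_formula(gpr, allow_not=False)
    return evaluate(node, lambda g: states.get(g, True))
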