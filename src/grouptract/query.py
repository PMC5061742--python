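"""ROI query expressions over label volumes.

A small set algebra for building inclusion/exclusion masks from a labelled
segmentation (FreeSurfer aparc+aseg style):

    expr   :=  diff ( "|" diff )*          union        (lowest precedence)
    diff   :=  inter ( "-" inter )*        set difference (left-assoc)
    inter  :=  unary ( "&" unary )*        intersection
    unary  :=  "!" unary | atom            complement   (highest precedence)
    atom   :=  "(" expr ")"
            |  "dilate" "(" expr "," INT ")"
            |  NAME | INT | "quoted name"

Label names are matched case-insensitively against the LUT; names containing
hyphens or spaces (e.g. "ctx-lh-precentral") must be quoted, since the bare
hyphen is the difference operator.  ``dilate(e, k)`` applies ``k`` iterations
of 26-neighborhood binary dilation.  A gray/white boundary mask is expressed
compositionally, e.g. ``dilate("ctx-lh-precentral", 1) & "cerebral-white"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, LabelVolume


class QueryParseError(ValueError):
    """Syntax error in a query string; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class QueryLookupError(KeyError):
    """A label reference that does not resolve against the LUT."""


# --- AST ---------------------------------------------------------------

@dataclass(frozen=True)
class LabelRef:
    name_or_id: str | int


@dataclass(frozen=True)
class Union_:
    left: "QueryExpr"
    right: "QueryExpr"


@dataclass(frozen=True)
class Intersection:
    left: "QueryExpr"
    right: "QueryExpr"


@dataclass(frozen=True)
class Difference:
    left: "QueryExpr"
    right: "QueryExpr"


@dataclass(frozen=True)
class Complement:
    operand: "QueryExpr"


@dataclass(frozen=True)
class Dilate:
    operand: "QueryExpr"
    k: int


QueryExpr = LabelRef | Union_ | Intersection | Difference | Complement | Dilate

# 26-neighborhood structuring element (full 3x3x3 cube)
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<quoted>"[^"]*"|'[^']*')
      | (?P<int>\d+)
      | (?P<name>[A-Za-z_][A-Za-z_0-9]*)
      | (?P<op>[|&!(),-])
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            offset = len(text) - len(stripped)
            raise QueryParseError(f"unknown token {stripped[0]!r}", offset)
        kind = m.lastgroup
        assert kind is not None
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise QueryParseError("unexpected end of query", len(self.text))
        self.i += 1
        return tok

    def expect_op(self, op: str):
        tok = self.peek()
        if tok is None or tok[0] != "op" or tok[1] != op:
            offset = tok[2] if tok else len(self.text)
            raise QueryParseError(f"expected {op!r}", offset)
        self.i += 1

    def parse(self) -> QueryExpr:
        expr = self.union()
        tok = self.peek()
        if tok is not None:
            raise QueryParseError(f"trailing input {tok[1]!r}", tok[2])
        return expr

    def union(self) -> QueryExpr:
        node = self.difference()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] == "|":
            self.i += 1
            node = Union_(node, self.difference())
        return node

    def difference(self) -> QueryExpr:
        node = self.intersection()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] == "-":
            self.i += 1
            node = Difference(node, self.intersection())
        return node

    def intersection(self) -> QueryExpr:
        node = self.unary()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] == "&":
            self.i += 1
            node = Intersection(node, self.unary())
        return node

    def unary(self) -> QueryExpr:
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] == "!":
            self.i += 1
            return Complement(self.unary())
        return self.atom()

    def atom(self) -> QueryExpr:
        tok = self.next()
        kind, value, offset = tok
        if kind == "op" and value == "(":
            node = self.union()
            self.expect_op(")")
            return node
        if kind == "name" and value.lower() == "dilate":
            self.expect_op("(")
            operand = self.union()
            self.expect_op(",")
            ktok = self.next()
            if ktok[0] != "int":
                raise QueryParseError("dilate radius must be a non-negative integer",
                                      ktok[2])
            self.expect_op(")")
            return Dilate(operand, int(ktok[1]))
        if kind == "name":
            return LabelRef(value)
        if kind == "quoted":
            return LabelRef(value[1:-1])
        if kind == "int":
            return LabelRef(int(value))
        raise QueryParseError(f"unexpected token {value!r}", offset)


def parse_query(text: str) -> QueryExpr:
    """Parse a query string into an AST; raises :class:`QueryParseError`
    with the offending character offset on bad input."""
    if not text or not text.strip():
        raise QueryParseError("empty query", 0)
    return _Parser(text).parse()


def _resolve(ref: LabelRef, labels: LabelVolume) -> int:
    key = ref.name_or_id
    if isinstance(key, int):
        if key in labels.lut:
            return key
        raise QueryLookupError(
            f"label ID {key} not in LUT; known: {sorted(labels.lut)}"
        )
    try:
        return labels.id_for_name(key)
    except KeyError:
        known = sorted(labels.lut.values())
        raise QueryLookupError(f"label name {key!r} not in LUT; known: {known}") from None


def evaluate_query(expr: QueryExpr, labels: LabelVolume) -> BinaryMask:
    """Evaluate a query AST to a BinaryMask on the label volume's grid.

    Pure function of its inputs: set semantics voxel-wise, complement within
    the grid, dilation by k iterations of 26-neighborhood dilation.
    """
    return BinaryMask(values=_eval(expr, labels), grid=labels.grid)


def _eval(expr: QueryExpr, labels: LabelVolume) -> np.ndarray:
    if isinstance(expr, LabelRef):
        return labels.labels == _resolve(expr, labels)
    if isinstance(expr, Union_):
        return _eval(expr.left, labels) | _eval(expr.right, labels)
    if isinstance(expr, Intersection):
        return _eval(expr.left, labels) & _eval(expr.right, labels)
    if isinstance(expr, Difference):
        return _eval(expr.left, labels) & ~_eval(expr.right, labels)
    if isinstance(expr, Complement):
        return ~_eval(expr.operand, labels)
    if isinstance(expr, Dilate):
        if expr.k < 0:
            raise ValueError("dilate radius must be >= 0")
        base = _eval(expr.operand, labels)
        if expr.k == 0 or not base.any():
            return base
        return ndimage.binary_dilation(base, structure=_STRUCT_26,
                                       iterations=expr.k)
    raise TypeError(f"not a query expression: {expr!r}")


def evaluate_query_string(text: str, labels: LabelVolume) -> BinaryMask:
    """Convenience: parse then evaluate."""
    return evaluate_query(parse_query(text), labels)
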