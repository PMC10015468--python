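"""Atom-selection query language: parser and evaluator.

The grammar mirrors the human-readable selection syntax of the preparation
tool::

    expr       := term ("or" term)*
    term       := factor ("and" factor)*
    factor     := "not" factor | "(" expr ")" | comparison
    comparison := keyword operator literal

Keywords: ``resname``, ``resid``, ``name``, ``type``, ``id``, ``mol``.
Operators: ``is``, ``not``, ``>``, ``<``, ``>=``/``≥``, ``<=``/``≤``.
Ordering operators apply only to the integer fields ``resid`` and ``id``;
using them on a string field is a parse error.  Keywords and operators are
case-insensitive, literals are case-sensitive.  ``not`` doubles as a
comparison operator (``name not CA``) and as a unary prefix
(``not resname is SOL``), disambiguated by position.

Evaluation against a :class:`~mimicprep.topology.Topology` returns global
atom ids in ascending order; ``and``/``or`` are set
intersection/union and unary ``not`` complements within all atoms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError

KEYWORDS = ("resname", "resid", "name", "type", "id", "mol")
INTEGER_KEYWORDS = ("resid", "id")
_FIELD = {"resname": "resname", "resid": "resid", "name": "name",
          "type": "type", "id": "id", "mol": "mol_name"}

ORDER_OPS = (">", "<", ">=", "<=")
_OP_ALIASES = {"≥": ">=", "≤": "<="}


@dataclass(frozen=True)
class Comparison:
    keyword: str
    operator: str  # one of: is, not, >, <, >=, <=
    literal: str | int


@dataclass(frozen=True)
class And:
    left: object
    right: object


@dataclass(frozen=True)
class Or:
    left: object
    right: object


@dataclass(frozen=True)
class Not:
    operand: object


_TOKEN_RE = re.compile(r"\s*(?:(?P<op>>=|<=|≥|≤|[><()])|(?P<word>[^\s()<>≥≤]+))")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tok = m.group("op") or m.group("word")
        tokens.append((_OP_ALIASES.get(tok, tok), m.start("op")
                       if m.group("op") else m.start("word")))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def fail(self, message: str, pos: int):
        raise ParseError(f"{message} in query {self.text!r}", column=pos)

    def parse(self):
        if not self.tokens:
            raise ParseError("empty selection query")
        ast = self.expr()
        tok, pos = self.peek()
        if tok is not None:
            self.fail(f"unexpected {tok!r}", pos)
        return ast

    def expr(self):
        node = self.term()
        while self.peek()[0] is not None and self.peek()[0].lower() == "or":
            self.next()
            node = Or(node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek()[0] is not None and self.peek()[0].lower() == "and":
            self.next()
            node = And(node, self.factor())
        return node

    def factor(self):
        tok, pos = self.peek()
        if tok is None:
            self.fail("unexpected end of query", pos)
        low = tok.lower()
        if low == "not":
            self.next()
            return Not(self.factor())
        if tok == "(":
            self.next()
            node = self.expr()
            tok2, pos2 = self.next()
            if tok2 != ")":
                self.fail("unbalanced brackets: expected ')'", pos2)
            return node
        if tok == ")":
            self.fail("unbalanced brackets: unexpected ')'", pos)
        if low in KEYWORDS:
            return self.comparison()
        self.fail(f"unknown keyword {tok!r}", pos)

    def comparison(self):
        keyword = self.next()[0].lower()
        op_tok, op_pos = self.next()
        if op_tok is None:
            self.fail(f"dangling {keyword!r}: expected an operator", op_pos)
        op = op_tok.lower() if op_tok.lower() in ("is", "not") else op_tok
        if op not in ("is", "not") + ORDER_OPS:
            self.fail(f"expected an operator after {keyword!r}, got "
                      f"{op_tok!r}", op_pos)
        if op in ORDER_OPS and keyword not in INTEGER_KEYWORDS:
            self.fail(f"operator {op!r} applies only to integer fields "
                      f"{INTEGER_KEYWORDS}", op_pos)
        lit_tok, lit_pos = self.next()
        if lit_tok is None or lit_tok in ("(", ")"):
            self.fail(f"dangling operator {op!r}: expected a value", lit_pos)
        literal: str | int = lit_tok
        if keyword in INTEGER_KEYWORDS:
            try:
                literal = int(lit_tok)
            except ValueError:
                self.fail(f"{keyword!r} needs an integer value, got "
                          f"{lit_tok!r}", lit_pos)
        return Comparison(keyword, op, literal)


def parse_query(text: str) -> Comparison | And | Or | Not:
    """Parse a selection query into its expression tree.

    Raises :class:`ParseError` (with the character position) on unknown
    keywords, dangling operators, or unbalanced brackets.
    """
    if not text or not text.strip():
        raise ParseError("empty selection query")
    return _Parser(text).parse()


def _mask(node, df: pd.DataFrame) -> np.ndarray:
    if isinstance(node, Comparison):
        col = df[_FIELD[node.keyword]]
        if node.keyword in INTEGER_KEYWORDS:
            col = col.astype(int)
        op = node.operator
        if op == "is":
            return (col == node.literal).to_numpy()
        if op == "not":
            return (col != node.literal).to_numpy()
        if op == ">":
            return (col > node.literal).to_numpy()
        if op == "<":
            return (col < node.literal).to_numpy()
        if op == ">=":
            return (col >= node.literal).to_numpy()
        if op == "<=":
            return (col <= node.literal).to_numpy()
        raise AssertionError(op)
    if isinstance(node, And):
        return _mask(node.left, df) & _mask(node.right, df)
    if isinstance(node, Or):
        return _mask(node.left, df) | _mask(node.right, df)
    if isinstance(node, Not):
        return ~_mask(node.operand, df)
    raise TypeError(f"not a query node: {node!r}")


def evaluate(ast, top) -> list[int]:
    """Evaluate a query AST against a topology's global atom table.

    Returns the matching global atom ids in ascending order.
    """
    df = top.global_atoms
    mask = _mask(ast, df)
    return [int(v) for v in df.loc[mask, "id"]]


def select(text: str, top) -> list[int]:
    """Parse and evaluate a query in one call."""
    return evaluate(parse_query(text), top)
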