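"""Gene-protein-reaction (GPR) boolean rules.

A GPR links genes to the catalysis of a reaction: ``and`` means the gene
products form a complex (all required), ``or`` means isozymes (any one
suffices).  An empty rule means the reaction needs no gene product at all
(spontaneous reactions and some transporters in genome-scale models).

Expressions are stored as a tiny immutable tree::

    None                      empty rule (always satisfied)
    "g1"                      single gene leaf
    ("and", (child, ...))     conjunction
    ("or",  (child, ...))     disjunction
"""

from __future__ import annotations

import re
from typing import Iterator, Optional, Union

GprNode = Union[None, str, tuple]

__all__ = [
    "GprError",
    "GprNode",
    "parse_gpr",
    "gpr_genes",
    "eval_gpr",
    "satisfied_leaves",
    "gpr_to_string",
]


class GprError(ValueError):
    """Raised for malformed GPR strings or trees."""


_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-']+)")


def _tokenize(text: str) -> Iterator[str]:
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise GprError(f"unexpected character in GPR at {text[pos:]!r}")
            return
        yield m.group(1)
        pos = m.end()


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprError("unexpected end of GPR expression")
        self.i += 1
        return tok

    # expr := term ('or' term)*
    def expr(self) -> GprNode:
        parts = [self.term()]
        while self.peek() is not None and self.peek().lower() in ("or", "|"):
            self.next()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else ("or", tuple(parts))

    # term := factor ('and' factor)*
    def term(self) -> GprNode:
        parts = [self.factor()]
        while self.peek() is not None and self.peek().lower() in ("and", "&"):
            self.next()
            parts.append(self.factor())
        return parts[0] if len(parts) == 1 else ("and", tuple(parts))

    def factor(self) -> GprNode:
        tok = self.next()
        if tok == "(":
            node = self.expr()
            if self.next() != ")":
                raise GprError("unbalanced parentheses in GPR")
            return node
        if tok == ")" or tok.lower() in ("and", "or", "&", "|"):
            raise GprError(f"unexpected token {tok!r} in GPR")
        return tok


def parse_gpr(text: Optional[str]) -> GprNode:
    """Parse a rule like ``"g1 and (g2 or g3)"`` into a GPR tree.

    Empty or whitespace-only input yields ``None`` (no gene requirement).
    """
    if text is None or not text.strip():
        return None
    tokens = list(_tokenize(text))
    parser = _Parser(tokens)
    node = parser.expr()
    if parser.peek() is not None:
        raise GprError(f"trailing tokens in GPR: {tokens[parser.i:]}")
    return node


def _check(node: GprNode) -> None:
    if node is None or isinstance(node, str):
        return
    if (
        not isinstance(node, tuple)
        or len(node) != 2
        or node[0] not in ("and", "or")
        or not isinstance(node[1], tuple)
        or not node[1]
    ):
        raise GprError(f"malformed GPR tree node: {node!r}")
    for child in node[1]:
        if child is None:
            raise GprError("empty child inside GPR tree")
        _check(child)


def gpr_genes(node: GprNode) -> frozenset:
    """All gene ids occurring anywhere in the rule."""
    _check(node)
    if node is None:
        return frozenset()
    if isinstance(node, str):
        return frozenset([node])
    out: set = set()
    for child in node[1]:
        out |= gpr_genes(child)
    return frozenset(out)


def eval_gpr(node: GprNode, deleted: frozenset | set = frozenset()) -> bool:
    """Evaluate the rule with the given genes deleted (False), others True.

    An empty rule is always satisfied.
    """
    _check(node)
    return _eval(node, frozenset(deleted))


def _eval(node: GprNode, deleted: frozenset) -> bool:
    if node is None:
        return True
    if isinstance(node, str):
        return node not in deleted
    op, children = node
    if op == "and":
        return all(_eval(c, deleted) for c in children)
    return any(_eval(c, deleted) for c in children)


def satisfied_leaves(node: GprNode, deleted: frozenset | set = frozenset()) -> frozenset:
    """Genes on satisfied branches of the rule.

    For an AND node all children must hold for any leaf to count; for an OR
    node only the satisfied children contribute.  Used by the optional
    ``satisfied_leaves`` gene-expression rule of the logic simulator.
    """
    _check(node)
    deleted = frozenset(deleted)

    def rec(n: GprNode) -> frozenset:
        if n is None:
            return frozenset()
        if isinstance(n, str):
            return frozenset() if n in deleted else frozenset([n])
        op, children = n
        if op == "and":
            if not _eval(n, deleted):
                return frozenset()
            out: set = set()
            for c in children:
                out |= rec(c)
            return frozenset(out)
        out = set()
        for c in children:
            if _eval(c, deleted):
                out |= rec(c)
        return frozenset(out)

    return rec(node)


def gpr_to_string(node: GprNode) -> str:
    """Render a GPR tree back to its string form (round-trips with parse)."""
    _check(node)
    if node is None:
        return ""
    if isinstance(node, str):
        return node
    op, children = node
    parts = []
    for c in children:
        s = gpr_to_string(c)
        if isinstance(c, tuple):
            s = f"({s})"
        parts.append(s)
    return f" {op} ".join(parts)
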