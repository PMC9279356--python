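"""Atom-selection mini-grammar.

Grammar (case-insensitive keywords)::

    expr     := term {('and' | 'or') term}*        # left-associative, AND binds tighter
    term     := 'not' term | '(' expr ')' | primary
    primary  := 'all'
              | 'chain'   ID [ID ...]
              | 'resid'   RANGE [RANGE ...]        # RANGE = n or n-m
              | 'resname' NAME [NAME ...]
              | 'name'    NAME [NAME ...]
              | 'element' SYM [SYM ...]

Resolution against a topology is deterministic and returns a sorted
integer index array; the empty selection is valid.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import Atom, Topology

_KEYWORDS = {"and", "or", "not", "all", "chain", "resid", "resname", "name", "element"}

_TOKEN_RE = re.compile(r"\s*([()]|[^\s()]+)")


class SelectionError(ValueError):
    """Raised on a syntax error; message carries the token position."""


@dataclass(frozen=True)
class Selection:
    """A selection expression; resolve with :func:`resolve_selection`."""

    expression: str

    def __str__(self) -> str:
        return self.expression


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


Predicate = Callable[[Atom], bool]


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        if self.i >= len(self.tokens):
            raise SelectionError(
                f"unexpected end of expression at position {len(self.text)}"
            )
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def fail(self, msg: str) -> None:
        pos = self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)
        raise SelectionError(f"{msg} at position {pos} in {self.text!r}")

    # expr := and_expr {'or' and_expr}
    def parse(self) -> Predicate:
        pred = self.parse_or()
        if self.i < len(self.tokens):
            self.fail(f"trailing token {self.peek()!r}")
        return pred

    def parse_or(self) -> Predicate:
        left = self.parse_and()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            right = self.parse_and()
            left = (lambda l, r: lambda a: l(a) or r(a))(left, right)
        return left

    def parse_and(self) -> Predicate:
        left = self.parse_term()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            right = self.parse_term()
            left = (lambda l, r: lambda a: l(a) and r(a))(left, right)
        return left

    def parse_term(self) -> Predicate:
        tok = self.peek()
        if tok is None:
            self.fail("expected a term")
        if tok.lower() == "not":
            self.next()
            inner = self.parse_term()
            return lambda a: not inner(a)
        if tok == "(":
            self.next()
            inner = self.parse_or()
            closing, _ = self.next()
            if closing != ")":
                self.fail("expected ')'")
            return inner
        return self.parse_primary()

    def _collect_values(self) -> list[str]:
        values = []
        while True:
            tok = self.peek()
            if tok is None or tok in ("(", ")") or tok.lower() in ("and", "or", "not"):
                break
            values.append(self.next()[0])
        if not values:
            self.fail("keyword needs at least one value")
        return values

    def parse_primary(self) -> Predicate:
        tok, _ = self.next()
        kw = tok.lower()
        if kw == "all":
            return lambda a: True
        if kw == "chain":
            values = set(self._collect_values())
            return lambda a: a.chain_id in values
        if kw == "resname":
            values = {v.upper() for v in self._collect_values()}
            return lambda a: a.residue_name.upper() in values
        if kw == "name":
            values = {v.upper() for v in self._collect_values()}
            return lambda a: a.name.upper() in values
        if kw == "element":
            values = {v.capitalize() for v in self._collect_values()}
            return lambda a: a.element in values
        if kw == "resid":
            ranges: list[tuple[int, int]] = []
            for v in self._collect_values():
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
                if not m:
                    raise SelectionError(f"bad resid range {v!r} in {self.text!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                ranges.append((lo, hi))
            return lambda a: any(lo <= a.residue_seq <= hi for lo, hi in ranges)
        self.i -= 1
        self.fail(f"unknown keyword {tok!r}")
        raise AssertionError  # unreachable


def compile_selection(sel: Selection | str) -> Predicate:
    expr = sel.expression if isinstance(sel, Selection) else sel
    if not expr.strip():
        raise SelectionError("empty selection expression")
    return _Parser(expr).parse()


def resolve_selection(topology: Topology, sel: Selection | str) -> np.ndarray:
    """Resolve a selection to a sorted array of atom indices."""
    pred = compile_selection(sel)
    idx = [i for i, a in enumerate(topology.atoms) if pred(a)]
    return np.asarray(idx, dtype=np.intp)
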