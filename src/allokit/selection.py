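"""Atom-selection mini-language.

Grammar (case-sensitive keywords, whitespace-separated tokens)::

    expr     := or_expr
    or_expr  := and_expr ( 'or' and_expr )*
    and_expr := unary ( 'and' unary )*
    unary    := 'not' unary | '(' expr ')' | clause
    clause   := 'name' <names>      e.g.  name CA CB
              | 'resname' <names>   e.g.  resname ARG LYS
              | 'chain' <names>     e.g.  chain A B
              | 'resid' <ranges>    e.g.  resid 1-3 7 10-12
              | 'backbone'          == name N CA C O
              | 'calpha'            == name CA

Selections resolve to sorted unique atom indices; an empty result is legal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .trajectory import Topology

__all__ = ["Selection", "SelectionSyntaxError", "select"]

_KEYWORDS = {"and", "or", "not", "name", "resname", "chain", "resid",
             "backbone", "calpha", "(", ")"}
_BACKBONE_NAMES = ("N", "CA", "C", "O")
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class SelectionSyntaxError(ValueError):
    """Selection expression could not be parsed; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Selection:
    """Resolved atom selection: sorted unique indices plus the source text."""

    indices: np.ndarray
    expression: str

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            raise ValueError("selection indices must be unique, sorted, non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


class _Parser:
    def __init__(self, expression: str, topology: Topology):
        self.expr = expression
        self.topo = topology
        self.tokens = [(m.group(), m.start()) for m in _TOKEN_RE.finditer(expression)]
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError("empty selection expression", 0)
        mask = self.or_expr()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionSyntaxError(f"unexpected token {tok!r}", at)
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek()[0] == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek()[0] == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok, at = self.peek()
        if tok == "not":
            self.next()
            return ~self.unary()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            tok, at = self.next()
            if tok != ")":
                raise SelectionSyntaxError("expected ')'", at)
            return mask
        return self.clause()

    def _values(self, keyword: str, at: int) -> list[str]:
        vals = []
        while self.peek()[0] is not None and self.peek()[0] not in _KEYWORDS:
            vals.append(self.next()[0])
        if not vals:
            raise SelectionSyntaxError(f"{keyword!r} needs at least one value", at)
        return vals

    def clause(self) -> np.ndarray:
        tok, at = self.next()
        topo = self.topo
        if tok == "backbone":
            return np.isin(topo.atom_names, _BACKBONE_NAMES)
        if tok == "calpha":
            return topo.atom_names == "CA"
        if tok == "name":
            return np.isin(topo.atom_names, self._values(tok, at))
        if tok == "resname":
            return np.isin(topo.res_names, self._values(tok, at))
        if tok == "chain":
            return np.isin(topo.chain_ids, self._values(tok, at))
        if tok == "resid":
            mask = np.zeros(topo.n_atoms, dtype=bool)
            for val in self._values(tok, at):
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", val)
                if m is None:
                    raise SelectionSyntaxError(f"bad resid token {val!r}", at)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                mask |= (topo.res_ids >= lo) & (topo.res_ids <= hi)
            return mask
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", at)
        raise SelectionSyntaxError(f"unexpected token {tok!r}", at)


def select(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression against a topology.

    Deterministic; an empty result is returned as an empty selection, not
    an error.  Syntax errors carry the character position.
    """
    mask = _Parser(expression, topology).parse()
    return Selection(np.flatnonzero(mask), expression)
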