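"""A small atom-selection language.

Grammar (precedence: ``not`` > ``and`` > ``or``)::

    expr     := term ("or" term)*
    term     := factor ("and" factor)*
    factor   := "not" factor | "(" expr ")" | primitive
    primitive:= keyword value+
    keyword  := segment | chain | resid | resname | name | element | group
    value    := word | integer | integer "-" integer   (resid ranges)

Examples: ``segment protein and resid 172``, ``group F1 and element C``,
``resid 170-175 or resid 195-200``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .core import Atom, Topology
from .errors import SelectionSyntaxError

__all__ = ["AtomSelection", "select"]

_KEYWORDS = {"segment", "chain", "resid", "resname", "name", "element", "group"}
_OPERATORS = {"and", "or", "not"}

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class AtomSelection:
    """A sorted, unique set of atom indices plus the expression that made it."""

    topology: Topology
    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.intp))
        if len(idx) and (idx[0] < 0 or idx[-1] >= self.topology.n_atoms):
            raise ValueError("selection index out of range")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def atoms(self) -> list[Atom]:
        return [self.topology.atoms[i] for i in self.indices]

    def union(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(
            self.topology,
            np.union1d(self.indices, other.indices),
            f"({self.expression}) or ({other.expression})",
        )


def _group_matches(label: str | None, value: str) -> bool:
    if label is None:
        return False
    if label == value:
        return True
    chain_part, _, group_part = label.partition(":")
    return value in (chain_part, group_part)


def _primitive_mask(topology: Topology, keyword: str, values: list[str]) -> np.ndarray:
    mask = np.zeros(topology.n_atoms, dtype=bool)
    for atom in topology.atoms:
        for value in values:
            if keyword == "segment":
                hit = atom.segment.value == value.lower()
            elif keyword == "chain":
                hit = atom.chain_id == value
            elif keyword == "resid":
                if "-" in value.strip("-") or ("-" in value and not value.startswith("-")):
                    lo, hi = value.split("-")
                    hit = int(lo) <= atom.residue_id <= int(hi)
                else:
                    hit = atom.residue_id == int(value)
            elif keyword == "resname":
                hit = atom.residue_name.upper() == value.upper()
            elif keyword == "name":
                hit = atom.name == value
            elif keyword == "element":
                hit = atom.element.upper() == value.upper()
            elif keyword == "group":
                hit = _group_matches(atom.group_label, value)
            else:  # pragma: no cover - guarded by parser
                hit = False
            if hit:
                mask[atom.index] = True
                break
    return mask


@dataclass
class _Parser:
    topology: Topology
    tokens: list[tuple[str, int]]
    pos: int = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse_expr(self) -> np.ndarray:
        mask = self.parse_term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.parse_term()
        return mask

    def parse_term(self) -> np.ndarray:
        mask = self.parse_factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.parse_factor()
        return mask

    def parse_factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError(
                self.tokens[-1][1] if self.tokens else 0, "unexpected end of expression"
            )
        if tok == "not":
            self.next()
            return ~self.parse_factor()
        if tok == "(":
            self.next()
            mask = self.parse_expr()
            if self.peek() != ")":
                _, position = self.tokens[self.pos - 1]
                raise SelectionSyntaxError(position, "missing closing parenthesis")
            self.next()
            return mask
        return self.parse_primitive()

    def parse_primitive(self) -> np.ndarray:
        keyword, position = self.next()
        if keyword not in _KEYWORDS:
            raise SelectionSyntaxError(position, f"unknown keyword {keyword!r}")
        values: list[str] = []
        while True:
            nxt = self.peek()
            if nxt is None or nxt in _KEYWORDS | _OPERATORS or nxt in ("(", ")"):
                break
            values.append(self.next()[0])
        if not values:
            raise SelectionSyntaxError(position, f"keyword {keyword!r} needs a value")
        return _primitive_mask(self.topology, keyword, values)


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression into a deterministic AtomSelection.

    An empty result is legal (a residue may simply never be matched); a
    syntax error raises :class:`SelectionSyntaxError` with the character
    position of the offending token.
    """
    tokens = [(m.group(0), m.start()) for m in _TOKEN.finditer(expression)]
    parser = _Parser(topology, tokens)
    mask = parser.parse_expr()
    if parser.pos != len(tokens):
        tok, position = tokens[parser.pos]
        raise SelectionSyntaxError(position, f"unexpected token {tok!r}")
    return AtomSelection(topology, np.flatnonzero(mask), expression)
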