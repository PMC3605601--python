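"""Case/control group formation as secret-shared index vectors.

Two scenarios, mirroring how analysts may or may not see clinical data:

1. the analyst holds the phenotypes in the clear, picks member IDs, and the
   resulting 0/1 membership vector is secret-shared before it touches the
   genotype hosts;
2. the phenotypes themselves are secret-shared, and the hosts evaluate the
   analyst's inclusion criterion obliviously — comparisons via secure >=,
   AND as a secure product, OR as ``a + b - a*b``, NOT as ``1 - a``.

The number of secure operations depends only on the criterion shape and the
donor count, never on attribute values, so the evaluation itself leaks
nothing about who matched.

Criterion mini-language (grammar version 1)::

    expr    := or
    or      := and ( '|' and )*
    and     := not ( '&' not )*
    not     := '!' not | atom
    atom    := '(' expr ')' | comparison | attribute
    comparison := attribute op integer
    op      := '>=' | '<=' | '==' | '=' | '>' | '<'

e.g. ``"age >= 50 & has_diabetes"`` or ``"!(bmi < 18) | has_t2d"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import CriterionError, ProtocolError
from .genotypes import SharedPhenotypeDB
from .mpc import Engine, SharedVector

GRAMMAR_VERSION = 1


class IndexVector(SharedVector):
    """A shared zero-one vector; entry i marks donor i's group membership."""


# --------------------------------------------------------------------------
# criterion AST

@dataclass(frozen=True)
class Attr:
    name: str


@dataclass(frozen=True)
class Cmp:
    attr: str
    op: str  # one of > >= < <= ==
    const: int


@dataclass(frozen=True)
class And:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Or:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Not:
    child: "Node"


Node = Union[Attr, Cmp, And, Or, Not]

_TOKEN = re.compile(r"\s*(>=|<=|==|=|[<>()&|!]|[A-Za-z_][A-Za-z0-9_]*|\d+)")


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise CriterionError(f"cannot tokenize criterion at {text[pos:]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_criterion(text: str) -> Node:
    """Parse the criterion mini-language into an expression tree."""
    tokens = _tokenize(text)
    if not tokens:
        raise CriterionError("empty criterion")
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else None

    def advance():
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_or() -> Node:
        node = parse_and()
        while peek() == "|":
            advance()
            node = Or(node, parse_and())
        return node

    def parse_and() -> Node:
        node = parse_not()
        while peek() == "&":
            advance()
            node = And(node, parse_not())
        return node

    def parse_not() -> Node:
        if peek() == "!":
            advance()
            return Not(parse_not())
        return parse_atom()

    def parse_atom() -> Node:
        tok = peek()
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise CriterionError("unbalanced parenthesis in criterion")
            advance()
            return node
        if tok is None or not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", tok):
            raise CriterionError(f"expected attribute, got {tok!r}")
        name = advance()
        if peek() in (">", ">=", "<", "<=", "==", "="):
            op = advance()
            if op == "=":
                op = "=="
            num = peek()
            if num is None or not num.isdigit():
                raise CriterionError(f"comparison {name} {op} needs an integer constant")
            advance()
            return Cmp(name, op, int(num))
        return Attr(name)

    node = parse_or()
    if idx != len(tokens):
        raise CriterionError(f"trailing tokens in criterion: {tokens[idx:]!r}")
    return node


def criterion_attributes(node: Node) -> set[str]:
    if isinstance(node, Attr):
        return {node.name}
    if isinstance(node, Cmp):
        return {node.attr}
    if isinstance(node, Not):
        return criterion_attributes(node.child)
    return criterion_attributes(node.left) | criterion_attributes(node.right)


# --------------------------------------------------------------------------
# scenario 1: analyst-supplied membership

def index_from_plaintext(
    member_ids: Sequence[str], donor_ids: Sequence[str], engine: Engine
) -> IndexVector:
    """Build and secret-share a membership vector from explicit donor IDs."""
    members = set(member_ids)
    unknown = members - set(donor_ids)
    if unknown:
        raise ProtocolError(f"unknown member IDs: {sorted(unknown)}")
    bits = [1 if d in members else 0 for d in donor_ids]
    v = engine.share_vector(bits)
    return IndexVector(v.rows, v.ring)


def complement(v: SharedVector) -> IndexVector:
    """Entrywise 1 - x_i, a local operation (host 0 flips, others negate)."""
    mask = v.ring.mask
    r0, r1, r2 = v.rows
    return IndexVector(
        ([(1 - x) & mask for x in r0], [(-x) & mask for x in r1], [(-x) & mask for x in r2]),
        v.ring,
    )


# --------------------------------------------------------------------------
# scenario 2: oblivious evaluation over shared phenotypes

def _ones(engine: Engine, n: int) -> SharedVector:
    # trivial sharing of the all-ones vector: public, so host 0 carries it
    mask = engine.ring.mask
    return SharedVector(([1 & mask] * n, [0] * n, [0] * n), engine.ring)


def _not_vec(v: SharedVector) -> SharedVector:
    c = complement(v)
    return SharedVector(c.rows, c.ring)


def _cmp_leaf(db: SharedPhenotypeDB, node: Cmp, engine: Engine) -> SharedVector:
    """Per-donor comparison bits against a public constant.

    The constant is shared trivially and compared with secure >=; strict and
    equality forms reduce to the one primitive:
    ``a > c  == !(c >= a)``, ``a < c == !(a >= c)``, ``a == c == (a>=c)&(c>=a)``.
    """
    col = db.columns[node.attr]
    if db.kinds[node.attr] != "int":
        raise CriterionError(f"attribute {node.attr!r} is boolean; comparisons need integers")
    const = engine.share(node.const)
    n = len(col)
    geq_ac = geq_ca = None
    if node.op in (">=", "<", "=="):
        geq_ac = [engine.geq(col[i], const) for i in range(n)]
    if node.op in ("<=", ">", "=="):
        geq_ca = [engine.geq(const, col[i]) for i in range(n)]
    if node.op == ">=":
        out = SharedVector.from_scalars(geq_ac)
    elif node.op == "<=":
        out = SharedVector.from_scalars(geq_ca)
    elif node.op == "<":
        out = _not_vec(SharedVector.from_scalars(geq_ac))
    elif node.op == ">":
        out = _not_vec(SharedVector.from_scalars(geq_ca))
    else:  # ==
        out = engine.mul_vec(
            SharedVector.from_scalars(geq_ac), SharedVector.from_scalars(geq_ca)
        )
    return out


def evaluate_criterion(
    db: SharedPhenotypeDB, criterion: Node | str, engine: Engine
) -> IndexVector:
    """Obliviously evaluate an inclusion criterion over the shared phenotype
    database; returns one shared membership bit per donor."""
    if isinstance(criterion, str):
        criterion = parse_criterion(criterion)
    missing = criterion_attributes(criterion) - set(db.columns)
    if missing:
        raise CriterionError(f"criterion references unknown attributes: {sorted(missing)}")

    def walk(node: Node) -> SharedVector:
        if isinstance(node, Attr):
            if db.kinds[node.name] != "bool":
                raise CriterionError(
                    f"bare attribute {node.name!r} must be boolean; compare integers explicitly"
                )
            return db.columns[node.name]
        if isinstance(node, Cmp):
            return _cmp_leaf(db, node, engine)
        if isinstance(node, Not):
            return _not_vec(walk(node.child))
        left = walk(node.left)
        right = walk(node.right)
        if isinstance(node, And):
            return engine.mul_vec(left, right)
        # OR: a + b - a*b
        prod = engine.mul_vec(left, right)
        mask = engine.ring.mask
        rows = tuple(
            [(a + b - p) & mask for a, b, p in zip(ra, rb, rp)]
            for ra, rb, rp in zip(left.rows, right.rows, prod.rows)
        )
        return SharedVector(rows, engine.ring)  # type: ignore[arg-type]

    out = walk(criterion)
    return IndexVector(out.rows, out.ring)


def evaluate_criterion_plain(data: pd.DataFrame, criterion: Node | str) -> np.ndarray:
    """Plaintext evaluation of the same criterion over a phenotype frame;
    used by the reference pipeline (the secure path must match it bit for bit)."""
    if isinstance(criterion, str):
        criterion = parse_criterion(criterion)

    def walk(node: Node) -> np.ndarray:
        if isinstance(node, Attr):
            return data[node.name].to_numpy().astype(bool)
        if isinstance(node, Cmp):
            col = data[node.attr].to_numpy().astype(int)
            return {
                ">=": col >= node.const,
                "<=": col <= node.const,
                ">": col > node.const,
                "<": col < node.const,
                "==": col == node.const,
            }[node.op]
        if isinstance(node, Not):
            return ~walk(node.child)
        if isinstance(node, And):
            return walk(node.left) & walk(node.right)
        return walk(node.left) | walk(node.right)

    return walk(criterion)
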