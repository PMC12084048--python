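"""Symbolic expression trees over named features.

An :class:`ExpressionTree` is the model representation evolved by the
genetic-programming engine: a tree whose internal nodes are arithmetic
operators and whose leaves are either floating-point constants or references
to named features of a patient record.  The function set is *protected* —
every operator is total on finite inputs, so a tree always evaluates to a
finite raw score regardless of the data it meets during evolution:

* ``a / b``   -> 1 wherever ``b == 0``
* ``log(x)``  -> 0 wherever ``x <= 0``
* ``sqrt(x)`` -> ``sqrt(|x|)``
* ``exp(x)``  -> input clamped to ``[-50, 50]``

Trees serialize both as nested JSON and as infix formula text; the grammar
(precedence ``+ -``  <  ``* /``  <  unary minus / function call) round-trips
through :func:`parse_formula`.
"""

from __future__ import annotations

import json
import re
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "Node",
    "ExpressionTree",
    "evaluate",
    "complexity",
    "depth",
    "used_features",
    "to_formula_text",
    "parse_formula",
    "to_json",
    "from_json",
    "random_tree",
    "sigmoid",
    "DEFAULT_FUNCTIONS",
]

_EXP_CLAMP = 50.0
PROB_EPS = 1e-12

# operator name -> arity
DEFAULT_FUNCTIONS: dict[str, int] = {
    "add": 2,
    "sub": 2,
    "mul": 2,
    "div": 2,
    "neg": 1,
    "log": 1,
    "exp": 1,
    "sqrt": 1,
}

_BINARY_SYMBOL = {"add": "+", "sub": "-", "mul": "*", "div": "/"}
_SYMBOL_BINARY = {v: k for k, v in _BINARY_SYMBOL.items()}


class Node:
    """A single tree node: operator, feature reference, or constant."""

    __slots__ = ("op", "children", "value", "name")

    def __init__(self, op: str, children: tuple["Node", ...] = (),
                 value: float | None = None, name: str | None = None):
        self.op = op
        self.children = children
        self.value = value
        self.name = name
        if op in DEFAULT_FUNCTIONS and len(children) != DEFAULT_FUNCTIONS[op]:
            raise ValueError(f"operator {op!r} expects "
                             f"{DEFAULT_FUNCTIONS[op]} children, got {len(children)}")
        if op == "const" and value is None:
            raise ValueError("constant node requires a value")
        if op == "feat" and not name:
            raise ValueError("feature node requires a name")

    # convenience constructors -------------------------------------------
    @staticmethod
    def const(value: float) -> "Node":
        return Node("const", value=float(value))

    @staticmethod
    def feat(name: str) -> "Node":
        return Node("feat", name=name)

    def copy(self) -> "Node":
        return Node(self.op, tuple(c.copy() for c in self.children),
                    self.value, self.name)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({to_formula_text(self)!r})"


# the spec-level alias: a tree is identified with its root node
ExpressionTree = Node


def iter_nodes(tree: Node) -> Iterator[Node]:
    """Depth-first, pre-order traversal."""
    stack = [tree]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def complexity(tree: Node) -> int:
    """Total node count: operators plus leaves."""
    return sum(1 for _ in iter_nodes(tree))


def depth(tree: Node) -> int:
    """Depth of the tree; a single leaf has depth 1."""
    if not tree.children:
        return 1
    return 1 + max(depth(c) for c in tree.children)


def used_features(tree: Node) -> set[str]:
    """The set of feature names referenced by the tree's leaves."""
    return {n.name for n in iter_nodes(tree) if n.op == "feat"}


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _protected_div(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    zero = y == 0
    safe = np.where(zero, 1.0, y)
    return np.where(zero, 1.0, np.asarray(x, dtype=float) / safe)


def _protected_log(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    bad = x <= 0
    return np.where(bad, 0.0, np.log(np.where(bad, 1.0, x)))


def _clamped_exp(x: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(x, -_EXP_CLAMP, _EXP_CLAMP))


def _protected_sqrt(x: np.ndarray) -> np.ndarray:
    return np.sqrt(np.abs(x))


_EVAL: dict[str, Callable] = {
    "add": lambda a, b: a + b,
    "sub": lambda a, b: a - b,
    "mul": lambda a, b: a * b,
    "div": _protected_div,
    "neg": lambda a: -np.asarray(a, dtype=float),
    "log": _protected_log,
    "exp": _clamped_exp,
    "sqrt": _protected_sqrt,
}


def evaluate(tree: Node, row) -> np.ndarray | float:
    """Evaluate the tree on a feature mapping.

    ``row`` may be a mapping of name -> scalar (a single patient) or of
    name -> array / a pandas DataFrame (vectorized over rows).  Raises
    ``KeyError`` for an unresolved feature reference.
    """
    if tree.op == "const":
        return tree.value
    if tree.op == "feat":
        value = row[tree.name]
        return np.asarray(value, dtype=float) if not np.isscalar(value) else float(value)
    args = [evaluate(c, row) for c in tree.children]
    return _EVAL[tree.op](*args)


def sigmoid(raw: np.ndarray) -> np.ndarray:
    """Logistic link used for classification, clipped into (0, 1)."""
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-np.clip(raw, -_EXP_CLAMP, _EXP_CLAMP)))
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def predict_proba(tree: Node, rows) -> np.ndarray:
    """Probability of the positive class for each row."""
    raw = evaluate(tree, rows)
    return sigmoid(np.atleast_1d(np.asarray(raw, dtype=float)))


# ---------------------------------------------------------------------------
# serialization: JSON
# ---------------------------------------------------------------------------

def to_json(tree: Node) -> str:
    def encode(node: Node):
        if node.op == "const":
            return {"const": node.value}
        if node.op == "feat":
            return {"feature": node.name}
        return {"op": node.op, "children": [encode(c) for c in node.children]}

    return json.dumps(encode(tree))


def from_json(text: str | dict) -> Node:
    def decode(obj) -> Node:
        if "const" in obj:
            return Node.const(obj["const"])
        if "feature" in obj:
            return Node.feat(obj["feature"])
        return Node(obj["op"], tuple(decode(c) for c in obj["children"]))

    return decode(json.loads(text) if isinstance(text, str) else text)


# ---------------------------------------------------------------------------
# serialization: infix formula text
# ---------------------------------------------------------------------------

def to_formula_text(tree: Node) -> str:
    """Render as minimally parenthesized infix text."""

    def render(node: Node, parent_prec: int) -> str:
        if node.op == "const":
            return repr(node.value)
        if node.op == "feat":
            return node.name
        if node.op == "neg":
            inner = render(node.children[0], 3)
            return f"-{inner}"
        if node.op in ("log", "exp", "sqrt"):
            return f"{node.op}({render(node.children[0], 0)})"
        prec = 1 if node.op in ("add", "sub") else 2
        left = render(node.children[0], prec - 1)
        # right side binds tighter so that a - (b - c) keeps parentheses
        right = render(node.children[1], prec)
        text = f"{left} {_BINARY_SYMBOL[node.op]} {right}"
        return f"({text})" if prec <= parent_prec else text

    return render(tree, 0)


class FormulaSyntaxError(ValueError):
    """Malformed formula text; carries the character offset of the error."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at offset {position}")
        self.position = position


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>[-+*/()]))"
)

_FUNCTIONS = {"log", "exp", "sqrt", "neg"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise FormulaSyntaxError(
                f"unexpected character {stripped[0]!r}",
                pos + (len(text[pos:]) - len(stripped)))
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


def parse_formula(text: str, feature_names: Sequence[str] | None = None) -> Node:
    """Parse infix formula text into an :class:`ExpressionTree`.

    When ``feature_names`` is given, identifiers outside the function set
    must belong to it; otherwise any identifier is accepted as a feature.
    """
    tokens = _tokenize(text)
    idx = 0

    def peek():
        return tokens[idx]

    def advance():
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def expect_op(symbol: str):
        kind, value, pos = peek()
        if kind != "op" or value != symbol:
            raise FormulaSyntaxError(f"expected {symbol!r}", pos)
        advance()

    def parse_expr() -> Node:
        node = parse_term()
        while True:
            kind, value, _ = peek()
            if kind == "op" and value in "+-":
                advance()
                rhs = parse_term()
                node = Node(_SYMBOL_BINARY[value], (node, rhs))
            else:
                return node

    def parse_term() -> Node:
        node = parse_factor()
        while True:
            kind, value, _ = peek()
            if kind == "op" and value in "*/":
                advance()
                rhs = parse_factor()
                node = Node(_SYMBOL_BINARY[value], (node, rhs))
            else:
                return node

    def parse_factor() -> Node:
        kind, value, pos = peek()
        if kind == "op" and value == "-":
            advance()
            return Node("neg", (parse_factor(),))
        return parse_primary()

    def parse_primary() -> Node:
        kind, value, pos = advance()
        if kind == "num":
            return Node.const(float(value))
        if kind == "name":
            if value in _FUNCTIONS:
                expect_op("(")
                inner = parse_expr()
                expect_op(")")
                if value == "neg":
                    return Node("neg", (inner,))
                return Node(value, (inner,))
            if feature_names is not None and value not in feature_names:
                raise FormulaSyntaxError(f"unknown symbol {value!r}", pos)
            return Node.feat(value)
        if kind == "op" and value == "(":
            inner = parse_expr()
            expect_op(")")
            return inner
        raise FormulaSyntaxError("expected operand", pos)

    node = parse_expr()
    kind, value, pos = peek()
    if kind != "end":
        raise FormulaSyntaxError(f"unexpected token {value!r}", pos)
    return node


# ---------------------------------------------------------------------------
# random tree construction (used by the engine's initialization and mutation)
# ---------------------------------------------------------------------------

def random_tree(rng: np.random.Generator, feature_names: Sequence[str],
                max_depth: int, method: str = "grow",
                functions: Sequence[str] | None = None,
                const_range: tuple[float, float] = (-2.0, 2.0)) -> Node:
    """Build a random tree by the ``grow`` or ``full`` method.

    Constants are ephemeral, drawn uniformly from ``const_range``; leaves are
    features with probability 0.8 and constants otherwise.
    """
    ops = list(functions) if functions is not None else list(DEFAULT_FUNCTIONS)

    def leaf() -> Node:
        if len(feature_names) and rng.random() < 0.8:
            return Node.feat(feature_names[rng.integers(len(feature_names))])
        lo, hi = const_range
        return Node.const(float(rng.uniform(lo, hi)))

    def build(level: int) -> Node:
        if level >= max_depth:
            return leaf()
        if method == "grow" and level > 1 and rng.random() < 0.3:
            return leaf()
        op = ops[rng.integers(len(ops))]
        arity = DEFAULT_FUNCTIONS[op]
        return Node(op, tuple(build(level + 1) for _ in range(arity)))

    return build(1)
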