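"""Integer expression trees for explicit qualitative-network target functions.

The default QN target function (rounded average difference between activator
and inhibitor levels) covers ordinary regulatory links, but some behaviours
need explicit algebra -- in particular latches ("become, and remain, active"),
which are written as ``max(SELF, trigger)`` gated by a reset term.  The
grammar is deliberately tiny and closed under integers:

    expr   := term (('+' | '-') term)*
    term   := factor ('*' factor)*
    factor := INT | NAME | '-' factor | '(' expr ')'
            | 'min' '(' expr (',' expr)+ ')' | 'max' '(' expr (',' expr)+ ')'

Expressions evaluate against a mapping from variable name to value, where a
value may be a Python int or a numpy array (all operations are elementwise),
so the same tree serves scalar simulation and vectorised state-space sweeps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Union

import numpy as np

Value = Union[int, np.ndarray]

__all__ = [
    "Expr", "Const", "Var", "Add", "Sub", "Mul", "MinOf", "MaxOf",
    "parse_expr", "ExprError",
]


class ExprError(ValueError):
    """Raised for syntax errors or references to unknown variables."""


class Expr:
    """Base class for expression nodes.  Nodes are immutable and hashable."""

    def eval(self, env: Mapping[str, Value]) -> Value:  # pragma: no cover - abstract
        raise NotImplementedError

    def names(self) -> frozenset:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Const(Expr):
    value: int

    def eval(self, env):
        return self.value

    def names(self):
        return frozenset()

    def __str__(self):
        return str(self.value)


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def eval(self, env):
        try:
            return env[self.name]
        except KeyError:
            raise ExprError(f"unknown variable {self.name!r}") from None

    def names(self):
        return frozenset({self.name})

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class _Bin(Expr):
    left: Expr
    right: Expr

    _op = None
    _sym = "?"

    def eval(self, env):
        return type(self)._apply(self.left.eval(env), self.right.eval(env))

    def names(self):
        return self.left.names() | self.right.names()

    def __str__(self):
        return f"({self.left} {self._sym} {self.right})"


class Add(_Bin):
    _sym = "+"

    @staticmethod
    def _apply(a, b):
        return a + b


class Sub(_Bin):
    _sym = "-"

    @staticmethod
    def _apply(a, b):
        return a - b


class Mul(_Bin):
    _sym = "*"

    @staticmethod
    def _apply(a, b):
        return a * b


@dataclass(frozen=True)
class _NAry(Expr):
    args: tuple

    _fn = None
    _name = "?"

    def eval(self, env):
        vals = [a.eval(env) for a in self.args]
        out = vals[0]
        for v in vals[1:]:
            out = type(self)._apply(out, v)
        return out

    def names(self):
        out = frozenset()
        for a in self.args:
            out |= a.names()
        return out

    def __str__(self):
        return f"{self._name}({', '.join(str(a) for a in self.args)})"


class MinOf(_NAry):
    _name = "min"

    @staticmethod
    def _apply(a, b):
        return np.minimum(a, b)


class MaxOf(_NAry):
    _name = "max"

    @staticmethod
    def _apply(a, b):
        return np.maximum(a, b)


_TOKEN = re.compile(r"\s*(?:(?P<int>\d+)|(?P<name>[A-Za-z_]\w*)|(?P<op>[-+*(),]))")


def _tokenize(text: str) -> Iterator[tuple]:
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise ExprError(f"bad character at {text[pos:]!r}")
        pos = m.end()
        if m.lastgroup == "int":
            yield ("int", int(m.group("int")))
        elif m.lastgroup == "name":
            yield ("name", m.group("name"))
        else:
            yield ("op", m.group("op"))
    yield ("end", None)


class _Parser:
    def __init__(self, text: str):
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind, value=None):
        tok = self.next()
        if tok[0] != kind or (value is not None and tok[1] != value):
            raise ExprError(f"expected {value or kind}, got {tok[1]!r}")
        return tok

    def expr(self) -> Expr:
        node = self.term()
        while self.peek() == ("op", "+") or self.peek() == ("op", "-"):
            op = self.next()[1]
            rhs = self.term()
            node = Add(node, rhs) if op == "+" else Sub(node, rhs)
        return node

    def term(self) -> Expr:
        node = self.factor()
        while self.peek() == ("op", "*"):
            self.next()
            node = Mul(node, self.factor())
        return node

    def factor(self) -> Expr:
        kind, value = self.next()
        if kind == "int":
            return Const(value)
        if kind == "op" and value == "-":
            return Sub(Const(0), self.factor())
        if kind == "op" and value == "(":
            node = self.expr()
            self.expect("op", ")")
            return node
        if kind == "name" and value in ("min", "max") and self.peek() == ("op", "("):
            self.next()
            args = [self.expr()]
            while self.peek() == ("op", ","):
                self.next()
                args.append(self.expr())
            self.expect("op", ")")
            cls = MinOf if value == "min" else MaxOf
            return cls(tuple(args))
        if kind == "name":
            return Var(value)
        raise ExprError(f"unexpected token {value!r}")


def parse_expr(text: str) -> Expr:
    """Parse ``text`` into an expression tree.

    Round-trips with ``str(expr)``: ``parse_expr(str(e))`` is structurally
    equal to ``e`` up to redundant parentheses.
    """
    p = _Parser(text)
    node = p.expr()
    p.expect("end")
    return node
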