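"""Safe arithmetic expressions for generic rate laws and variable densities.

ChannelML allows rate laws and non-uniform channel densities to be written
as small arithmetic expressions (in the membrane potential ``v``, ligand
concentration ``ca``, temperature ``celsius``, or a spatial metric ``d``).
These are parsed with a tiny recursive-descent grammar -- never with
host-language evaluation -- supporting::

    expr    := term (('+' | '-') term)*
    term    := factor (('*' | '/') factor)*
    factor  := ('-' | '+') factor | power
    power   := atom ('^' factor)?
    atom    := NUMBER | NAME | NAME '(' expr (',' expr)* ')' | '(' expr ')'

Allowed functions: ``exp``, ``pow``, ``sqrt``, ``log``.  Evaluation is
numpy-aware, so vectorized voltage grids work transparently.
"""

from __future__ import annotations

import re
from typing import Callable, Sequence

import numpy as np

__all__ = ["ExpressionError", "Expression", "compile_expression"]

_TOKEN = re.compile(r"\s*(?:(\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?"
                    r"|\d+(?:[eE][+-]?\d+)?)|([A-Za-z_][A-Za-z_0-9]*)"
                    r"|(\*\*|[-+*/^(),]))")

_FUNCTIONS: dict[str, Callable] = {
    "exp": np.exp,
    "sqrt": np.sqrt,
    "log": np.log,
    "pow": np.power,
}
_FUNC_ARITY = {"exp": 1, "sqrt": 1, "log": 1, "pow": 2}


class ExpressionError(ValueError):
    """Raised for syntax errors or disallowed names in an expression."""


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ExpressionError(
                    f"unexpected character {text[pos]!r} at position {pos}")
            break
        if m.group(1) is not None:
            tokens.append(("num", m.group(1)))
        elif m.group(2) is not None:
            tokens.append(("name", m.group(2)))
        else:
            op = m.group(3)
            tokens.append(("op", "^" if op == "**" else op))
        pos = m.end()
    tokens.append(("end", ""))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], variables: Sequence[str]):
        self.tokens = tokens
        self.pos = 0
        self.variables = tuple(variables)

    def peek(self) -> tuple[str, str]:
        return self.tokens[self.pos]

    def advance(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val = self.advance()
        if val != value:
            raise ExpressionError(f"expected {value!r}, found {val or kind!r}")

    def parse(self) -> Callable:
        node = self.expr()
        kind, val = self.peek()
        if kind != "end":
            raise ExpressionError(f"trailing input at token {val!r}")
        return node

    def expr(self) -> Callable:
        node = self.term()
        while self.peek() == ("op", "+") or self.peek() == ("op", "-"):
            _, op = self.advance()
            rhs = self.term()
            node = self._binary(op, node, rhs)
        return node

    def term(self) -> Callable:
        node = self.factor()
        while self.peek() == ("op", "*") or self.peek() == ("op", "/"):
            _, op = self.advance()
            rhs = self.factor()
            node = self._binary(op, node, rhs)
        return node

    def factor(self) -> Callable:
        if self.peek() == ("op", "-"):
            self.advance()
            inner = self.factor()
            return lambda env: -inner(env)
        if self.peek() == ("op", "+"):
            self.advance()
            return self.factor()
        return self.power()

    def power(self) -> Callable:
        base = self.atom()
        if self.peek() == ("op", "^"):
            self.advance()
            exponent = self.factor()   # right-associative
            return lambda env: np.power(base(env), exponent(env))
        return base

    def atom(self) -> Callable:
        kind, val = self.advance()
        if kind == "num":
            const = float(val)
            return lambda env: const
        if kind == "name":
            if self.peek() == ("op", "("):
                if val not in _FUNCTIONS:
                    raise ExpressionError(f"unknown function {val!r}")
                self.advance()
                args = [self.expr()]
                while self.peek() == ("op", ","):
                    self.advance()
                    args.append(self.expr())
                self.expect(")")
                if len(args) != _FUNC_ARITY[val]:
                    raise ExpressionError(
                        f"{val} takes {_FUNC_ARITY[val]} argument(s)")
                fn = _FUNCTIONS[val]
                return lambda env: fn(*(a(env) for a in args))
            if val not in self.variables:
                raise ExpressionError(
                    f"unknown variable {val!r} (allowed: {self.variables})")
            name = val
            return lambda env: env[name]
        if (kind, val) == ("op", "("):
            inner = self.expr()
            self.expect(")")
            return inner
        raise ExpressionError(f"unexpected token {val or kind!r}")

    @staticmethod
    def _binary(op: str, lhs: Callable, rhs: Callable) -> Callable:
        if op == "+":
            return lambda env: lhs(env) + rhs(env)
        if op == "-":
            return lambda env: lhs(env) - rhs(env)
        if op == "*":
            return lambda env: lhs(env) * rhs(env)
        return lambda env: lhs(env) / rhs(env)


class Expression:
    """A compiled arithmetic expression over a fixed set of variable names."""

    def __init__(self, text: str, variables: Sequence[str] = ("v", "ca", "celsius")):
        self.text = text
        self.variables = tuple(variables)
        self._fn = _Parser(_tokenize(text), self.variables).parse()

    def __call__(self, **env: float | np.ndarray):
        for name in env:
            if name not in self.variables:
                raise ExpressionError(f"unknown variable {name!r}")
        return self._fn(env)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Expression({self.text!r})"


def compile_expression(text: str,
                       variables: Sequence[str] = ("v", "ca", "celsius"),
                       ) -> Expression:
    return Expression(text, variables)
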