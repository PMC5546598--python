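"""Arithmetic expression engine for rate laws and parameter formulas.

The netlist carries three kinds of formulas: parameter definitions
(arithmetic over previously declared parameter names), custom reaction
rates (type ``X``, referencing species as ``[Name]`` and parameters as
bare identifiers), and species attribute values.  All of them share one
small grammar::

    expr   := term (("+" | "-") term)*
    term   := unary (("*" | "/") unary)*
    unary  := "-" unary | power
    power  := atom ("^" unary)?          # right-associative
    atom   := NUMBER | IDENT | IDENT "(" expr ("," expr)* ")"
            | "[" IDENT "]" | "(" expr ")"

Supported functions: ``exp``, ``ln``, ``log10``, ``pow``, ``min``,
``max``, ``sqrt``.  Numeric literals accept scientific notation and the
SPICE engineering suffixes (``T G meg k m u n p f``).

Expressions are parsed once into a small tuple-based AST and evaluated
against a :class:`dict` environment; the AST is also what the SBML and
NGSPICE writers serialise.
"""

from __future__ import annotations

import math
import re
from typing import Iterable

__all__ = [
    "ExprError",
    "parse_expr",
    "eval_expr",
    "free_symbols",
    "free_species",
    "substitute",
    "parse_number",
    "format_number",
]


class ExprError(ValueError):
    """Raised for tokenisation, parse or evaluation failures.

    Carries the character position of the offending token when known.
    """

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


# SPICE engineering suffixes, case-insensitive; "meg" must be checked
# before "m" (mega vs milli).
_SUFFIXES = {
    "t": 1e12,
    "g": 1e9,
    "meg": 1e6,
    "k": 1e3,
    "m": 1e-3,
    "u": 1e-6,
    "n": 1e-9,
    "p": 1e-12,
    "f": 1e-15,
}

_NUMBER_RE = re.compile(
    r"(?P<mant>\d+\.?\d*|\.\d+)(?P<exp>[eE][+-]?\d+)?(?P<suffix>[a-zA-Z]+)?"
)


def parse_number(text: str) -> float:
    """Parse a numeric literal with optional SPICE suffix (``2k`` -> 2000)."""
    m = _NUMBER_RE.fullmatch(text.strip())
    if m is None:
        raise ExprError(f"not a numeric literal: {text!r}")
    value = float(m.group("mant") + (m.group("exp") or ""))
    suffix = m.group("suffix")
    if suffix:
        key = "meg" if suffix.lower().startswith("meg") else suffix[0].lower()
        if key not in _SUFFIXES:
            raise ExprError(f"unknown engineering suffix {suffix!r} in {text!r}")
        value *= _SUFFIXES[key]
    return value


def format_number(x: float) -> str:
    """Shortest round-tripping decimal form (no suffixes on output)."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?[a-zA-Z]*)"
    r"|(?P<species>\[[A-Za-z_][A-Za-z0-9_]*\])"
    r"|(?P<ident>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>[-+*/^(),])"
    r")"
)

_FUNCTIONS = {
    "exp": (1, math.exp),
    "ln": (1, math.log),
    "log10": (1, math.log10),
    "sqrt": (1, math.sqrt),
    "pow": (2, pow),
    "min": (2, min),
    "max": (2, max),
}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise ExprError(f"unexpected character {text[pos]!r}", pos)
        for kind in ("num", "species", "ident", "op"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val, m.start(kind)))
                break
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect_op(self, op: str):
        kind, val, pos = self.next()
        if kind != "op" or val != op:
            raise ExprError(f"expected {op!r}, found {val!r}", pos)

    def parse(self):
        node = self.expr()
        kind, val, pos = self.peek()
        if kind is not None:
            raise ExprError(f"trailing input {val!r}", pos)
        return node

    def expr(self):
        node = self.term()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in "+-":
                self.next()
                node = ("bin", val, node, self.term())
            else:
                return node

    def term(self):
        node = self.unary()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in "*/":
                self.next()
                node = ("bin", val, node, self.unary())
            else:
                return node

    def unary(self):
        kind, val, _ = self.peek()
        if kind == "op" and val == "-":
            self.next()
            return ("neg", self.unary())
        if kind == "op" and val == "+":
            self.next()
            return self.unary()
        return self.power()

    def power(self):
        base = self.atom()
        kind, val, _ = self.peek()
        if kind == "op" and val == "^":
            self.next()
            return ("bin", "^", base, self.unary())
        return base

    def atom(self):
        kind, val, pos = self.next()
        if kind == "num":
            return ("num", parse_number(val))
        if kind == "species":
            return ("species", val[1:-1])
        if kind == "ident":
            nxt_kind, nxt_val, _ = self.peek()
            if nxt_kind == "op" and nxt_val == "(":
                if val not in _FUNCTIONS:
                    raise ExprError(f"unknown function {val!r}", pos)
                self.next()
                args = [self.expr()]
                while True:
                    k, v, p = self.next()
                    if k == "op" and v == ")":
                        break
                    if k == "op" and v == ",":
                        args.append(self.expr())
                    else:
                        raise ExprError(f"expected ',' or ')', found {v!r}", p)
                arity = _FUNCTIONS[val][0]
                if len(args) != arity:
                    raise ExprError(
                        f"function {val} takes {arity} argument(s), got {len(args)}", pos
                    )
                return ("call", val, tuple(args))
            return ("param", val)
        if kind == "op" and val == "(":
            node = self.expr()
            self.expect_op(")")
            return node
        raise ExprError(f"unexpected token {val!r}", pos)


def parse_expr(text: str):
    """Parse ``text`` into an AST (nested tuples)."""
    if not isinstance(text, str) or not text.strip():
        raise ExprError("empty expression")
    return _Parser(text).parse()


def eval_expr(node, env: dict[str, float], species: dict[str, float] | None = None) -> float:
    """Evaluate an AST against parameter environment ``env`` and, when the
    expression references bracketed species, the ``species`` concentration map.
    """
    op = node[0]
    if op == "num":
        return node[1]
    if op == "param":
        try:
            return float(env[node[1]])
        except KeyError:
            raise ExprError(f"undefined symbol {node[1]!r}") from None
    if op == "species":
        if species is None or node[1] not in species:
            raise ExprError(f"undefined species [{node[1]}]")
        return float(species[node[1]])
    if op == "neg":
        return -eval_expr(node[1], env, species)
    if op == "bin":
        a = eval_expr(node[2], env, species)
        b = eval_expr(node[3], env, species)
        o = node[1]
        if o == "+":
            return a + b
        if o == "-":
            return a - b
        if o == "*":
            return a * b
        if o == "/":
            if b == 0.0:
                raise ExprError("division by zero")
            return a / b
        if o == "^":
            try:
                result = float(a) ** float(b)
            except (OverflowError, ValueError) as exc:
                raise ExprError(f"power evaluation failed: {exc}") from None
            if isinstance(result, complex):  # negative base, fractional power
                raise ExprError(f"power of negative base {a} is not real")
            return result
    if op == "call":
        fn = _FUNCTIONS[node[1]][1]
        args = [eval_expr(a, env, species) for a in node[2]]
        try:
            return float(fn(*args))
        except ValueError as exc:
            raise ExprError(f"{node[1]} evaluation failed: {exc}") from None
    raise ExprError(f"malformed AST node {node!r}")


def free_symbols(node) -> set[str]:
    """Bare identifiers (parameter names) referenced by the expression."""
    out: set[str] = set()
    _walk(node, out, "param")
    return out


def free_species(node) -> set[str]:
    """Bracketed species names referenced by the expression."""
    out: set[str] = set()
    _walk(node, out, "species")
    return out


def _walk(node, out: set[str], kind: str) -> None:
    op = node[0]
    if op == kind:
        out.add(node[1])
    elif op == "neg":
        _walk(node[1], out, kind)
    elif op == "bin":
        _walk(node[2], out, kind)
        _walk(node[3], out, kind)
    elif op == "call":
        for a in node[2]:
            _walk(a, out, kind)


def substitute(node, params: dict | None = None, species: dict | None = None):
    """Replace symbols by numbers or other ASTs; used for inlining SBML
    function definitions and reaction-local parameter values."""
    op = node[0]
    if op == "param" and params and node[1] in params:
        repl = params[node[1]]
        return ("num", float(repl)) if isinstance(repl, (int, float)) else repl
    if op == "species" and species and node[1] in species:
        repl = species[node[1]]
        return ("num", float(repl)) if isinstance(repl, (int, float)) else repl
    if op == "neg":
        return ("neg", substitute(node[1], params, species))
    if op == "bin":
        return ("bin", node[1], substitute(node[2], params, species), substitute(node[3], params, species))
    if op == "call":
        return ("call", node[1], tuple(substitute(a, params, species) for a in node[2]))
    return node


def to_text(node) -> str:
    """Serialise an AST back to netlist expression syntax."""
    op = node[0]
    if op == "num":
        return format_number(node[1])
    if op == "param":
        return node[1]
    if op == "species":
        return f"[{node[1]}]"
    if op == "neg":
        return f"(-{to_text(node[1])})"
    if op == "bin":
        return f"({to_text(node[2])}{node[1]}{to_text(node[3])})"
    if op == "call":
        return f"{node[1]}({','.join(to_text(a) for a in node[2])})"
    raise ExprError(f"malformed AST node {node!r}")
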