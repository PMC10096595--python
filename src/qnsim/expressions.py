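"""Target-function expression language.

Each node of a qualitative network chases a *target function*: an arithmetic
expression over the (range-scaled) levels of its regulators.  The grammar is
deliberately small so that interval evaluation (used by the stability engine)
stays sound:

    expr    := term (('+' | '-') term)*
    term    := factor (('*' | '/') factor)*
    factor  := INT | 'var' '(' NAME ')' | FUNC '(' expr (',' expr)* ')'
             | '(' expr ')' | '-' factor
    FUNC    := 'avg' | 'min' | 'max' | 'ceil' | 'floor'

``ceil`` and ``floor`` are unary; ``avg``/``min``/``max`` are n-ary.  Division
denominators must fold to a non-zero constant.  All evaluation is exact
rational arithmetic (:class:`fractions.Fraction`); floats never appear, so
fixed points are decided by exact comparison.

The tokens ``pos`` and ``neg`` (the activator and inhibitor sets of the node
being parsed) are expanded at parse time by the caller supplying concrete
sub-expressions; see :func:`qnsim.network.parse_target_expression`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Mapping, Sequence

__all__ = [
    "Expr",
    "Const",
    "Var",
    "BinOp",
    "Call",
    "ExpressionError",
    "ParseError",
    "UnresolvedReference",
    "parse_expression",
    "Interval",
]

Interval = tuple[Fraction, Fraction]


class ExpressionError(ValueError):
    """Base class for target-function errors."""


class ParseError(ExpressionError):
    """Syntax error; carries the character position where parsing failed."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnresolvedReference(ExpressionError):
    """A var(...) reference does not name a regulator of the node."""


@dataclass(frozen=True)
class Expr:
    def evaluate(self, env: Mapping[str, Fraction]) -> Fraction:
        raise NotImplementedError

    def interval(self, env: Mapping[str, Interval]) -> Interval:
        """Sound over-approximation of the expression's value range when each
        variable ranges over its interval in ``env``."""
        raise NotImplementedError

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def unparse(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.unparse()


@dataclass(frozen=True)
class Const(Expr):
    value: Fraction

    def __post_init__(self):
        object.__setattr__(self, "value", Fraction(self.value))

    def evaluate(self, env):
        return self.value

    def interval(self, env):
        return (self.value, self.value)

    def variables(self):
        return frozenset()

    def unparse(self):
        v = self.value
        if v.denominator == 1:
            return str(v.numerator) if v >= 0 else f"({v.numerator})"
        return f"({v.numerator}/{v.denominator})"


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, env):
        try:
            return env[self.name]
        except KeyError:
            raise UnresolvedReference(f"no level bound for var({self.name})") from None

    def interval(self, env):
        try:
            return env[self.name]
        except KeyError:
            raise UnresolvedReference(f"no interval bound for var({self.name})") from None

    def variables(self):
        return frozenset({self.name})

    def unparse(self):
        return f"var({self.name})"


_BINOPS = {"+", "-", "*", "/"}


@dataclass(frozen=True)
class BinOp(Expr):
    op: str
    left: Expr
    right: Expr

    def __post_init__(self):
        if self.op not in _BINOPS:
            raise ExpressionError(f"unknown operator {self.op!r}")

    def evaluate(self, env):
        a = self.left.evaluate(env)
        b = self.right.evaluate(env)
        if self.op == "+":
            return a + b
        if self.op == "-":
            return a - b
        if self.op == "*":
            return a * b
        if b == 0:
            raise ExpressionError("division by zero")
        return a / b

    def interval(self, env):
        lo1, hi1 = self.left.interval(env)
        lo2, hi2 = self.right.interval(env)
        if self.op == "+":
            return (lo1 + lo2, hi1 + hi2)
        if self.op == "-":
            return (lo1 - hi2, hi1 - lo2)
        if self.op == "*":
            corners = (lo1 * lo2, lo1 * hi2, hi1 * lo2, hi1 * hi2)
            return (min(corners), max(corners))
        # division: denominator is a constant (enforced at parse/validate time)
        if lo2 != hi2:
            raise ExpressionError("interval division requires a constant denominator")
        c = lo2
        if c == 0:
            raise ExpressionError("division by zero")
        if c > 0:
            return (lo1 / c, hi1 / c)
        return (hi1 / c, lo1 / c)

    def variables(self):
        return self.left.variables() | self.right.variables()

    def unparse(self):
        return f"({self.left.unparse()} {self.op} {self.right.unparse()})"


_NARY = ("avg", "min", "max")
_UNARY = ("ceil", "floor")


@dataclass(frozen=True)
class Call(Expr):
    func: str
    args: tuple[Expr, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "args", tuple(self.args))
        if self.func not in _NARY + _UNARY:
            raise ExpressionError(f"unknown function {self.func!r}")
        if not self.args:
            raise ExpressionError(f"{self.func}() needs at least one argument")
        if self.func in _UNARY and len(self.args) != 1:
            raise ExpressionError(f"{self.func}() takes exactly one argument")

    def evaluate(self, env):
        vals = [a.evaluate(env) for a in self.args]
        if self.func == "avg":
            return sum(vals, Fraction(0)) / len(vals)
        if self.func == "min":
            return min(vals)
        if self.func == "max":
            return max(vals)
        if self.func == "ceil":
            return Fraction(math.ceil(vals[0]))
        return Fraction(math.floor(vals[0]))

    def interval(self, env):
        ivs = [a.interval(env) for a in self.args]
        los = [iv[0] for iv in ivs]
        his = [iv[1] for iv in ivs]
        if self.func == "avg":
            n = len(ivs)
            return (sum(los, Fraction(0)) / n, sum(his, Fraction(0)) / n)
        if self.func == "min":
            return (min(los), min(his))
        if self.func == "max":
            return (max(los), max(his))
        if self.func == "ceil":
            return (Fraction(math.ceil(los[0])), Fraction(math.ceil(his[0])))
        return (Fraction(math.floor(los[0])), Fraction(math.floor(his[0])))

    def variables(self):
        out: frozenset[str] = frozenset()
        for a in self.args:
            out |= a.variables()
        return out

    def unparse(self):
        return f"{self.func}({', '.join(a.unparse() for a in self.args)})"


def constant_fold(expr: Expr) -> Fraction | None:
    """Return the expression's value if it contains no variables, else None."""
    if not expr.variables():
        return expr.evaluate({})
    return None


# ---------------------------------------------------------------------------
# Parser (recursive descent)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<INT>\d+)
  | (?P<NAME>[A-Za-z_][A-Za-z0-9_\-\.]*)
  | (?P<OP>[+\-*/(),])
  | (?P<WS>\s+)
""",
    re.VERBOSE,
)


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind != "WS":
            yield (kind, m.group(), pos)
        pos = m.end()
    yield ("EOF", "", len(text))


class _Parser:
    """Recursive-descent parser.

    ``pos_args``/``neg_args`` are the activator/inhibitor var lists of the node
    whose function is being parsed; the bare tokens ``pos`` and ``neg`` splice
    them into n-ary calls, so ``avg(pos)`` on a node with activators A, B
    parses to ``avg(var(A), var(B))``.  When a splice leaves a call with no
    arguments, the call collapses to the supplied empty-set convention value
    (``empty_pos``/``empty_neg``).
    """

    def __init__(
        self,
        text: str,
        pos_args: tuple[Expr, ...] | None,
        neg_args: tuple[Expr, ...] | None,
        empty_pos: Expr | None,
        empty_neg: Expr | None,
    ):
        self.tokens = list(_tokenize(text))
        self.i = 0
        self.pos_args = pos_args
        self.neg_args = neg_args
        self.empty_pos = empty_pos
        self.empty_neg = empty_neg

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, val, p = self.next()
        if val != value:
            raise ParseError(f"expected {value!r}, found {val or 'end of input'!r}", p)

    def parse(self) -> Expr:
        e = self.expr()
        kind, val, p = self.peek()
        if kind != "EOF":
            raise ParseError(f"trailing input {val!r}", p)
        return e

    def expr(self) -> Expr:
        e = self.term()
        while self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            e = BinOp(op, e, self.term())
        return e

    def term(self) -> Expr:
        e = self.factor()
        while self.peek()[1] in ("*", "/"):
            _, op, p = self.next()
            rhs = self.factor()
            if op == "/":
                c = constant_fold(rhs)
                if c is None:
                    raise ParseError("division denominator must be a constant", p)
                if c == 0:
                    raise ParseError("division by zero", p)
            e = BinOp(op, e, rhs)
        return e

    def factor(self) -> Expr:
        kind, val, p = self.next()
        if kind == "INT":
            return Const(Fraction(int(val)))
        if val == "-":
            f = self.factor()
            if isinstance(f, Const):
                return Const(-f.value)
            return BinOp("-", Const(Fraction(0)), f)
        if val == "(":
            e = self.expr()
            self.expect(")")
            return e
        if kind == "NAME":
            if val == "var":
                self.expect("(")
                k2, name, p2 = self.next()
                if k2 not in ("NAME", "INT"):
                    raise ParseError("var(...) needs a node name", p2)
                self.expect(")")
                return Var(name)
            if val in _NARY + _UNARY:
                self.expect("(")
                args: list[Expr] = []
                spliced: set[str] = set()
                self._call_arg(args, spliced, p)
                while self.peek()[1] == ",":
                    self.next()
                    self._call_arg(args, spliced, p)
                self.expect(")")
                if not args:
                    # all arguments were empty pos/neg splices: apply the
                    # empty-regulator-set convention
                    if spliced == {"pos"}:
                        return self.empty_pos  # type: ignore[return-value]
                    if spliced == {"neg"}:
                        return self.empty_neg  # type: ignore[return-value]
                    raise ParseError(f"{val}() over empty regulator sets", p)
                return Call(val, tuple(args))
            if val in ("pos", "neg"):
                raise ParseError(
                    f"{val!r} may only appear as an argument of avg/min/max", p
                )
            raise ParseError(f"unknown identifier {val!r}", p)
        raise ParseError(f"unexpected {val or 'end of input'!r}", p)

    def _call_arg(self, args: list[Expr], spliced: set[str], p: int) -> None:
        """Parse one call argument, splicing bare pos/neg token lists."""
        kind, val, q = self.peek()
        if kind == "NAME" and val in ("pos", "neg"):
            # only a *bare* pos/neg splices; `pos + 1` etc. is rejected below
            nxt = self.tokens[self.i + 1][1]
            if nxt in (",", ")"):
                self.next()
                expansion = self.pos_args if val == "pos" else self.neg_args
                if expansion is None:
                    raise ParseError(f"{val!r} used outside a node context", q)
                args.extend(expansion)
                spliced.add(val)
                return
        args.append(self.expr())


def parse_expression(
    text: str,
    pos_args: tuple[Expr, ...] | None = None,
    neg_args: tuple[Expr, ...] | None = None,
    empty_pos: Expr | None = None,
    empty_neg: Expr | None = None,
) -> Expr:
    """Parse ``text`` into an AST.

    ``pos_args``/``neg_args`` are spliced for the bare tokens ``pos`` and
    ``neg`` inside n-ary calls; ``empty_pos``/``empty_neg`` replace a call
    whose spliced argument list comes out empty.  Leave all four as None when
    parsing context-free text (then ``pos``/``neg`` are syntax errors).
    """
    if pos_args is not None and not pos_args and empty_pos is None:
        raise ExpressionError("empty pos requires an empty_pos convention value")
    if neg_args is not None and not neg_args and empty_neg is None:
        raise ExpressionError("empty neg requires an empty_neg convention value")
    return _Parser(text, pos_args, neg_args, empty_pos, empty_neg).parse()


def check_references(expr: Expr, allowed: Sequence[str], owner: str = "") -> None:
    """Raise UnresolvedReference if the expression names a variable outside
    ``allowed`` (the in-edge sources of the node owning the expression)."""
    extra = expr.variables() - set(allowed)
    if extra:
        where = f" of node {owner!r}" if owner else ""
        raise UnresolvedReference(
            f"var reference(s) {sorted(extra)} are not regulators{where}"
        )
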