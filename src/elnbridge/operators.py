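"""Transfer operators: the value transformations applied during transfer.

A transfer operator adapts one field value to the conventions of the target
platform — re-pattern a date-time, translate a choice label, cast a type,
scale a number, wrap or split a string.  Operators are small, serializable
expression trees over exactly one input value; they are pure (no access to
the payload beyond the given value, no external state) and deliberately
non-Turing-complete: there are no loops, because list iteration is handled
structurally by array mappings.

The textual DSL embedded in configuration files uses function-call syntax::

    id
    cast("int")
    datefmt("%Y-%m-%d %H:%M", "%d.%m.%Y %H:%M")
    remap({"done": "Successful", "failed": "Not Successful"})
    add(2.5)   sub(1)   mul(10)   div(2)
    concat("PAN$", ";")          # prefix, suffix
    split(";", 0)                # separator, element index
    ifeq("done", remap({"done": "ok"}), id)
    pipe(remap({"a": "1"}), cast("int"))

``parse_operator`` and ``serialize_operator`` are exact inverses on the
expression tree.  Evaluation failures (a date that does not match the source
pattern, a cast that cannot succeed, a choice with no remap entry) raise
:class:`OperatorDomainError` so the engine can skip that mapping and log it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Any, Union

__all__ = [
    "OperatorExpr",
    "Identity",
    "Cast",
    "DateFormat",
    "Remap",
    "Arith",
    "Concat",
    "Split",
    "IfEq",
    "Pipe",
    "OperatorDomainError",
    "OperatorSyntaxError",
    "evaluate_operator",
    "parse_operator",
    "serialize_operator",
]


class OperatorDomainError(ValueError):
    """The input value lies outside the operator's declared domain."""


class OperatorSyntaxError(ValueError):
    """DSL text could not be parsed; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# --------------------------------------------------------------------------
# expression tree


@dataclass(frozen=True)
class Identity:
    """Copy the value unchanged, type included."""

    def evaluate(self, value: Any) -> Any:
        return value


_CAST_KINDS = ("int", "float", "str")


@dataclass(frozen=True)
class Cast:
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _CAST_KINDS:
            raise ValueError(f"unknown cast kind {self.kind!r}; expected one of {_CAST_KINDS}")

    def evaluate(self, value: Any) -> Any:
        try:
            if self.kind == "int":
                if isinstance(value, bool):
                    return int(value)
                if isinstance(value, float) and not value.is_integer():
                    raise ValueError(f"{value!r} is not integral")
                return int(value)
            if self.kind == "float":
                return float(value)
            return str(value)
        except (TypeError, ValueError) as exc:
            raise OperatorDomainError(f"cannot cast {value!r} to {self.kind}: {exc}") from exc


@dataclass(frozen=True)
class DateFormat:
    """Re-pattern a date-time string from *source* to *target* strptime patterns."""

    source: str
    target: str

    def evaluate(self, value: Any) -> Any:
        if not isinstance(value, str):
            raise OperatorDomainError(f"datefmt expects a string, got {type(value).__name__}")
        try:
            parsed = datetime.strptime(value, self.source)
        except ValueError as exc:
            raise OperatorDomainError(
                f"value {value!r} does not match date pattern {self.source!r}"
            ) from exc
        return parsed.strftime(self.target)


@dataclass(frozen=True)
class Remap:
    """Finite dictionary translation; a missing key is a domain error unless a default is set."""

    table: tuple[tuple[str, Any], ...]
    default: Any = None
    has_default: bool = False

    @classmethod
    def from_dict(cls, table: dict, default: Any = None, has_default: bool = False) -> "Remap":
        return cls(tuple(table.items()), default, has_default)

    def as_dict(self) -> dict:
        return dict(self.table)

    def evaluate(self, value: Any) -> Any:
        table = self.as_dict()
        try:
            hit = value in table
        except TypeError as exc:
            raise OperatorDomainError(f"unhashable remap input {value!r}") from exc
        if hit:
            return table[value]
        if self.has_default:
            return self.default
        raise OperatorDomainError(f"value {value!r} has no remap entry")


_ARITH_OPS = ("add", "sub", "mul", "div")


@dataclass(frozen=True)
class Arith:
    op: str
    operand: Union[int, float]

    def __post_init__(self) -> None:
        if self.op not in _ARITH_OPS:
            raise ValueError(f"unknown arithmetic op {self.op!r}")
        if self.op == "div" and self.operand == 0:
            raise ValueError("division by constant zero")

    def evaluate(self, value: Any) -> Any:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise OperatorDomainError(f"{self.op} expects a number, got {value!r}")
        if self.op == "add":
            return value + self.operand
        if self.op == "sub":
            return value - self.operand
        if self.op == "mul":
            return value * self.operand
        return value / self.operand


@dataclass(frozen=True)
class Concat:
    prefix: str = ""
    suffix: str = ""

    def evaluate(self, value: Any) -> Any:
        if not isinstance(value, str):
            raise OperatorDomainError(f"concat expects a string, got {type(value).__name__}")
        return self.prefix + value + self.suffix


@dataclass(frozen=True)
class Split:
    separator: str
    index: int

    def __post_init__(self) -> None:
        if not self.separator:
            raise ValueError("split separator must be non-empty")

    def evaluate(self, value: Any) -> Any:
        if not isinstance(value, str):
            raise OperatorDomainError(f"split expects a string, got {type(value).__name__}")
        parts = value.split(self.separator)
        if not -len(parts) <= self.index < len(parts):
            raise OperatorDomainError(
                f"split index {self.index} out of range for {len(parts)} parts of {value!r}"
            )
        return parts[self.index]


@dataclass(frozen=True)
class IfEq:
    """Equality-conditional: apply *then_op* when the value equals *compare*, else *else_op*."""

    compare: Any
    then_op: "OperatorExpr"
    else_op: "OperatorExpr"

    def evaluate(self, value: Any) -> Any:
        branch = self.then_op if value == self.compare else self.else_op
        return branch.evaluate(value)


@dataclass(frozen=True)
class Pipe:
    """Left-to-right composition of two or more operators."""

    steps: tuple["OperatorExpr", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.steps) < 2:
            raise ValueError("pipe needs at least two steps")

    def evaluate(self, value: Any) -> Any:
        for step in self.steps:
            value = step.evaluate(value)
        return value


OperatorExpr = Union[Identity, Cast, DateFormat, Remap, Arith, Concat, Split, IfEq, Pipe]


def evaluate_operator(op: OperatorExpr, value: Any) -> Any:
    """Apply *op* to *value*; deterministic, pure, total over the op's domain."""
    return op.evaluate(value)


# --------------------------------------------------------------------------
# serialization


def _quote(text: str) -> str:
    out = text.replace("\\", "\\\\").replace('"', '\\"')
    out = out.replace("\n", "\\n").replace("\t", "\\t")
    return f'"{out}"'


def _literal(value: Any) -> str:
    if value is None:
        return "null"
    if value is True:
        return "true"
    if value is False:
        return "false"
    if isinstance(value, str):
        return _quote(value)
    if isinstance(value, (int, float)):
        return repr(value)
    raise TypeError(f"unserializable literal {value!r}")


def serialize_operator(op: OperatorExpr) -> str:
    """Render the expression tree as canonical DSL text."""
    if isinstance(op, Identity):
        return "id"
    if isinstance(op, Cast):
        return f"cast({_quote(op.kind)})"
    if isinstance(op, DateFormat):
        return f"datefmt({_quote(op.source)}, {_quote(op.target)})"
    if isinstance(op, Remap):
        body = "{" + ", ".join(f"{_quote(k)}: {_literal(v)}" for k, v in op.table) + "}"
        if op.has_default:
            return f"remap({body}, {_literal(op.default)})"
        return f"remap({body})"
    if isinstance(op, Arith):
        return f"{op.op}({_literal(op.operand)})"
    if isinstance(op, Concat):
        return f"concat({_quote(op.prefix)}, {_quote(op.suffix)})"
    if isinstance(op, Split):
        return f"split({_quote(op.separator)}, {op.index})"
    if isinstance(op, IfEq):
        return (
            f"ifeq({_literal(op.compare)}, "
            f"{serialize_operator(op.then_op)}, {serialize_operator(op.else_op)})"
        )
    if isinstance(op, Pipe):
        return "pipe(" + ", ".join(serialize_operator(s) for s in op.steps) + ")"
    raise TypeError(f"not an operator expression: {op!r}")


# --------------------------------------------------------------------------
# parsing: tokenizer + recursive descent


@dataclass
class _Token:
    kind: str  # name | string | number | punct | end
    text: str
    value: Any
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "(){},:":
            tokens.append(_Token("punct", ch, ch, i))
            i += 1
            continue
        if ch == '"':
            j = i + 1
            out = []
            while j < n and text[j] != '"':
                if text[j] == "\\":
                    if j + 1 >= n:
                        raise OperatorSyntaxError("unterminated escape", j)
                    esc = text[j + 1]
                    out.append({"n": "\n", "t": "\t", '"': '"', "\\": "\\"}.get(esc, esc))
                    j += 2
                else:
                    out.append(text[j])
                    j += 1
            if j >= n:
                raise OperatorSyntaxError("unterminated string", i)
            tokens.append(_Token("string", text[i : j + 1], "".join(out), i))
            i = j + 1
            continue
        if ch.isdigit() or (ch == "-" and i + 1 < n and text[i + 1].isdigit()):
            j = i + 1
            while j < n and (text[j].isdigit() or text[j] in ".eE+-"):
                # stop '+'/'-' unless part of an exponent
                if text[j] in "+-" and text[j - 1] not in "eE":
                    break
                j += 1
            raw = text[i:j]
            try:
                value: Any = int(raw)
            except ValueError:
                try:
                    value = float(raw)
                except ValueError:
                    raise OperatorSyntaxError(f"bad number {raw!r}", i) from None
            tokens.append(_Token("number", raw, value, i))
            i = j
            continue
        if ch.isalpha() or ch == "_":
            j = i + 1
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(_Token("name", text[i:j], text[i:j], i))
            i = j
            continue
        raise OperatorSyntaxError(f"unexpected character {ch!r}", i)
    tokens.append(_Token("end", "", None, n))
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.cur
        self.i += 1
        return tok

    def expect(self, kind: str, text: str | None = None) -> _Token:
        tok = self.cur
        if tok.kind != kind or (text is not None and tok.text != text):
            want = text or kind
            raise OperatorSyntaxError(f"expected {want!r}, found {tok.text or 'end of input'!r}", tok.pos)
        return self.advance()

    def parse_expr(self) -> OperatorExpr:
        tok = self.expect("name")
        name = tok.value
        args: list[Any] = []
        if self.cur.kind == "punct" and self.cur.text == "(":
            self.advance()
            if not (self.cur.kind == "punct" and self.cur.text == ")"):
                args.append(self.parse_value())
                while self.cur.kind == "punct" and self.cur.text == ",":
                    self.advance()
                    args.append(self.parse_value())
            self.expect("punct", ")")
        return self.build(name, args, tok.pos)

    def parse_value(self) -> Any:
        tok = self.cur
        if tok.kind == "string" or tok.kind == "number":
            return self.advance().value
        if tok.kind == "punct" and tok.text == "{":
            return self.parse_dict()
        if tok.kind == "name":
            if tok.text in ("true", "false", "null"):
                self.advance()
                return {"true": True, "false": False, "null": None}[tok.text]
            return self.parse_expr()
        raise OperatorSyntaxError(f"unexpected token {tok.text!r}", tok.pos)

    def parse_dict(self) -> dict:
        self.expect("punct", "{")
        out: dict = {}
        if not (self.cur.kind == "punct" and self.cur.text == "}"):
            while True:
                key = self.expect("string").value
                self.expect("punct", ":")
                out[key] = self.parse_value()
                if self.cur.kind == "punct" and self.cur.text == ",":
                    self.advance()
                    continue
                break
        self.expect("punct", "}")
        return out

    def build(self, name: str, args: list[Any], pos: int) -> OperatorExpr:
        def need(n: int, *alts: int) -> None:
            if len(args) != n and len(args) not in alts:
                raise OperatorSyntaxError(
                    f"{name} takes {n} argument(s), got {len(args)}", pos
                )

        def op_arg(x: Any) -> OperatorExpr:
            if not _is_operator(x):
                raise OperatorSyntaxError(f"{name} expects an operator argument", pos)
            return x

        try:
            if name == "id":
                need(0)
                return Identity()
            if name == "cast":
                need(1)
                return Cast(args[0])
            if name == "datefmt":
                need(2)
                return DateFormat(args[0], args[1])
            if name == "remap":
                need(1, 2)
                if not isinstance(args[0], dict):
                    raise OperatorSyntaxError("remap expects a {..} table", pos)
                if len(args) == 2:
                    return Remap.from_dict(args[0], args[1], has_default=True)
                return Remap.from_dict(args[0])
            if name in _ARITH_OPS:
                need(1)
                if not isinstance(args[0], (int, float)) or isinstance(args[0], bool):
                    raise OperatorSyntaxError(f"{name} expects a numeric constant", pos)
                return Arith(name, args[0])
            if name == "concat":
                need(2)
                return Concat(str(args[0]), str(args[1]))
            if name == "split":
                need(2)
                return Split(args[0], args[1])
            if name == "ifeq":
                need(3)
                return IfEq(args[0], op_arg(args[1]), op_arg(args[2]))
            if name == "pipe":
                if len(args) < 2:
                    raise OperatorSyntaxError("pipe needs at least two steps", pos)
                return Pipe(tuple(op_arg(a) for a in args))
        except ValueError as exc:
            raise OperatorSyntaxError(str(exc), pos) from exc
        raise OperatorSyntaxError(f"unknown operator {name!r}", pos)


def _is_operator(x: Any) -> bool:
    return isinstance(x, (Identity, Cast, DateFormat, Remap, Arith, Concat, Split, IfEq, Pipe))


def parse_operator(text: str) -> OperatorExpr:
    """Parse DSL *text* into an expression tree; inverse of :func:`serialize_operator`."""
    parser = _Parser(_tokenize(text))
    expr = parser.parse_expr()
    tok = parser.cur
    if tok.kind != "end":
        raise OperatorSyntaxError(f"trailing input {tok.text!r}", tok.pos)
    return expr
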