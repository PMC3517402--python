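"""Model language and configuration parsing.

A model is a set of ``node`` blocks, each declaring the node's activation
rate (``rate_up``, fires while the node is 0) and inactivation rate
(``rate_down``, fires while the node is 1) as expressions over the current
network state and named parameters::

    node C {
      rate_up = B ? $kb : (A ? $ka : 0.0);
      rate_down = !(A & B) ? 1.0 : 0.0;
    }

Expressions support Boolean operators (``!``/NOT, ``&``/``&&``/AND,
``|``/``||``/OR, ``^``/XOR), arithmetic (+ - * /), comparisons
(== != < <= > >=) and the C ternary ``cond ? a : b`` with C precedence.
Node states are 0/1; any numeric value is treated as true iff it is
non-zero, and Boolean results coerce to 1.0/0.0 in arithmetic context.
Named parameters are written ``$name`` and may be left unbound until the
configuration supplies them.  A block may also define auxiliary
expressions (``logic = ...;``) referenced as ``@logic`` within the same
block; they are inlined at parse time.

The configuration file is a list of ``key = value;`` statements covering
simulation parameters (``timetick``, ``max_time``, ``sample_count``,
``statdist_traj_count``, ``statdist_cluster_threshold``, ``seed``,
``parallel_degree``), parameter bindings (``$k = 0.5;``) and per-node
settings (``X.istate = 1;``, ``X.is_internal = TRUE;``,
``X.refstate = 0;``).  ``#`` and ``//`` start line comments in both files.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "DslError",
    "EvaluationError",
    "NodeSpec",
    "Model",
    "SimulationConfig",
    "parse_expression",
    "parse_model",
    "parse_config",
    "evaluate_rate",
    "evaluate_expression",
    "expression_to_source",
    "serialize_model",
]

DEFAULT_SAMPLE_COUNT = 10_000
DEFAULT_STATDIST_TRAJ_COUNT = 100
DEFAULT_CLUSTER_THRESHOLD = 0.9
DEFAULT_SEED = 0


class DslError(ValueError):
    """Syntax or semantic error in a model or configuration file."""

    def __init__(self, message: str, line: Optional[int] = None, col: Optional[int] = None):
        self.line, self.col = line, col
        where = f" (line {line}, col {col})" if line is not None else ""
        super().__init__(message + where)


class EvaluationError(ValueError):
    """Rate expression evaluated to an invalid value (negative, non-finite,
    division by zero, or an unbound parameter)."""


# ---------------------------------------------------------------------------
# Lexer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
      (?P<ws>\s+|\#[^\n]*|//[^\n]*)
    | (?P<num>(?:\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?)
    | (?P<param>\$[A-Za-z_]\w*)
    | (?P<atref>@[A-Za-z_]\w*)
    | (?P<name>[A-Za-z_]\w*)
    | (?P<op>\|\||&&|==|!=|<=|>=|[|&^!<>+\-*/?:;={}()\[\],.])
    """,
    re.VERBOSE,
)


@dataclass
class _Token:
    kind: str  # num | param | atref | name | op | eof
    text: str
    line: int
    col: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos, line, line_start = 0, 1, 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise DslError(f"unexpected character {text[pos]!r}", line, pos - line_start + 1)
        kind = m.lastgroup
        tok = m.group()
        if kind != "ws":
            tokens.append(_Token(kind, tok, line, m.start() - line_start + 1))
        nl = tok.count("\n")
        if nl:
            line += nl
            line_start = m.start() + tok.rindex("\n") + 1
        pos = m.end()
    tokens.append(_Token("eof", "", line, 1))
    return tokens


# ---------------------------------------------------------------------------
# Expression parser (precedence climbing, C-like precedence)
# ---------------------------------------------------------------------------
# AST nodes are tuples:
#   ("num", float) ("node", name) ("param", name) ("field", name)
#   ("not", a) ("neg", a) ("bin", op, a, b) ("ite", cond, a, b)

_KEYWORD_OPS = {"AND": "&", "OR": "|", "NOT": "!", "XOR": "^", "TRUE": None, "FALSE": None}

_BINARY_LEVELS = [  # outermost (loosest) first; ternary handled separately
    {"|", "||"},
    {"&", "&&"},
    {"^"},
    {"==", "!="},
    {"<", "<=", ">", ">="},
    {"+", "-"},
    {"*", "/"},
]


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.toks = tokens
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.toks[self.i]

    def advance(self) -> _Token:
        t = self.cur
        self.i += 1
        return t

    def expect(self, text: str) -> _Token:
        t = self.cur
        if t.text != text:
            raise DslError(f"expected {text!r}, found {t.text or 'end of input'!r}", t.line, t.col)
        return self.advance()

    def error(self, msg: str) -> DslError:
        t = self.cur
        return DslError(msg, t.line, t.col)

    # -- expressions --------------------------------------------------------

    def expression(self):
        return self._ternary()

    def _ternary(self):
        cond = self._binary(0)
        if self.cur.text == "?":
            self.advance()
            a = self._ternary()
            self.expect(":")
            b = self._ternary()  # right associative
            return ("ite", cond, a, b)
        return cond

    def _binary(self, level: int):
        if level >= len(_BINARY_LEVELS):
            return self._unary()
        ops = _BINARY_LEVELS[level]
        left = self._binary(level + 1)
        while True:
            t = self.cur
            op = t.text
            if t.kind == "name" and t.text in ("AND", "OR", "XOR"):
                op = _KEYWORD_OPS[t.text]
            if op not in ops:
                return left
            self.advance()
            right = self._binary(level + 1)
            left = ("bin", "|" if op == "||" else "&" if op == "&&" else op, left, right)

    def _unary(self):
        t = self.cur
        if t.text == "!" or (t.kind == "name" and t.text == "NOT"):
            self.advance()
            return ("not", self._unary())
        if t.text == "-":
            self.advance()
            return ("neg", self._unary())
        if t.text == "+":
            self.advance()
            return self._unary()
        return self._primary()

    def _primary(self):
        t = self.cur
        if t.text == "(":
            self.advance()
            e = self.expression()
            self.expect(")")
            return e
        if t.kind == "num":
            self.advance()
            return ("num", float(t.text))
        if t.kind == "param":
            self.advance()
            return ("param", t.text[1:])
        if t.kind == "atref":
            self.advance()
            return ("field", t.text[1:])
        if t.kind == "name":
            if t.text == "TRUE":
                self.advance()
                return ("num", 1.0)
            if t.text == "FALSE":
                self.advance()
                return ("num", 0.0)
            if t.text in ("AND", "OR", "XOR", "NOT"):
                raise self.error(f"operator keyword {t.text} cannot start an operand")
            self.advance()
            return ("node", t.text)
        raise self.error(f"unexpected token {t.text or 'end of input'!r} in expression")


def parse_expression(text: str):
    """Parse a single rate expression from source text, returning its AST."""
    p = _Parser(_tokenize(text))
    e = p.expression()
    if p.cur.kind != "eof":
        raise p.error(f"trailing input {p.cur.text!r} after expression")
    return e


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class NodeSpec:
    """One node of the network: name, activation/inactivation rate
    expressions, and the flags set by the configuration."""

    name: str
    rate_up: tuple
    rate_down: tuple
    is_internal: bool = False
    is_reference: bool = False
    reference_value: Optional[int] = None
    initial: str = "random"  # "random" | "fixed-0" | "fixed-1"

    @property
    def is_input(self) -> bool:
        """Input nodes have a fixed initial condition."""
        return self.initial != "random"


@dataclass
class Model:
    """Parsed network: nodes in declaration order (bit ``i`` of a state word
    is the state of ``nodes[i]``) plus parameter bindings."""

    nodes: list[NodeSpec]
    parameters: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 1 <= len(self.nodes) <= 64:
            raise DslError(f"model must have between 1 and 64 nodes, got {len(self.nodes)}")
        self.index = {spec.name: i for i, spec in enumerate(self.nodes)}
        for name, v in self.parameters.items():
            if not math.isfinite(v):
                raise DslError(f"parameter ${name} is not finite")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def node(self, name: str) -> NodeSpec:
        try:
            return self.nodes[self.index[name]]
        except KeyError:
            raise DslError(f"unknown node {name!r}") from None

    # bit masks used throughout the estimators
    @property
    def output_mask(self) -> int:
        return sum(1 << i for i, s in enumerate(self.nodes) if not s.is_internal)

    @property
    def reference_mask(self) -> int:
        return sum(1 << i for i, s in enumerate(self.nodes) if s.is_reference)

    @property
    def reference_state(self) -> int:
        bits = 0
        for i, s in enumerate(self.nodes):
            if s.is_reference:
                if s.reference_value is None:
                    raise DslError(f"reference node {s.name} has no reference value")
                bits |= s.reference_value << i
        return bits

    def format_state(self, state: int, mask: Optional[int] = None) -> str:
        """Render a state as the names of its active nodes, in declaration
        order, e.g. ``[A C]``; the all-off state renders as ``[]``."""
        names = [
            s.name
            for i, s in enumerate(self.nodes)
            if (state >> i) & 1 and (mask is None or (mask >> i) & 1)
        ]
        return "[" + " ".join(names) + "]"

    def format_bits(self, state: int) -> str:
        """Render a state as a bit string in declaration order, e.g. [101]."""
        return "[" + "".join(str((state >> i) & 1) for i in range(self.n)) + "]"


@dataclass
class SimulationConfig:
    timetick: float
    max_time: float
    sample_count: int = DEFAULT_SAMPLE_COUNT
    statdist_traj_count: Optional[int] = None  # defaults to min(sample_count, 100)
    statdist_cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD
    seed: int = DEFAULT_SEED
    parallel_degree: int = 1

    def __post_init__(self):
        if self.statdist_traj_count is None:
            self.statdist_traj_count = min(self.sample_count, DEFAULT_STATDIST_TRAJ_COUNT)
        if self.timetick <= 0:
            raise DslError("timetick must be > 0")
        if self.max_time <= 0:
            raise DslError("max_time must be > 0")
        if self.max_time < self.timetick:
            raise DslError("max_time must be at least one timetick")
        if self.sample_count < 1:
            raise DslError("sample_count must be >= 1")
        if not 0 <= self.statdist_traj_count <= self.sample_count:
            raise DslError("statdist_traj_count must lie in [0, sample_count]")
        if not 0 < self.statdist_cluster_threshold <= 1:
            raise DslError("statdist_cluster_threshold must lie in (0, 1]")
        if self.parallel_degree < 1:
            raise DslError("parallel_degree must be >= 1")


# ---------------------------------------------------------------------------
# Model file parsing
# ---------------------------------------------------------------------------


def _resolve_fields(expr, fields: dict, stack: tuple = ()):
    """Inline @field references within a node block."""
    tag = expr[0]
    if tag == "field":
        name = expr[1]
        if name not in fields:
            raise DslError(f"reference to undefined field @{name}")
        if name in stack:
            raise DslError(f"circular field reference @{name}")
        return _resolve_fields(fields[name], fields, stack + (name,))
    if tag in ("num", "node", "param"):
        return expr
    if tag in ("not", "neg"):
        return (tag, _resolve_fields(expr[1], fields, stack))
    if tag == "bin":
        return ("bin", expr[1], _resolve_fields(expr[2], fields, stack), _resolve_fields(expr[3], fields, stack))
    if tag == "ite":
        return ("ite", *(_resolve_fields(e, fields, stack) for e in expr[1:]))
    raise AssertionError(f"unknown AST tag {tag}")


def _node_refs(expr) -> set:
    tag = expr[0]
    if tag == "node":
        return {expr[1]}
    if tag in ("num", "param"):
        return set()
    return set().union(*(_node_refs(e) for e in expr[1:] if isinstance(e, tuple)))


def parse_model(text: str) -> Model:
    """Parse model source into a :class:`Model`.

    Node order follows declaration order and defines the bit index of each
    node in state words.  Parameters may remain unbound here; binding them
    is the configuration's job.
    """
    p = _Parser(_tokenize(text))
    nodes: list[NodeSpec] = []
    seen: dict[str, int] = {}
    while p.cur.kind != "eof":
        t = p.cur
        if t.kind != "name" or t.text != "node":
            raise p.error(f"expected 'node' block, found {t.text!r}")
        p.advance()
        name_tok = p.cur
        if name_tok.kind != "name":
            raise p.error("expected node name after 'node'")
        name = p.advance().text
        if name in seen:
            raise DslError(f"duplicate node name {name!r}", name_tok.line, name_tok.col)
        seen[name] = len(nodes)
        p.expect("{")
        fields: dict[str, tuple] = {}
        while p.cur.text != "}":
            key_tok = p.cur
            if key_tok.kind != "name":
                raise p.error("expected field name inside node block")
            key = p.advance().text
            p.expect("=")
            expr = p.expression()
            p.expect(";")
            if key in fields:
                raise DslError(f"field {key!r} repeated in node {name}", key_tok.line, key_tok.col)
            fields[key] = expr
        p.expect("}")
        if "rate_up" not in fields or "rate_down" not in fields:
            raise DslError(f"node {name} must declare both rate_up and rate_down")
        aux = {k: v for k, v in fields.items() if k not in ("rate_up", "rate_down")}
        nodes.append(
            NodeSpec(
                name=name,
                rate_up=_resolve_fields(fields["rate_up"], aux),
                rate_down=_resolve_fields(fields["rate_down"], aux),
            )
        )
    if not nodes:
        raise DslError("no nodes declared")
    model = Model(nodes=nodes)
    for spec in nodes:
        for expr in (spec.rate_up, spec.rate_down):
            for ref in _node_refs(expr):
                if ref not in model.index:
                    raise DslError(f"node {spec.name} references undeclared node {ref!r}")
    return model


# ---------------------------------------------------------------------------
# Configuration parsing
# ---------------------------------------------------------------------------

_CFG_INT_KEYS = {"sample_count", "statdist_traj_count", "seed", "parallel_degree"}
_CFG_FLOAT_KEYS = {"timetick", "max_time", "statdist_cluster_threshold"}


def _cfg_value(p: _Parser) -> float:
    """A configuration value: signed number, or TRUE/FALSE."""
    t = p.cur
    sign = 1.0
    if t.text in ("+", "-"):
        sign = -1.0 if t.text == "-" else 1.0
        p.advance()
        t = p.cur
    if t.kind == "num":
        p.advance()
        return sign * float(t.text)
    if t.kind == "name" and t.text in ("TRUE", "FALSE"):
        p.advance()
        return 1.0 if t.text == "TRUE" else 0.0
    raise p.error(f"expected a numeric value, found {t.text!r}")


def parse_config(text: str, model: Model) -> SimulationConfig:
    """Parse a configuration file against a parsed model.

    Returns the :class:`SimulationConfig`; parameter bindings are merged
    into ``model.parameters`` and per-node settings (``istate``,
    ``is_internal``, ``refstate``) are applied to the model's node specs.
    """
    p = _Parser(_tokenize(text))
    values: dict[str, float] = {}
    while p.cur.kind != "eof":
        t = p.cur
        if t.kind == "param":
            name = p.advance().text[1:]
            p.expect("=")
            model.parameters[name] = _cfg_value(p)
            p.expect(";")
            continue
        if t.kind != "name":
            raise p.error(f"expected a setting name, found {t.text!r}")
        key = p.advance().text
        if p.cur.text == ".":  # node-scoped setting
            p.advance()
            if key not in model.index:
                raise DslError(f"configuration refers to unknown node {key!r}", t.line, t.col)
            spec = model.node(key)
            sub_tok = p.cur
            sub = p.advance().text
            p.expect("=")
            if sub == "istate":
                if p.cur.kind == "name" and p.cur.text == "random":
                    p.advance()
                    spec.initial = "random"
                else:
                    v = _cfg_value(p)
                    if v not in (0.0, 1.0):
                        raise DslError(f"{key}.istate must be 0, 1 or random", t.line, t.col)
                    spec.initial = f"fixed-{int(v)}"
            elif sub == "is_internal":
                spec.is_internal = _cfg_value(p) != 0.0
            elif sub == "refstate":
                v = _cfg_value(p)
                if v not in (0.0, 1.0):
                    raise DslError(f"{key}.refstate must be 0 or 1", t.line, t.col)
                spec.is_reference = True
                spec.reference_value = int(v)
            else:
                raise DslError(f"unknown node setting {sub!r}", sub_tok.line, sub_tok.col)
            p.expect(";")
            continue
        p.expect("=")
        v = _cfg_value(p)
        p.expect(";")
        if key in _CFG_INT_KEYS:
            values[key] = int(v)
        elif key in _CFG_FLOAT_KEYS:
            values[key] = float(v)
        else:
            raise DslError(f"unknown configuration key {key!r}", t.line, t.col)
    if "timetick" not in values or "max_time" not in values:
        raise DslError("configuration must set timetick and max_time explicitly")
    values.setdefault("sample_count", DEFAULT_SAMPLE_COUNT)
    values.setdefault(
        "statdist_traj_count", min(values["sample_count"], DEFAULT_STATDIST_TRAJ_COUNT)
    )
    return SimulationConfig(**values)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_expression(expr, state: int, params: dict, index: dict) -> float:
    """Evaluate an expression AST on a state word. Boolean results are
    1.0/0.0; a numeric operand is true iff non-zero."""
    tag = expr[0]
    if tag == "num":
        return expr[1]
    if tag == "node":
        try:
            return float((state >> index[expr[1]]) & 1)
        except KeyError:
            raise EvaluationError(f"undeclared node {expr[1]!r}") from None
    if tag == "param":
        try:
            return float(params[expr[1]])
        except KeyError:
            raise EvaluationError(f"unbound parameter ${expr[1]}") from None
    if tag == "not":
        return 0.0 if evaluate_expression(expr[1], state, params, index) != 0.0 else 1.0
    if tag == "neg":
        return -evaluate_expression(expr[1], state, params, index)
    if tag == "ite":
        cond = evaluate_expression(expr[1], state, params, index)
        return evaluate_expression(expr[2] if cond != 0.0 else expr[3], state, params, index)
    if tag == "bin":
        op = expr[1]
        a = evaluate_expression(expr[2], state, params, index)
        b = evaluate_expression(expr[3], state, params, index)
        if op == "&":
            return 1.0 if (a != 0.0 and b != 0.0) else 0.0
        if op == "|":
            return 1.0 if (a != 0.0 or b != 0.0) else 0.0
        if op == "^":
            return 1.0 if (a != 0.0) != (b != 0.0) else 0.0
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            if b == 0.0:
                raise EvaluationError("division by zero in rate expression")
            return a / b
        if op == "==":
            return 1.0 if a == b else 0.0
        if op == "!=":
            return 1.0 if a != b else 0.0
        if op == "<":
            return 1.0 if a < b else 0.0
        if op == "<=":
            return 1.0 if a <= b else 0.0
        if op == ">":
            return 1.0 if a > b else 0.0
        if op == ">=":
            return 1.0 if a >= b else 0.0
    raise AssertionError(f"unknown AST node {expr!r}")


def evaluate_rate(expr, state: int, params: dict, model: Model) -> float:
    """Evaluate a rate expression; the result must be finite and >= 0."""
    v = evaluate_expression(expr, state, params, model.index)
    if not math.isfinite(v):
        raise EvaluationError(f"rate evaluated to non-finite value {v}")
    if v < 0:
        raise EvaluationError(f"rate evaluated to negative value {v}")
    return v


# ---------------------------------------------------------------------------
# Serialization (round-trip support)
# ---------------------------------------------------------------------------

_PRECEDENCE = {"|": 1, "&": 2, "^": 3, "==": 4, "!=": 4, "<": 5, "<=": 5, ">": 5, ">=": 5,
               "+": 6, "-": 6, "*": 7, "/": 7}


def expression_to_source(expr, _parent_prec: int = 0) -> str:
    tag = expr[0]
    if tag == "num":
        v = expr[1]
        return repr(v) if v != int(v) else f"{int(v)}.0" if "." in repr(v) else repr(v)
    if tag == "node":
        return expr[1]
    if tag == "param":
        return "$" + expr[1]
    if tag == "not":
        return "!" + expression_to_source(expr[1], 8)
    if tag == "neg":
        return "-" + expression_to_source(expr[1], 8)
    if tag == "ite":
        s = (
            expression_to_source(expr[1], 1)
            + " ? "
            + expression_to_source(expr[2], 0)
            + " : "
            + expression_to_source(expr[3], 0)
        )
        return "(" + s + ")" if _parent_prec > 0 else s
    if tag == "bin":
        op = expr[1]
        prec = _PRECEDENCE[op]
        s = (
            expression_to_source(expr[2], prec)
            + f" {op} "
            + expression_to_source(expr[3], prec + 1)
        )
        return "(" + s + ")" if prec < _parent_prec else s
    raise AssertionError(f"unknown AST node {expr!r}")


def serialize_model(model: Model) -> str:
    """Render a model back to source; reparsing yields an identical AST."""
    blocks = []
    for spec in model.nodes:
        blocks.append(
            f"node {spec.name} {{\n"
            f"  rate_up = {expression_to_source(spec.rate_up)};\n"
            f"  rate_down = {expression_to_source(spec.rate_down)};\n"
            f"}}"
        )
    return "\n".join(blocks) + "\n"
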