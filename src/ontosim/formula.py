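"""The formula DSL: user-defined similarity algorithms.

A similarity algorithm is a named arithmetic formula over a closed
registry of graph components, evaluated for one ordered term pair with
one selected common ancestor:

====================  =====================================================
component             meaning for the pair (term1, term2)
====================  =====================================================
P.Node1 / P.Node2     annotation probability of each compared term
P.CommonAncestor      annotation probability of the selected common ancestor
Depth.*               root-relative depth (unit or depth-weighted edges)
Children.*            number of direct children
Parents.Node1/Node2   number of direct parents
Distance.Shortest     min over common ancestors of the up-down distance
Distance.Average      mean of the same set
Distance.Total        sum of the same set
Distance.Maximum      max of the same set
SharedPath            depth of the selected common ancestor
====================  =====================================================

Grammar (precedence low → high)::

    additive    :=  multiplicative (("+" | "-") multiplicative)*
    multiplic.  :=  unary (("*" | "/") unary)*
    unary       :=  "-" unary | power
    power       :=  atom ("^" unary)?          # right-associative
    atom        :=  NUMBER | COMPONENT | "log" "(" additive ")"
                  | "sqrt" "(" additive ")" | "(" additive ")"

so ``-x^2`` parses as ``-(x^2)`` and ``a/b*c`` as ``(a/b)*c``.  The
classical information-content measures are one-liners::

    Resnik         -log(P.CommonAncestor)
    Lin            2*log(P.CommonAncestor)/(log(P.Node1)+log(P.Node2))
    Jiang-Conrath  log(P.Node1)+log(P.Node2)-2*log(P.CommonAncestor)
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple
from urllib.parse import quote, unquote

from .errors import (
    CorruptFileError,
    DivisionByZeroError,
    DomainError,
    DuplicateNameError,
    FormulaSyntaxError,
    NotFoundError,
    UnknownComponentError,
    ValidationError,
)
from . import ontology as core
from .ontology import OntologyDAG

COMPONENTS: FrozenSet[str] = frozenset(
    {
        "P.Node1",
        "P.Node2",
        "P.CommonAncestor",
        "Depth.Node1",
        "Depth.Node2",
        "Depth.CommonAncestor",
        "Children.Node1",
        "Children.Node2",
        "Children.CommonAncestor",
        "Parents.Node1",
        "Parents.Node2",
        "Distance.Shortest",
        "Distance.Average",
        "Distance.Total",
        "Distance.Maximum",
        "SharedPath",
    }
)

_FUNCTIONS = ("log", "sqrt")
_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}

# --- AST -------------------------------------------------------------------


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Component:
    name: str


@dataclass(frozen=True)
class BinOp:
    op: str  # + - * / ^
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Neg:
    operand: "Node"


@dataclass(frozen=True)
class Func:
    name: str  # log | sqrt
    operand: "Node"


Node = object  # Num | Component | BinOp | Neg | Func


def components_used(ast: Node) -> Set[str]:
    """Set of registry components appearing as leaves of the AST."""
    if isinstance(ast, Component):
        return {ast.name}
    if isinstance(ast, Num):
        return set()
    if isinstance(ast, Neg) or isinstance(ast, Func):
        return components_used(ast.operand)
    if isinstance(ast, BinOp):
        return components_used(ast.left) | components_used(ast.right)
    raise TypeError(f"not an AST node: {ast!r}")


def to_text(ast: Node) -> str:
    """Render an AST back to formula text; reparsing yields an equal AST."""
    if isinstance(ast, Num):
        v = ast.value
        return repr(int(v)) if float(v).is_integer() and abs(v) < 1e15 else repr(v)
    if isinstance(ast, Component):
        return ast.name
    if isinstance(ast, Neg):
        return f"(-({to_text(ast.operand)}))"
    if isinstance(ast, Func):
        return f"{ast.name}({to_text(ast.operand)})"
    if isinstance(ast, BinOp):
        return f"({to_text(ast.left)}{ast.op}{to_text(ast.right)})"
    raise TypeError(f"not an AST node: {ast!r}")


# --- tokenizer / recursive-descent parser ----------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)"
    r"|(?P<ident>[A-Za-z_][A-Za-z0-9_]*(?:\.[A-Za-z_][A-Za-z0-9_]*)*)"
    r"|(?P<op>[-+*/^()]))"
)


def _tokenize(text: str) -> List[Tuple[str, str, int]]:
    tokens: List[Tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            # skip over leading whitespace before complaining
            rest = text[pos:]
            if rest.strip() == "":
                break
            bad = pos + (len(rest) - len(rest.lstrip()))
            raise FormulaSyntaxError(f"unexpected character {text[bad]!r}", bad)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> Optional[Tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> Tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise FormulaSyntaxError("unexpected end of formula", len(self.text))
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        tok = self.peek()
        if tok is None or tok[1] != value:
            pos = tok[2] if tok else len(self.text)
            raise FormulaSyntaxError(f"expected {value!r}", pos)
        self.i += 1

    def parse(self) -> Node:
        node = self.additive()
        tok = self.peek()
        if tok is not None:
            raise FormulaSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def additive(self) -> Node:
        node = self.multiplicative()
        while (tok := self.peek()) and tok[1] in ("+", "-"):
            self.i += 1
            node = BinOp(tok[1], node, self.multiplicative())
        return node

    def multiplicative(self) -> Node:
        node = self.unary()
        while (tok := self.peek()) and tok[1] in ("*", "/"):
            self.i += 1
            node = BinOp(tok[1], node, self.unary())
        return node

    def unary(self) -> Node:
        tok = self.peek()
        if tok and tok[1] == "-":
            self.i += 1
            return Neg(self.unary())
        return self.power()

    def power(self) -> Node:
        base = self.atom()
        tok = self.peek()
        if tok and tok[1] == "^":
            self.i += 1
            return BinOp("^", base, self.unary())  # right-assoc, allows 2^-3
        return base

    def atom(self) -> Node:
        kind, value, pos = self.next()
        if kind == "num":
            return Num(float(value))
        if kind == "ident":
            if value in _FUNCTIONS:
                self.expect("(")
                inner = self.additive()
                self.expect(")")
                return Func(value, inner)
            if value not in COMPONENTS:
                raise UnknownComponentError(
                    f"unknown component {value!r} (registry: "
                    f"{', '.join(sorted(COMPONENTS))})"
                )
            return Component(value)
        if value == "(":
            inner = self.additive()
            self.expect(")")
            return inner
        raise FormulaSyntaxError(f"unexpected token {value!r}", pos)


def parse_formula(formula_text: str) -> Node:
    """Parse formula text into an AST.

    Raises :class:`FormulaSyntaxError` (with character position) on bad
    syntax and :class:`UnknownComponentError` for identifiers outside the
    component registry.
    """
    if not formula_text or not formula_text.strip():
        raise FormulaSyntaxError("empty formula", 0)
    return _Parser(formula_text).parse()


# --- evaluation ------------------------------------------------------------


def evaluate(ast: Node, ctx: Dict[str, float], log_base: str = "e") -> float:
    """Evaluate an AST against bound component values.

    log uses the algorithm's base (e, 2 or 10).  A log of a non-positive
    value or sqrt of a negative raises :class:`DomainError` naming the
    offending value; division by zero raises
    :class:`DivisionByZeroError`.  The result is always finite.
    """
    if log_base not in _LOG_BASES:
        raise ValueError(f"log base must be one of {sorted(_LOG_BASES)}")
    base = _LOG_BASES[log_base]
    value = _eval(ast, ctx, base)
    if not math.isfinite(value):
        raise DomainError(f"formula evaluated to non-finite value {value!r}")
    return value + 0.0  # normalizes -0.0


def _eval(ast: Node, ctx: Dict[str, float], base: float) -> float:
    if isinstance(ast, Num):
        return ast.value
    if isinstance(ast, Component):
        try:
            return float(ctx[ast.name])
        except KeyError:
            raise UnknownComponentError(
                f"component {ast.name!r} not bound in evaluation context"
            ) from None
    if isinstance(ast, Neg):
        return -_eval(ast.operand, ctx, base)
    if isinstance(ast, Func):
        x = _eval(ast.operand, ctx, base)
        if ast.name == "log":
            if x <= 0.0:
                raise DomainError(
                    f"log of non-positive value {x!r} in {to_text(ast)!r}"
                )
            return math.log(x) / math.log(base)
        if x < 0.0:
            raise DomainError(f"sqrt of negative value {x!r} in {to_text(ast)!r}")
        return math.sqrt(x)
    if isinstance(ast, BinOp):
        a = _eval(ast.left, ctx, base)
        b = _eval(ast.right, ctx, base)
        if ast.op == "+":
            return a + b
        if ast.op == "-":
            return a - b
        if ast.op == "*":
            return a * b
        if ast.op == "/":
            if b == 0.0:
                raise DivisionByZeroError(f"division by zero in {to_text(ast)!r}")
            return a / b
        if ast.op == "^":
            if a == 0.0 and b < 0.0:
                raise DivisionByZeroError(
                    f"zero raised to negative power in {to_text(ast)!r}"
                )
            if a < 0.0 and not float(b).is_integer():
                raise DomainError(
                    f"negative base {a!r} with non-integer exponent {b!r}"
                )
            try:
                return math.pow(a, b)
            except OverflowError:
                raise DomainError(f"overflow in {to_text(ast)!r}") from None
    raise TypeError(f"not an AST node: {ast!r}")


# --- algorithm definitions -------------------------------------------------


@dataclass(frozen=True)
class AlgorithmDefinition:
    """A named, validated formula plus its evaluation options."""

    name: str
    formula_text: str
    ast: Node = field(compare=False)
    components: FrozenSet[str] = field(compare=False)
    ancestor_strategy: str = "mica"  # mica | deepest
    edge_weighting: str = "unit"  # unit | depth
    log_base: str = "e"  # e | 2 | 10

    @staticmethod
    def from_formula(
        name: str,
        formula_text: str,
        ancestor_strategy: str = "mica",
        edge_weighting: str = "unit",
        log_base: str = "e",
    ) -> "AlgorithmDefinition":
        ast = parse_formula(formula_text)
        return AlgorithmDefinition(
            name=name,
            formula_text=formula_text,
            ast=ast,
            components=frozenset(components_used(ast)),
            ancestor_strategy=ancestor_strategy,
            edge_weighting=edge_weighting,
            log_base=log_base,
        )


_NEEDS_CA = {
    "P.CommonAncestor",
    "Depth.CommonAncestor",
    "Children.CommonAncestor",
    "SharedPath",
}


def bind_context(
    dag: OntologyDAG, t1: str, t2: str, alg: AlgorithmDefinition
) -> Dict[str, float]:
    """Bind every component the algorithm uses, and only those.

    The common ancestor is selected with the algorithm's strategy only if
    some used component refers to it; probabilities are only computed for
    P.* components, so an unannotated DAG still supports purely
    structural formulas.
    """
    ctx: Dict[str, float] = {}
    used = alg.components
    ca: Optional[str] = None
    if used & _NEEDS_CA:
        ca = core.select_common_ancestor(dag, t1, t2, alg.ancestor_strategy)
    w = alg.edge_weighting
    for comp in sorted(used):
        family, _, which = comp.partition(".")
        if family == "P":
            tid = {"Node1": t1, "Node2": t2, "CommonAncestor": ca}[which]
            ctx[comp] = core.probability(dag, tid)
        elif family == "Depth":
            tid = {"Node1": t1, "Node2": t2, "CommonAncestor": ca}[which]
            ctx[comp] = core.depth(dag, tid, w)
        elif family == "Children":
            tid = {"Node1": t1, "Node2": t2, "CommonAncestor": ca}[which]
            ctx[comp] = float(core.children_count(dag, tid))
        elif family == "Parents":
            tid = {"Node1": t1, "Node2": t2}[which]
            ctx[comp] = float(core.parents_count(dag, tid))
        elif family == "Distance":
            ctx[comp] = core.distance(dag, t1, t2, which.lower(), w)
        elif comp == "SharedPath":
            ctx[comp] = core.shared_path(dag, ca, w)
        else:  # pragma: no cover - registry is closed
            raise UnknownComponentError(comp)
    return ctx


# --- the question/answer definition dialogue -------------------------------

# menu groups offered one at a time in the wizard; picking a group
# declares all of its components for formula validation
COMPONENT_GROUPS: Dict[str, FrozenSet[str]] = {
    "CommonAncestor": frozenset(
        {"P.CommonAncestor", "Depth.CommonAncestor", "Children.CommonAncestor", "SharedPath"}
    ),
    "Node1": frozenset({"P.Node1", "Depth.Node1", "Children.Node1", "Parents.Node1"}),
    "Node2": frozenset({"P.Node2", "Depth.Node2", "Children.Node2", "Parents.Node2"}),
    "Distance": frozenset(
        {"Distance.Shortest", "Distance.Average", "Distance.Total", "Distance.Maximum"}
    ),
}
_MENU = {"1": "CommonAncestor", "2": "Node1", "3": "Node2", "4": "Distance"}
_YES = {"yes", "y"}
_NO = {"no", "n"}


def _resolve_choice(answer: str) -> FrozenSet[str]:
    ans = answer.strip()
    if ans in _MENU:
        return COMPONENT_GROUPS[_MENU[ans]]
    for group, members in COMPONENT_GROUPS.items():
        if ans.lower() == group.lower():
            return members
    if ans in COMPONENTS:
        return frozenset({ans})
    raise ValidationError(
        f"unrecognized component choice {answer!r}; pick 1-4, a group name, "
        f"or a registry component"
    )


def define_algorithm(
    answers: Iterable[str],
    existing_names: Iterable[str] = (),
    ancestor_strategy: str = "mica",
    edge_weighting: str = "unit",
    log_base: str = "e",
) -> Optional[AlgorithmDefinition]:
    """Drive the definition dialogue from an ordered answer transcript.

    Expected order: component choice, then the "any other component?"
    answer, repeated while affirmative; formula text; algorithm name;
    confirmation.  A negative confirmation aborts and returns None.
    Formulas referencing components outside the declared groups raise
    :class:`ValidationError`; a name already in ``existing_names`` raises
    :class:`DuplicateNameError`.
    """
    it: Iterator[str] = iter(answers)

    def ask(what: str) -> str:
        try:
            return next(it).strip()
        except StopIteration:
            raise ValidationError(f"transcript ended early: missing {what}") from None

    declared: Set[str] = set()
    while True:
        declared |= _resolve_choice(ask("component choice"))
        more = ask("'any other component?' answer").lower()
        if more in _NO:
            break
        if more not in _YES:
            raise ValidationError(f"expected yes/no, got {more!r}")
    formula_text = ask("formula")
    name = ask("algorithm name")
    confirm = ask("confirmation").lower()
    if confirm not in _YES:
        return None

    ast = parse_formula(formula_text)
    used = components_used(ast)
    undeclared = sorted(used - declared)
    if undeclared:
        raise ValidationError(
            f"formula uses components not chosen in the dialogue: "
            f"{', '.join(undeclared)}"
        )
    if name in set(existing_names):
        raise DuplicateNameError(f"algorithm {name!r} already exists")
    return AlgorithmDefinition(
        name=name,
        formula_text=formula_text,
        ast=ast,
        components=frozenset(used),
        ancestor_strategy=ancestor_strategy,
        edge_weighting=edge_weighting,
        log_base=log_base,
    )


# --- flat-file algorithm store ---------------------------------------------

_MANDATORY_KEYS = ("name", "formula")
_SUFFIX = ".alg"


def _algorithm_path(name: str, store_dir) -> str:
    return os.path.join(store_dir, quote(name, safe="") + _SUFFIX)


def save_algorithm(alg: AlgorithmDefinition, store_dir) -> str:
    """Persist one algorithm as a flat key: value text file; returns the path."""
    os.makedirs(store_dir, exist_ok=True)
    path = _algorithm_path(alg.name, store_dir)
    lines = [
        f"name: {alg.name}",
        f"formula: {alg.formula_text}",
        f"ancestor_strategy: {alg.ancestor_strategy}",
        f"edge_weighting: {alg.edge_weighting}",
        f"log_base: {alg.log_base}",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def load_algorithm(name: str, store_dir) -> AlgorithmDefinition:
    """Load a stored algorithm; load→save→load is a fixpoint."""
    path = _algorithm_path(name, store_dir)
    if not os.path.exists(path):
        raise NotFoundError(f"no stored algorithm named {name!r} in {store_dir}")
    fields: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or ":" not in line:
                continue
            key, value = line.split(":", 1)
            fields[key.strip()] = value.strip()
    for key in _MANDATORY_KEYS:
        if key not in fields:
            raise CorruptFileError(f"algorithm file {path} missing key {key!r}")
    return AlgorithmDefinition.from_formula(
        name=fields["name"],
        formula_text=fields["formula"],
        ancestor_strategy=fields.get("ancestor_strategy", "mica"),
        edge_weighting=fields.get("edge_weighting", "unit"),
        log_base=fields.get("log_base", "e"),
    )


def list_algorithms(store_dir) -> List[str]:
    """Names of all algorithms stored in a directory, sorted."""
    if not os.path.isdir(store_dir):
        return []
    names = []
    for fn in os.listdir(store_dir):
        if fn.endswith(_SUFFIX):
            names.append(unquote(fn[: -len(_SUFFIX)]))
    return sorted(names)
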