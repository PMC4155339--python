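"""Tree-program representation of network generators.

A *generator* is a small program — an expression tree over arithmetic
operators, conditionals and an affinity function — that computes a weight
``w(i, j)`` for a candidate arc from node ``i`` to node ``j``.  The weight
drives stochastic arc selection during network growth, so the tree *is* the
growth model: ``1.0`` is uniform random attachment, ``k'`` is preferential
attachment to the target's degree, ``(/ 1 i)`` gives nodes hyperbolically
decaying propensities, and ``(psi g a b)`` encodes group affinity.

Programs are immutable: mutation and subtree replacement build new trees.
All evaluation is *protected* (division by zero, logs of non-positive
numbers and numeric overflow are tamed) so that randomly generated and
mutated programs always return finite weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ProgramNode",
    "GeneratorProgram",
    "ProgramSyntaxError",
    "affinity",
    "parse",
    "random_program",
    "mutate",
    "program_length",
]

#: magnitude cap for protected arithmetic
MAX_MAGNITUDE = 1e300
#: exp argument cap keeping exp(x) <= 1e300
_EXP_ARG_CAP = 690.0

#: operator symbol -> arity
OPERATORS: dict[str, int] = {
    "+": 2,
    "-": 2,
    "*": 2,
    "/": 2,
    "pow": 2,
    "min": 2,
    "max": 2,
    "exp": 1,
    "log": 1,
    "abs": 1,
    # conditionals select a branch: (gt a b t f) -> t if a > b else f;
    # eq0 is ternary: (eq0 x t f) -> t if x == 0 else f
    "gt": 4,
    "lt": 4,
    "eq": 4,
    "eq0": 3,
    # affinity: (psi g a b) with the arc endpoints i, j implicit
    "psi": 3,
}

#: variables legal in directed mode: endpoint identifiers, in-degrees
#: (origin k, target k'), and the three walk-heuristic distances
VARIABLES_DIRECTED: tuple[str, ...] = ("i", "j", "k", "k'", "d", "d_D", "d_R")
#: undirected mode drops the directed distances; k / k' are total degrees
VARIABLES_UNDIRECTED: tuple[str, ...] = ("i", "j", "k", "k'", "d")
#: variables whose values require random-walk distance estimation
DISTANCE_VARIABLES: frozenset[str] = frozenset({"d", "d_D", "d_R"})

_ALIASES = {"ψ": "psi", "−": "-", "×": "*"}


class ProgramSyntaxError(ValueError):
    """Raised when program text cannot be parsed (carries a position)."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


@dataclass(frozen=True, slots=True)
class ProgramNode:
    """One node of a generator tree.

    ``kind`` is ``"op"``, ``"var"`` or ``"const"``.  Operator nodes carry a
    symbol from :data:`OPERATORS` and exactly the arity it demands; variable
    nodes carry a symbol from the mode's variable set; constant nodes carry
    a finite float in ``value``.
    """

    kind: str
    symbol: str = ""
    value: float = 0.0
    children: tuple["ProgramNode", ...] = ()

    def __post_init__(self):
        if self.kind == "op":
            arity = OPERATORS.get(self.symbol)
            if arity is None:
                raise ValueError(f"unknown operator {self.symbol!r}")
            if len(self.children) != arity:
                raise ValueError(
                    f"operator {self.symbol!r} needs {arity} children, "
                    f"got {len(self.children)}"
                )
        elif self.kind == "var":
            if self.symbol not in VARIABLES_DIRECTED:
                raise ValueError(f"unknown variable {self.symbol!r}")
            if self.children:
                raise ValueError("variable nodes are leaves")
        elif self.kind == "const":
            if not np.isfinite(self.value):
                raise ValueError("constants must be finite")
            if self.children:
                raise ValueError("constant nodes are leaves")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def op(symbol: str, *children: "ProgramNode") -> "ProgramNode":
        return ProgramNode("op", symbol=symbol, children=tuple(children))

    @staticmethod
    def var(symbol: str) -> "ProgramNode":
        return ProgramNode("var", symbol=symbol)

    @staticmethod
    def const(value: float) -> "ProgramNode":
        return ProgramNode("const", value=float(value))

    # -- traversal ---------------------------------------------------------
    def walk(self) -> Iterator["ProgramNode"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __len__(self) -> int:
        return sum(1 for _ in self.walk())

    @property
    def depth(self) -> int:
        if not self.children:
            return 0
        return 1 + max(c.depth for c in self.children)


def _clamp(x: np.ndarray) -> np.ndarray:
    """Cap magnitudes at 1e300 (maps ±inf overflow back to the cap).

    With both arguments already finite and the division/log/exp guards in
    place, no operator can produce NaN, so a two-sided clip suffices to
    keep every intermediate value finite.
    """
    return np.minimum(np.maximum(x, -MAX_MAGNITUDE), MAX_MAGNITUDE)


def _eval_node(node: ProgramNode, ctx: Mapping[str, np.ndarray]) -> np.ndarray:
    if node.kind == "const":
        return np.asarray(node.value, dtype=float)
    if node.kind == "var":
        return np.asarray(ctx[node.symbol], dtype=float)
    sym = node.symbol
    args = [_eval_node(c, ctx) for c in node.children]
    with np.errstate(all="ignore"):
        if sym == "+":
            return _clamp(args[0] + args[1])
        if sym == "-":
            return _clamp(args[0] - args[1])
        if sym == "*":
            return _clamp(args[0] * args[1])
        if sym == "/":
            denom = args[1]
            return _clamp(np.where(denom == 0, 0.0,
                                   args[0] / np.where(denom == 0, 1.0, denom)))
        if sym == "pow":
            # protected power: |base| ** exponent (|x|**0 == 1), capped
            return _clamp(np.abs(args[0]) ** args[1])
        if sym == "min":
            return np.minimum(args[0], args[1])
        if sym == "max":
            return np.maximum(args[0], args[1])
        if sym == "exp":
            return np.exp(np.minimum(args[0], _EXP_ARG_CAP))
        if sym == "log":
            a = args[0]
            return np.where(a > 0, np.log(np.where(a > 0, a, 1.0)), 0.0)
        if sym == "abs":
            return np.abs(args[0])
        if sym == "gt":
            return np.where(args[0] > args[1], args[2], args[3])
        if sym == "lt":
            return np.where(args[0] < args[1], args[2], args[3])
        if sym == "eq":
            return np.where(args[0] == args[1], args[2], args[3])
        if sym == "eq0":
            return np.where(args[0] == 0, args[1], args[2])
        if sym == "psi":
            g = np.trunc(args[0])
            g = np.where(g < 1, 1.0, g)
            same = np.mod(ctx["i"], g) == np.mod(ctx["j"], g)
            return np.where(same, args[1], args[2])
        raise AssertionError(sym)  # pragma: no cover - guarded by validation


@dataclass(frozen=True)
class GeneratorProgram:
    """A validated generator: an expression tree plus its directedness mode.

    The mode fixes the legal variable set: undirected programs may not
    reference the directed distances ``d_D`` / ``d_R``.
    """

    root: ProgramNode
    directed: bool = True
    _variables: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        legal = set(VARIABLES_DIRECTED if self.directed else VARIABLES_UNDIRECTED)
        used = {n.symbol for n in self.root.walk() if n.kind == "var"}
        # psi reads the endpoint identifiers implicitly
        if any(n.kind == "op" and n.symbol == "psi" for n in self.root.walk()):
            used |= {"i", "j"}
        illegal = used - legal
        if illegal:
            mode = "directed" if self.directed else "undirected"
            raise ValueError(
                f"variables {sorted(illegal)} are illegal in {mode} mode"
            )
        object.__setattr__(self, "_variables", frozenset(used))

    # -- introspection -----------------------------------------------------
    @property
    def variables(self) -> frozenset[str]:
        """Variable symbols the program references."""
        return self._variables

    @property
    def distance_variables(self) -> frozenset[str]:
        """Which walk-heuristic distances the program needs (possibly none)."""
        return self._variables & DISTANCE_VARIABLES

    def __len__(self) -> int:
        return len(self.root)

    # -- evaluation --------------------------------------------------------
    def evaluate(self, ctx: Mapping[str, float | np.ndarray]) -> np.ndarray | float:
        """Compute the arc weight(s) for a context of scalars or arrays.

        Always returns finite values; vector contexts are evaluated in one
        pass (every variable array must share one shape).
        """
        out = _eval_node(self.root, ctx)
        if out.ndim == 0:
            return float(out)
        return out

    def __call__(self, **ctx: float | np.ndarray) -> np.ndarray | float:
        return self.evaluate(ctx)

    # -- text --------------------------------------------------------------
    def format(self) -> str:
        """Canonical prefix s-expression text."""
        return _format_node(self.root)

    def to_infix(self) -> str:
        """Human-oriented infix rendering for reports."""
        return _infix_node(self.root)

    def __str__(self) -> str:
        return self.format()

    # -- editing -----------------------------------------------------------
    def replace_subtree(self, index: int, subtree: ProgramNode) -> "GeneratorProgram":
        """Return a copy with the pre-order node ``index`` replaced."""
        new_root, _ = _replace_at(self.root, index, subtree)
        return GeneratorProgram(new_root, directed=self.directed)

    def node_at(self, index: int) -> ProgramNode:
        for pos, node in enumerate(self.root.walk()):
            if pos == index:
                return node
        raise IndexError(index)


# ---------------------------------------------------------------------------
# linearized form for the compiled growth engine
# ---------------------------------------------------------------------------

#: ctx-matrix row index per variable symbol
VARIABLE_ROWS = {sym: row for row, sym in enumerate(VARIABLES_DIRECTED)}

#: opcode table for the postorder stack machine (0..6 are variable pushes)
OPCODE_CONST = 10
OPCODES = {"+": 20, "-": 21, "*": 22, "/": 23, "pow": 24, "min": 25,
           "max": 26, "exp": 27, "log": 28, "abs": 29, "gt": 30, "lt": 31,
           "eq": 32, "eq0": 33, "psi": 34}


def compile_program(program: GeneratorProgram) -> tuple[np.ndarray, np.ndarray]:
    """Linearize a program to postorder opcodes plus a constant pool.

    The compiled form evaluates on a ``(7, S)`` context matrix whose rows
    follow :data:`VARIABLE_ROWS`; it is consumed by the numba growth
    kernel and must agree exactly with :meth:`GeneratorProgram.evaluate`.
    """
    codes: list[int] = []
    consts: list[float] = []

    def emit(node: ProgramNode) -> None:
        if node.kind == "const":
            codes.append(OPCODE_CONST)
            consts.append(node.value)
            return
        if node.kind == "var":
            codes.append(VARIABLE_ROWS[node.symbol])
            return
        for child in node.children:
            emit(child)
        codes.append(OPCODES[node.symbol])

    emit(program.root)
    return (np.array(codes, dtype=np.int64),
            np.array(consts if consts else [0.0], dtype=np.float64))


def affinity(i: int, j: int, g: float, a: float, b: float) -> float:
    """Group-affinity weight: ``a`` if ``i`` and ``j`` are congruent mod ``g``.

    ``g`` is truncated to an integer; any ``g <= 1`` puts every node in a
    single group, so the result is ``a``.
    """
    g = int(g)
    if g <= 1:
        return a
    return a if (int(i) % g) == (int(j) % g) else b


def program_length(program: GeneratorProgram) -> int:
    """Number of nodes in the tree — the program's complexity measure."""
    return len(program)


# ---------------------------------------------------------------------------
# text format: prefix s-expressions
# ---------------------------------------------------------------------------

def _format_node(node: ProgramNode) -> str:
    if node.kind == "const":
        v = node.value
        return repr(int(v)) if float(v).is_integer() and abs(v) < 1e15 else repr(v)
    if node.kind == "var":
        return node.symbol
    inner = " ".join(_format_node(c) for c in node.children)
    return f"({node.symbol} {inner})"


_INFIX_BINARY = {"+", "-", "*", "/"}


def _infix_node(node: ProgramNode) -> str:
    if node.kind != "op":
        return _format_node(node)
    if node.symbol in _INFIX_BINARY:
        a, b = (_infix_node(c) for c in node.children)
        return f"({a} {node.symbol} {b})"
    if node.symbol == "psi":
        args = ", ".join(_infix_node(c) for c in node.children)
        return f"ψ({args})"
    if node.symbol in {"gt", "lt", "eq"}:
        cmp = {"gt": ">", "lt": "<", "eq": "="}[node.symbol]
        a, b, t, f = (_infix_node(c) for c in node.children)
        return f"[{a} {cmp} {b} ? {t} : {f}]"
    if node.symbol == "eq0":
        x, t, f = (_infix_node(c) for c in node.children)
        return f"[{x} = 0 ? {t} : {f}]"
    args = ", ".join(_infix_node(c) for c in node.children)
    return f"{node.symbol}({args})"


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in "()":
            tokens.append((ch, i))
            i += 1
        elif ch.isspace():
            i += 1
        elif ch == "#":
            while i < n and text[i] != "\n":
                i += 1
        else:
            start = i
            while i < n and not text[i].isspace() and text[i] not in "()#":
                i += 1
            tokens.append((text[start:i], start))
    return tokens


def _parse_atom(token: str, pos: int) -> ProgramNode:
    token = _ALIASES.get(token, token)
    if token in VARIABLES_DIRECTED:
        return ProgramNode.var(token)
    try:
        return ProgramNode.const(float(token))
    except ValueError:
        raise ProgramSyntaxError(f"unknown symbol {token!r}", pos) from None


def _parse_expr(tokens: list[tuple[str, int]], cursor: int) -> tuple[ProgramNode, int]:
    if cursor >= len(tokens):
        raise ProgramSyntaxError("unexpected end of input")
    token, pos = tokens[cursor]
    if token == ")":
        raise ProgramSyntaxError("unexpected ')'", pos)
    if token != "(":
        return _parse_atom(token, pos), cursor + 1
    cursor += 1
    if cursor >= len(tokens):
        raise ProgramSyntaxError("unclosed '('", pos)
    head, head_pos = tokens[cursor]
    head = _ALIASES.get(head, head)
    if head not in OPERATORS:
        raise ProgramSyntaxError(f"unknown operator {head!r}", head_pos)
    cursor += 1
    children = []
    while cursor < len(tokens) and tokens[cursor][0] != ")":
        child, cursor = _parse_expr(tokens, cursor)
        children.append(child)
    if cursor >= len(tokens):
        raise ProgramSyntaxError("unclosed '('", pos)
    cursor += 1  # consume ')'
    arity = OPERATORS[head]
    if len(children) != arity:
        raise ProgramSyntaxError(
            f"operator {head!r} takes {arity} arguments, got {len(children)}",
            head_pos,
        )
    return ProgramNode.op(head, *children), cursor


def parse(text: str, directed: bool = True) -> GeneratorProgram:
    """Parse prefix s-expression text into a validated program.

    Raises :class:`ProgramSyntaxError` for malformed text and
    :class:`ValueError` if a variable is illegal for the mode.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ProgramSyntaxError("empty program text")
    root, cursor = _parse_expr(tokens, 0)
    if cursor != len(tokens):
        raise ProgramSyntaxError("trailing tokens after expression", tokens[cursor][1])
    return GeneratorProgram(root, directed=directed)


# ---------------------------------------------------------------------------
# random creation and mutation
# ---------------------------------------------------------------------------

def _random_constant(rng: np.random.Generator) -> ProgramNode:
    # half small non-negative integers, half uniform reals in [0, 1)
    if rng.random() < 0.5:
        return ProgramNode.const(float(rng.integers(0, 10)))
    return ProgramNode.const(float(rng.uniform(0.0, 1.0)))


def _random_terminal(rng: np.random.Generator, variables: Sequence[str],
                     p_variable: float) -> ProgramNode:
    if rng.random() < p_variable:
        return ProgramNode.var(variables[rng.integers(len(variables))])
    return _random_constant(rng)


_OPERATOR_LIST = tuple(OPERATORS)


def _grow(rng: np.random.Generator, variables: Sequence[str], depth: int,
          p_terminal: float, p_variable: float) -> ProgramNode:
    if depth <= 0 or rng.random() < p_terminal:
        return _random_terminal(rng, variables, p_variable)
    sym = _OPERATOR_LIST[rng.integers(len(_OPERATOR_LIST))]
    children = tuple(
        _grow(rng, variables, depth - 1, p_terminal, p_variable)
        for _ in range(OPERATORS[sym])
    )
    return ProgramNode.op(sym, *children)


def random_program(rng: np.random.Generator, directed: bool = True,
                   max_depth: int = 5, p_terminal: float = 0.4,
                   p_variable: float = 0.6) -> GeneratorProgram:
    """Draw a random generator with grow-style tree creation.

    ``max_depth`` bounds the tree depth; at every internal position the
    draw terminates early with probability ``p_terminal``, and terminals are
    variables with probability ``p_variable`` (else random constants).
    """
    if max_depth < 0:
        raise ValueError("max_depth must be non-negative")
    variables = VARIABLES_DIRECTED if directed else VARIABLES_UNDIRECTED
    root = _grow(rng, variables, max_depth, p_terminal, p_variable)
    return GeneratorProgram(root, directed=directed)


def _replace_at(node: ProgramNode, index: int,
                subtree: ProgramNode) -> tuple[ProgramNode, int]:
    """Replace the pre-order ``index``-th node; returns (new node, consumed)."""
    if index == 0:
        return subtree, len(node)
    consumed = 1
    new_children = list(node.children)
    for pos, child in enumerate(node.children):
        size = len(child)
        if index < consumed + size:
            replaced, _ = _replace_at(child, index - consumed, subtree)
            new_children[pos] = replaced
            return ProgramNode(node.kind, node.symbol, node.value,
                               tuple(new_children)), len(node)
        consumed += size
    raise IndexError(index)  # pragma: no cover


def mutate(parent: GeneratorProgram, rng: np.random.Generator,
           max_depth: int = 5, max_size: int = 200) -> GeneratorProgram:
    """Sub-tree replacement mutation.

    A node of the parent is picked uniformly at random and replaced by a
    sub-tree picked uniformly from a freshly created random tree.  The
    parent is untouched.  ``max_size`` caps runaway growth: oversized
    children are re-drawn a few times, finally falling back to a terminal
    replacement (the anti-bloat bookkeeping handles ordinary bloat).
    """
    size = len(parent)
    for _ in range(10):
        target_index = int(rng.integers(size))
        donor = random_program(rng, directed=parent.directed, max_depth=max_depth)
        donor_nodes = list(donor.root.walk())
        sub = donor_nodes[int(rng.integers(len(donor_nodes)))]
        child = parent.replace_subtree(target_index, sub)
        if len(child) <= max_size:
            return child
    variables = VARIABLES_DIRECTED if parent.directed else VARIABLES_UNDIRECTED
    terminal = _random_terminal(rng, variables, p_variable=0.6)
    return parent.replace_subtree(int(rng.integers(size)), terminal)
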