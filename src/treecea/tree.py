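"""Decision-tree representation, validation, rollback and path enumeration.

A model holds one decision node (the strategy choice at the root) and, per
strategy, an out-tree of chance nodes ending in terminal nodes.  Branch
probabilities are expressions over named parameters: a single reference, a
product of references, or the complement ``1 - sum(siblings)``.  Terminal
payoffs are a linear combination of cost parameters (each with an optional
multiplier, e.g. two catheters) and a single utility parameter for the
effect.

Rollback computes, per strategy, the probability-weighted expected cost and
effect from the leaves up; ``enumerate_paths`` lists every root-to-leaf
path with its probability and payoffs and serves as the independent oracle
for rollback in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Union

from .params import ParameterSet

__all__ = [
    "Ref",
    "Product",
    "Complement",
    "Branch",
    "ChanceNode",
    "CostTerm",
    "TerminalNode",
    "Strategy",
    "DecisionTree",
    "StrategyOutcome",
    "Path",
    "Violation",
    "TreeValidationError",
    "validate_tree",
    "rollback",
    "enumerate_paths",
]

PROB_TOL = 1e-9


@dataclass(frozen=True)
class Ref:
    """Branch probability given by one named parameter."""

    name: str


@dataclass(frozen=True)
class Product:
    """Branch probability given by a product of named parameters."""

    names: tuple[str, ...]


@dataclass(frozen=True)
class Complement:
    """Branch probability 1 - sum of the explicit sibling branches."""


ProbExpr = Union[Ref, Product, Complement]


@dataclass(frozen=True)
class Branch:
    child: str
    prob: ProbExpr


@dataclass(frozen=True)
class ChanceNode:
    id: str
    branches: tuple[Branch, ...]


@dataclass(frozen=True)
class CostTerm:
    ref: str
    times: float = 1.0


@dataclass(frozen=True)
class TerminalNode:
    id: str
    cost: tuple[CostTerm, ...]
    effect: str  # utility parameter name


Node = Union[ChanceNode, TerminalNode]


@dataclass(frozen=True)
class Strategy:
    name: str
    root: str


@dataclass
class DecisionTree:
    strategies: list[Strategy]
    nodes: dict[str, Node] = field(default_factory=dict)

    def node(self, node_id: str) -> Node:
        return self.nodes[node_id]


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected cost (RMB) and expected effectiveness (QALY) of one strategy."""

    strategy: str
    expected_cost: float
    expected_effect: float


@dataclass(frozen=True)
class Path:
    strategy: str
    nodes: tuple[str, ...]  # node ids from root to terminal
    probability: float
    cost: float
    effect: float


@dataclass(frozen=True)
class Violation:
    code: str
    where: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.where}: {self.message}"


class TreeValidationError(ValueError):
    """Raised when evaluation is attempted on an invalid tree."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


def _expr_params(expr: ProbExpr) -> tuple[str, ...]:
    if isinstance(expr, Ref):
        return (expr.name,)
    if isinstance(expr, Product):
        return expr.names
    return ()


def _eval_expr(expr: ProbExpr, values: Mapping[str, float]) -> float:
    if isinstance(expr, Ref):
        return values[expr.name]
    if isinstance(expr, Product):
        p = 1.0
        for n in expr.names:
            p *= values[n]
        return p
    raise TypeError("complement branches are resolved at node level")


def _resolve_branch_probs(
    node: ChanceNode, values: Mapping[str, float]
) -> list[float]:
    """Resolve branch probabilities; explicit branches first, one complement last."""
    explicit_sum = 0.0
    probs: list[float | None] = []
    for b in node.branches:
        if isinstance(b.prob, Complement):
            probs.append(None)
        else:
            p = _eval_expr(b.prob, values)
            probs.append(p)
            explicit_sum += p
    return [1.0 - explicit_sum if p is None else p for p in probs]


def validate_tree(tree: DecisionTree, params: ParameterSet) -> list[Violation]:
    """Check every structural invariant at the parameter base values.

    Returns an empty list iff the tree is valid: all parameter references
    resolve, each chance node has at most one complement branch and its
    resolved probabilities lie in [0, 1] and sum to 1 within 1e-9, every
    node is reachable exactly once (out-tree, no cycles), and every leaf is
    a terminal.
    """
    out: list[Violation] = []
    values = params.base_values()

    if not tree.strategies:
        out.append(Violation("no-strategies", "tree", "no strategies defined"))
    seen_names = set()
    for s in tree.strategies:
        if s.name in seen_names:
            out.append(Violation("duplicate-strategy", s.name, "duplicate strategy name"))
        seen_names.add(s.name)
        if s.root not in tree.nodes:
            out.append(Violation("missing-node", s.name, f"root node {s.root!r} undefined"))

    # reference resolution
    for node in tree.nodes.values():
        if isinstance(node, ChanceNode):
            n_comp = sum(isinstance(b.prob, Complement) for b in node.branches)
            if n_comp > 1:
                out.append(
                    Violation(
                        "multiple-complements",
                        node.id,
                        f"{n_comp} complement branches (at most one allowed)",
                    )
                )
            if not node.branches:
                out.append(Violation("empty-chance", node.id, "chance node has no branches"))
            for b in node.branches:
                if b.child not in tree.nodes:
                    out.append(
                        Violation("missing-node", node.id, f"child {b.child!r} undefined")
                    )
                for pname in _expr_params(b.prob):
                    if pname not in params:
                        out.append(
                            Violation(
                                "unresolved-parameter",
                                node.id,
                                f"branch probability references unknown parameter {pname!r}",
                            )
                        )
        else:
            for t in node.cost:
                if t.ref not in params:
                    out.append(
                        Violation(
                            "unresolved-parameter",
                            node.id,
                            f"cost term references unknown parameter {t.ref!r}",
                        )
                    )
            if node.effect not in params:
                out.append(
                    Violation(
                        "unresolved-parameter",
                        node.id,
                        f"effect references unknown parameter {node.effect!r}",
                    )
                )
    if out:
        # Numeric checks below assume references resolve.
        return out

    # probability values and sums at base values
    for node in tree.nodes.values():
        if not isinstance(node, ChanceNode):
            continue
        probs = _resolve_branch_probs(node, values)
        for b, p in zip(node.branches, probs):
            if p < -PROB_TOL or p > 1.0 + PROB_TOL:
                out.append(
                    Violation(
                        "probability-out-of-range",
                        node.id,
                        f"branch to {b.child!r} resolves to {p!r} outside [0, 1]",
                    )
                )
        s = sum(probs)
        if abs(s - 1.0) > PROB_TOL:
            out.append(
                Violation(
                    "probability-sum",
                    node.id,
                    f"branch probabilities sum to {s!r} (must be 1 within {PROB_TOL})",
                )
            )

    # out-tree shape: each node referenced at most once, reachable from one root
    referenced: dict[str, str] = {}
    for node in tree.nodes.values():
        if isinstance(node, ChanceNode):
            for b in node.branches:
                if b.child in referenced:
                    out.append(
                        Violation(
                            "shared-subtree",
                            b.child,
                            f"node referenced by both {referenced[b.child]!r} and {node.id!r}",
                        )
                    )
                referenced[b.child] = node.id
    roots = {s.root for s in tree.strategies}
    for r in roots:
        if r in referenced:
            out.append(Violation("cycle", r, "strategy root is also a branch target"))
    # reachability / cycle detection per strategy
    for s in tree.strategies:
        stack, seen = [s.root], set()
        while stack:
            nid = stack.pop()
            if nid in seen:
                out.append(Violation("cycle", nid, f"node revisited in strategy {s.name!r}"))
                break
            seen.add(nid)
            node = tree.nodes[nid]
            if isinstance(node, ChanceNode):
                stack.extend(b.child for b in node.branches)
    reachable = set(roots)
    frontier = list(roots)
    while frontier:
        node = tree.nodes.get(frontier.pop())
        if isinstance(node, ChanceNode):
            for b in node.branches:
                if b.child not in reachable:
                    reachable.add(b.child)
                    frontier.append(b.child)
    for nid in tree.nodes:
        if nid not in reachable:
            out.append(Violation("unreachable", nid, "node not reachable from any strategy"))
    return out


def _terminal_payoff(node: TerminalNode, values: Mapping[str, float]) -> tuple[float, float]:
    cost = 0.0
    for t in node.cost:
        cost += values[t.ref] * t.times
    return cost, values[node.effect]


def _expected_value(
    tree: DecisionTree, node_id: str, values: Mapping[str, float]
) -> tuple[float, float]:
    node = tree.nodes[node_id]
    if isinstance(node, TerminalNode):
        return _terminal_payoff(node, values)
    probs = _resolve_branch_probs(node, values)
    cost = 0.0
    effect = 0.0
    for b, p in zip(node.branches, probs):
        c, e = _expected_value(tree, b.child, values)
        cost += p * c
        effect += p * e
    return cost, effect


def _check_values(tree: DecisionTree, values: Mapping[str, float]) -> None:
    bad: list[Violation] = []
    for node in tree.nodes.values():
        if not isinstance(node, ChanceNode):
            continue
        probs = _resolve_branch_probs(node, values)
        s = sum(probs)
        if abs(s - 1.0) > PROB_TOL:
            bad.append(
                Violation("probability-sum", node.id, f"branch probabilities sum to {s!r}")
            )
        for b, p in zip(node.branches, probs):
            if p < -PROB_TOL or p > 1.0 + PROB_TOL:
                bad.append(
                    Violation(
                        "probability-out-of-range",
                        node.id,
                        f"branch to {b.child!r} resolves to {p!r}",
                    )
                )
    if bad:
        raise TreeValidationError(bad)


def rollback(
    tree: DecisionTree,
    values: Mapping[str, float],
    *,
    check: bool = True,
) -> list[StrategyOutcome]:
    """Expected-value rollback: probability-weighted payoffs per strategy.

    ``values`` maps every referenced parameter name to a number (typically
    ``ParameterSet.base_values()`` or one probabilistic draw).  With
    ``check=True`` branch-probability validity is re-verified at these
    values and a TreeValidationError raised on violation.
    """
    if check:
        _check_values(tree, values)
    return [
        StrategyOutcome(s.name, *_expected_value(tree, s.root, values))
        for s in tree.strategies
    ]


def _walk_paths(
    tree: DecisionTree,
    strategy: str,
    node_id: str,
    prefix: tuple[str, ...],
    prob: float,
    values: Mapping[str, float],
) -> Iterator[Path]:
    node = tree.nodes[node_id]
    if isinstance(node, TerminalNode):
        cost, effect = _terminal_payoff(node, values)
        yield Path(strategy, prefix + (node_id,), prob, cost, effect)
        return
    probs = _resolve_branch_probs(node, values)
    for b, p in zip(node.branches, probs):
        yield from _walk_paths(tree, strategy, b.child, prefix + (node_id,), prob * p, values)


def enumerate_paths(
    tree: DecisionTree,
    values: Mapping[str, float],
    *,
    check: bool = True,
) -> list[Path]:
    """Every root-to-terminal path with probability, cost and effect.

    Within each strategy path probabilities sum to 1, and the probability-
    weighted sums of path payoffs equal the rollback output (the oracle
    identity the test-suite asserts).
    """
    if check:
        _check_values(tree, values)
    out: list[Path] = []
    for s in tree.strategies:
        out.extend(_walk_paths(tree, s.name, s.root, (), 1.0, values))
    return out
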