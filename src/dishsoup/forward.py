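"""Forward reachability: breadth-first search over the rewrite relation.

Starting from a ground dish, states are expanded in FIFO order; among
rules applicable at one state the application order is lexicographic by
rule label, and among matches of one rule the deterministic match order —
so "the first solution" is well defined and reproducible.  States are
deduplicated by canonical form, which guarantees termination on finite
state spaces (the vending machine loops forever without it).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .errors import StaleSolutionError
from .kb import KnowledgeBase
from .matching import apply_rule, match
from .substitution import Substitution
from .terms import Dish, canonicalize, is_ground

__all__ = ["SearchGoal", "SearchSolution", "forward_search", "path_labels", "graph_to_dot"]


@dataclass
class SearchGoal:
    """A goal pattern plus search parameters.

    ``min_steps`` defaults to 1 (reach the goal in at least one rewrite,
    the ``=>+`` search mode); pass 0 for the ``=>*`` mode that also accepts
    the start state.  ``conditions`` are sort-membership tests on goal
    variables, e.g. ``("prot", "ErkS")`` for a variable ``prot:BProtein``.
    """

    pattern: Dish
    conditions: tuple[tuple[str, str], ...] = ()
    max_solutions: Optional[int] = None
    max_depth: Optional[int] = None
    min_steps: int = 1


@dataclass
class SearchSolution:
    """A reached goal instance: the ground dish, bindings, and the rule path."""

    final_dish: Dish
    bindings: Substitution
    path: tuple[str, ...]
    depth: int
    start: Dish = field(repr=False, default=None)
    kb_fingerprint: str = field(repr=False, default="")
    _kb: KnowledgeBase = field(repr=False, default=None)

    def to_json(self):
        from .terms import dish_to_json

        return {
            "final_dish": dish_to_json(self.final_dish),
            "bindings": self.bindings.to_json(),
            "path": list(self.path),
            "depth": self.depth,
        }


def forward_search(
    kb: KnowledgeBase,
    start: Dish,
    goal: SearchGoal,
    graph: Optional[nx.DiGraph] = None,
) -> list[SearchSolution]:
    """Breadth-first search from ``start`` for instances of ``goal.pattern``.

    Solutions come back in nondecreasing depth, at most ``max_solutions`` of
    them, each carrying a rule-label path that replays from ``start`` to its
    final dish.  Passing a ``graph`` records the explored transition system
    (nodes are canonical dishes, edges labeled by rule).
    """
    if not is_ground(start):
        raise ValueError("forward search starts from a ground dish")
    fingerprint = kb.fingerprint()
    rules = kb.rule_list()
    solutions: list[SearchSolution] = []

    start_key = canonicalize(start)
    visited: set[str] = {start_key}
    queue: deque[tuple[Dish, int, tuple[str, ...]]] = deque([(start, 0, ())])
    if graph is not None:
        graph.add_node(start_key, start=True)

    def done() -> bool:
        return goal.max_solutions is not None and len(solutions) >= goal.max_solutions

    while queue and not done():
        dish, depth, path = queue.popleft()
        if depth >= goal.min_steps:
            bindings = match(goal.pattern, dish, kb.sorts, goal.conditions)
            if bindings:
                solutions.append(
                    SearchSolution(
                        final_dish=dish,
                        bindings=bindings[0],
                        path=path,
                        depth=depth,
                        start=start,
                        kb_fingerprint=fingerprint,
                        _kb=kb,
                    )
                )
                if done():
                    break
        if goal.max_depth is not None and depth >= goal.max_depth:
            continue
        key = canonicalize(dish)
        for rule in rules:
            for succ, _sub in apply_rule(rule, dish, kb.sorts):
                succ_key = canonicalize(succ)
                if graph is not None:
                    graph.add_edge(key, succ_key, rule=rule.label)
                if succ_key not in visited:
                    visited.add(succ_key)
                    queue.append((succ, depth + 1, path + (rule.label,)))
    return solutions


def path_labels(sol: SearchSolution) -> list[str]:
    """The rule labels applied to reach the solution, in application order.

    Replays the path against the solution's knowledge base and raises
    :class:`StaleSolutionError` if the KB changed since the search or the
    replay no longer reproduces the final dish.
    """
    kb = sol._kb
    if kb is None or sol.start is None:
        return list(sol.path)
    if kb.fingerprint() != sol.kb_fingerprint:
        raise StaleSolutionError("knowledge base changed since this solution was found")
    current = {canonicalize(sol.start): sol.start}
    for label in sol.path:
        rule = kb.rules.get(label)
        if rule is None:
            raise StaleSolutionError(f"rule {label!r} no longer exists")
        nxt: dict[str, Dish] = {}
        for d in current.values():
            for succ, _ in apply_rule(rule, d, kb.sorts):
                nxt[canonicalize(succ)] = succ
        current = nxt
    if canonicalize(sol.final_dish) not in current:
        raise StaleSolutionError("replaying the path does not reproduce the final dish")
    return list(sol.path)


def graph_to_dot(graph: nx.DiGraph) -> str:
    """Serialize an explored transition graph in Graphviz DOT."""
    lines = ["digraph dishsoup {", "  rankdir=LR;"]
    index = {node: f"n{i}" for i, node in enumerate(sorted(graph.nodes))}
    for node, nid in index.items():
        label = node.replace("\\", "\\\\").replace('"', '\\"')
        shape = "box" if graph.nodes[node].get("start") else "ellipse"
        lines.append(f'  {nid} [label="{label}", shape={shape}];')
    for u, v, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1])):
        rule = str(data.get("rule", "")).replace('"', '\\"')
        lines.append(f'  {index[u]} -> {index[v]} [label="{rule}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
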