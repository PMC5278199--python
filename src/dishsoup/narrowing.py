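"""Backward search by narrowing: inferring most-general causes of a goal.

Forward rewriting needs a ground start state; narrowing instead unifies a
rule with a *pattern*, assigning values to variables on the fly, so a
search can run backwards from a goal containing variables and return the
most general initial dishes from which the goal is reachable, together
with the binding of the goal's variables.

Narrowing requires rules that apply at the top of the whole state term.
Pathway rules touch sub-multisets of a few locations, so they are first
*topified*: every mentioned location gains a fresh shared collection
variable and the rule gains a fresh dish variable covering unmentioned
locations.  Ground rewriting with a topified rule at the top yields
exactly the same transition relation as the original rule applied below
the top.

One backward step unifies the current goal pattern with a topified rule's
RHS and emits the correspondingly instantiated LHS as the new, more
initial pattern; solutions are enumerated by nondecreasing depth, the
depth-0 identity solution (the goal already holds) first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .kb import KnowledgeBase, Rule
from .matching import match
from .sorts import SortHierarchy
from .substitution import Substitution
from .terms import (
    Complex,
    Dish,
    ElementVar,
    Entity,
    FreshNames,
    Soup,
    Term,
    canonicalize,
    dish_to_json,
    is_ground,
    vars_of,
)
from .unification import (
    UnificationProblem,
    _VAR_TOKEN,
    rename_vars,
    unify,
)

__all__ = ["BackwardSolution", "topify", "backward_search", "ground_check", "pattern_key"]


@dataclass
class BackwardSolution:
    """A proposed initial pattern from which the goal is reachable.

    Every ground instance of ``initial_pattern`` forward-reaches the
    corresponding instance of ``substitute(goal, accumulated_substitution)``
    in exactly ``depth`` steps along ``rule_path`` (labels in forward
    application order).
    """

    initial_pattern: Dish
    accumulated_substitution: Substitution
    rule_path: tuple[str, ...]
    depth: int
    goal: Dish = field(repr=False, default=None)

    def to_json(self, goal_vars: Optional[Iterable[str]] = None):
        sub = self.accumulated_substitution
        if goal_vars is not None:
            sub = sub.restrict(goal_vars)
        return {
            "initial_pattern": dish_to_json(self.initial_pattern),
            "substitution": sub.to_json(),
            "rule_path": list(self.rule_path),
            "depth": self.depth,
        }


def topify(r: Rule, kb: KnowledgeBase, fresh: Optional[FreshNames] = None) -> Rule:
    """Extend a rule so it rewrites the whole dish at the top.

    Each location the rule mentions gains one fresh collection variable,
    shared between LHS and RHS so the untouched remainder passes through;
    a fresh dish variable (likewise shared) stands for every unmentioned
    location.  Locations already carrying a collection variable, and rules
    already carrying a dish variable, are left alone, which makes the
    transform idempotent up to renaming.
    """
    fresh = fresh or FreshNames("t#")
    lhs_map = r.lhs.mapping()
    rhs_map = r.rhs.mapping()
    for tag in sorted(lhs_map):
        if lhs_map[tag].var is None:
            v = fresh.soup_var()
            lhs_map[tag] = Soup(lhs_map[tag].counts, var=v)
            if rhs_map[tag].var is None:
                rhs_map[tag] = Soup(rhs_map[tag].counts, var=v)
    lhs_var, rhs_var = r.lhs.var, r.rhs.var
    if lhs_var is None:
        lhs_var = fresh.dish_var()
        if rhs_var is None:
            rhs_var = lhs_var
    return Rule(
        label=r.label,
        lhs=Dish.of(lhs_map, var=lhs_var),
        rhs=Dish.of(rhs_map, var=rhs_var),
        conditions=r.conditions,
        source=r.source,
    )


def pattern_key(d: Dish) -> str:
    """Canonical form of a pattern with variables renamed by first appearance.

    Used to deduplicate narrowing subgoals that differ only in fresh
    variable names.  (Renaming can shuffle multiset member order, so the
    key may still distinguish some equivalent patterns; that costs
    duplicate work, never soundness.)
    """
    rendered = canonicalize(d)
    mapping: dict[str, str] = {}
    names = vars_of(d).names()
    for tok in _VAR_TOKEN.findall(rendered):
        if tok in names and tok not in mapping:
            mapping[tok] = f"p#{len(mapping) + 1}"
    return canonicalize(rename_vars(d, mapping, mapping, mapping))


def _conditions_ok(
    sub: Substitution, conditions: Iterable[tuple[str, str]], h: SortHierarchy
) -> bool:
    """Sort constraints on goal variables, checked against partial bindings.

    Unbound variables stay unconstrained (checked again once bound);
    a binding outside the sort prunes the branch.
    """
    for var, sort in conditions:
        bound = sub.element.get(var)
        if bound is None:
            continue
        if not h.member(bound, sort):
            return False
    return True


def _rename_rule(r: Rule, fresh: FreshNames) -> Rule:
    vs = vars_of(r.lhs)
    rv = vars_of(r.rhs)
    names = sorted(vs.names() | rv.names())
    mapping = {n: fresh.name() for n in names}
    return Rule(
        label=r.label,
        lhs=rename_vars(r.lhs, mapping, mapping, mapping),
        rhs=rename_vars(r.rhs, mapping, mapping, mapping),
        conditions=tuple((mapping.get(v, v), s) for v, s in r.conditions),
        source=r.source,
    )


def backward_search(
    kb: KnowledgeBase,
    goal: Dish,
    conditions: Iterable[tuple[str, str]] = (),
    max_depth: int = 3,
    max_solutions: Optional[int] = None,
    subsume: bool = False,
) -> list[BackwardSolution]:
    """Depth-bounded backward narrowing from a goal pattern.

    Solutions are enumerated by nondecreasing depth; within one depth, by
    (rule label, unifier index), so "first solution", "second solution"
    numbering is reproducible.  The depth-0 identity solution — the goal is
    reached by applying no rules — always comes first.  With ``subsume``,
    a solution whose initial pattern is an instance of an already retained
    pattern at the same or smaller depth is dropped.
    """
    conditions = tuple(conditions)
    h = kb.sorts
    fresh = FreshNames("n#")
    solutions: list[BackwardSolution] = [
        BackwardSolution(goal, Substitution(), (), 0, goal=goal)
    ]
    from collections import deque

    queue: deque[tuple[Dish, Substitution, tuple[str, ...], int]] = deque(
        [(goal, Substitution(), (), 0)]
    )
    visited: set[str] = {pattern_key(goal)}
    retained: list[Dish] = [goal]

    def full() -> bool:
        return max_solutions is not None and len(solutions) >= max_solutions

    while queue and not full():
        pattern, acc, path, depth = queue.popleft()
        if depth >= max_depth:
            continue
        for rule in kb.rule_list():
            renamed = _rename_rule(topify(rule, kb, fresh), fresh)
            for sigma in unify(UnificationProblem(pattern, renamed.rhs, h), fresh):
                if not _conditions_ok(sigma, renamed.conditions, h):
                    continue
                if not _conditions_ok(acc.compose(sigma), conditions, h):
                    continue
                new_pattern = sigma.apply_dish(renamed.lhs)
                new_acc = acc.compose(sigma)
                key = pattern_key(new_pattern)
                if key in visited:
                    continue
                visited.add(key)
                if subsume and any(
                    _pattern_instance_of(new_pattern, kept, h) for kept in retained
                ):
                    continue
                sol = BackwardSolution(
                    initial_pattern=new_pattern,
                    accumulated_substitution=new_acc,
                    rule_path=(rule.label,) + path,
                    depth=depth + 1,
                    goal=goal,
                )
                solutions.append(sol)
                retained.append(new_pattern)
                if full():
                    return solutions
                queue.append((new_pattern, new_acc, (rule.label,) + path, depth + 1))
    return solutions


def _freeze(d: Dish) -> Dish:
    """Turn a pattern's variables into rigid marker entities for instance tests."""
    vs = vars_of(d)
    emap = {n: n for n in vs.element}
    # variables become entities named frz.<name>; soup/dish variables become
    # one marker occurrence in their soup / one marker location

    def on_term(t: Term) -> Term:
        if isinstance(t, Entity):
            return t
        if isinstance(t, ElementVar):
            return Entity(f"frz.{t.name}", t.mods)
        return Complex.of(*(on_term(p) for p in t.parts))

    locations = {}
    for tag, s in d.locations:
        terms = [on_term(t) for t in s.terms()]
        if s.var is not None:
            terms.append(Entity(f"frz.{s.var}"))
        locations[tag] = Soup.of(*terms)
    if d.var is not None:
        locations[f"FrzLoc.{d.var}"] = Soup.of(Entity(f"frz.{d.var}"))
    return Dish.of(locations)


def _pattern_instance_of(specific: Dish, general: Dish, h: SortHierarchy) -> bool:
    """True iff ``specific`` is an instance of ``general``.

    Conservative: the specific pattern's variables are frozen into rigid
    markers, so variable-for-variable generalizations are only recognized
    through collection variables; a False answer never discards anything.
    """
    frozen = _freeze(specific)
    try:
        return bool(match(general, frozen, h))
    except Exception:
        return False


def _grounding_for(patterns: Iterable[Dish], kb: KnowledgeBase) -> Substitution:
    """Bind every variable to a smallest representative: collection variables to
    the empty soup/dish, element variables to the first member of their sort."""
    sub = Substitution()
    default_entity = sorted(kb.entities)[0] if kb.entities else "X"
    for p in patterns:
        vs = vars_of(p)
        for name, sort in sorted(vs.element.items()):
            if name in sub.element:
                continue
            members = sorted(kb.sorts.denotation(sort)) if sort in kb.sorts.sorts else []
            sub.element[name] = Entity(members[0] if members else default_entity)
        for name in sorted(vs.soup):
            sub.soup.setdefault(name, Soup())
        for name in sorted(vs.dish):
            sub.dish.setdefault(name, Dish())
    return sub


def ground_check(
    sol: BackwardSolution, kb: KnowledgeBase, max_states: int = 10000
) -> bool:
    """Validate a backward solution by forward replay of a ground instance.

    The initial pattern and the narrowed goal share fresh variables, so one
    grounding substitution (collection variables to empty, element
    variables to a sort representative) is applied to both; forward
    rewriting along ``sol.rule_path`` must then carry the instance of the
    initial pattern to the instance of the goal in exactly ``sol.depth``
    steps.  (A breadth-first search would not do here: it reports each
    state only at its first depth, missing cyclic paths that return to an
    already-seen state.)
    """
    from .matching import apply_rule

    goal_inst = sol.accumulated_substitution.apply_dish(sol.goal)
    grounding = _grounding_for([sol.initial_pattern, goal_inst], kb)
    start = grounding.apply_dish(sol.initial_pattern)
    target = grounding.apply_dish(goal_inst)
    if not (is_ground(start) and is_ground(target)):
        return False
    frontier = {canonicalize(start): start}
    for label in sol.rule_path:
        rule = kb.rules.get(label)
        if rule is None:
            return False
        nxt: dict[str, Dish] = {}
        for d in frontier.values():
            for succ, _ in apply_rule(rule, d, kb.sorts):
                nxt[canonicalize(succ)] = succ
            if len(nxt) > max_states:
                return False
        frontier = nxt
    return canonicalize(target) in frontier
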