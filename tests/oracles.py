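"""Independent brute-force oracles the engine implementations are checked against.

Everything here favors exhaustive enumeration over cleverness and shares no
search code with the package: matching is checked by enumerating candidate
variable assignments, unification by enumerating ground instances over a
tiny universe, and shortest paths by a plain dictionary BFS.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque

from dishsoup import (
    Dish,
    Entity,
    Soup,
    Substitution,
    canonicalize,
    match,
    vars_of,
)
from dishsoup.matching import apply_rule


def enumerate_matches(pattern: Dish, ground: Dish, hierarchy) -> set[str]:
    """All substitution keys making ``pattern`` equal ``ground``, by brute force.

    Element variables (assumed unmodified) range over every term occurring in
    the ground dish; collection and dish variables are then forced by
    multiset difference.  Returns the set of ``Substitution.key()`` strings.
    """
    pvars = vars_of(pattern)
    candidates = sorted(
        {t for _, soup in ground.locations for t in soup.terms()},
        key=lambda t: str(t),
    )
    names = sorted(pvars.element)
    found: set[str] = set()
    for combo in itertools.product(candidates, repeat=len(names)):
        sub = Substitution(element=dict(zip(names, combo)))
        # element-var sort membership must hold
        if not all(
            hierarchy.member(t, pvars.element[n]) for n, t in sub.element.items()
        ):
            continue
        ok = True
        gmap = {tag: s for tag, s in ground.locations if not s.is_empty()}
        for tag, psoup in pattern.locations:
            applied = sub.apply_soup(psoup)
            gsoup = gmap.pop(tag, Soup())
            diff = gsoup.counter() - applied.counter()
            if applied.counter() - gsoup.counter():
                ok = False  # pattern demands occurrences the state lacks
                break
            if applied.var is not None:
                sub = sub.bind_soup(applied.var, Soup.from_counter(diff))
            elif diff:
                ok = False
                break
        if not ok:
            continue
        if gmap:  # locations the pattern does not mention
            if pattern.var is None:
                continue
            sub = sub.bind_dish(pattern.var, Dish.of(gmap))
        elif pattern.var is not None:
            sub = sub.bind_dish(pattern.var, Dish())
        if canonicalize(sub.apply_dish(pattern)) == canonicalize(ground):
            found.add(sub.key())
    return found


def ground_soups(universe: list[str], max_size: int) -> list[Soup]:
    """Every multiset over ``universe`` up to ``max_size`` occurrences."""
    out = [Soup()]
    for size in range(1, max_size + 1):
        for combo in itertools.combinations_with_replacement(sorted(universe), size):
            out.append(Soup.of(*(Entity(n) for n in combo)))
    return out


def bfs_shortest_depths(kb, start: Dish, max_states: int = 2000) -> dict[str, int]:
    """Exhaustive shortest-path depths by plain BFS over canonical states."""
    depths = {canonicalize(start): 0}
    frontier = deque([start])
    while frontier:
        d = frontier.popleft()
        depth = depths[canonicalize(d)]
        for rule in kb.rule_list():
            for succ, _ in apply_rule(rule, d, kb.sorts):
                key = canonicalize(succ)
                if key not in depths:
                    depths[key] = depth + 1
                    frontier.append(succ)
                    if len(depths) > max_states:
                        raise RuntimeError("state space larger than expected")
    return depths


def goal_reach_depth(kb, start: Dish, goal_pattern: Dish, conditions=(), max_depth=5):
    """First depth at which some state matching the goal is reached, or None."""
    seen = {canonicalize(start)}
    frontier = [start]
    for depth in range(max_depth + 1):
        for d in frontier:
            if match(goal_pattern, d, kb.sorts, conditions):
                return depth
        nxt = []
        for d in frontier:
            for rule in kb.rule_list():
                for succ, _ in apply_rule(rule, d, kb.sorts):
                    key = canonicalize(succ)
                    if key not in seen:
                        seen.add(key)
                        nxt.append(succ)
        frontier = nxt
        if not frontier:
            return None
    return None
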