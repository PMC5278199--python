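"""AC matching of dish patterns against ground dishes, and rule application.

Soups are associative-commutative with identity, so matching a pattern
soup against a ground soup is multiset matching: ground pattern members
consume equal ground occurrences, sorted element variables try each
candidate occurrence (checking sort membership), and the optional
collection variable absorbs whatever is left.  Forward rule application
matches the rule's LHS *below the top*: the LHS soup must be a sub-multiset
of the state's soup at each mentioned location, the untouched remainder and
unmentioned locations passing through unchanged.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional

from .errors import RestrictionViolation
from .kb import Rule
from .sorts import SortHierarchy
from .substitution import Substitution, merge_soups
from .terms import (
    Complex,
    Dish,
    ElementVar,
    Entity,
    Soup,
    Term,
    canonicalize,
    is_ground,
    render_term,
)

__all__ = ["match", "match_soup", "apply_rule"]


def _match_term(
    pt: Term, gt: Term, h: SortHierarchy, subst: Substitution
) -> list[Substitution]:
    pt = subst.apply_term(pt)
    if isinstance(pt, Entity):
        return [subst] if pt == gt else []
    if isinstance(pt, ElementVar):
        if not h.member(gt, pt.sort):
            return []
        if isinstance(gt, Entity):
            if not pt.mods <= gt.mods:
                return []
            base: Term = Entity(gt.name, gt.mods - pt.mods)
        else:  # complex: only a plain variable of a sort admitting it (Things)
            if pt.mods:
                return []
            base = gt
        return [subst.bind_element(pt.name, base)]
    if isinstance(pt, Complex):
        if not isinstance(gt, Complex) or len(pt.parts) != len(gt.parts):
            return []
        out, _rem = [], None
        results = _match_multiset(list(pt.parts), gt.counter(), h, subst)
        for s, rem in results:
            if not rem:
                out.append(s)
        return _dedup(out)
    raise TypeError(f"not a term: {pt!r}")


def _match_multiset(
    pterms: list[Term], ground: Counter, h: SortHierarchy, subst: Substitution
) -> list[tuple[Substitution, Counter]]:
    """All ways of consuming one ground occurrence per pattern term.

    Returns (substitution, remaining occurrences) pairs.  Ground pattern
    terms are consumed first (cheap count checks); variable-containing
    terms then try each distinct remaining occurrence in canonical order.
    """
    ground = Counter(ground)
    pending: list[Term] = []
    for t in pterms:
        t = subst.apply_term(t)
        if is_ground(t):
            if ground[t] > 0:
                ground[t] -= 1
            else:
                return []
        else:
            pending.append(t)
    pending.sort(key=render_term)
    if not pending:
        return [(subst, +ground)]
    results: list[tuple[Substitution, Counter]] = []
    t = pending[0]
    for g in sorted((g for g, n in ground.items() if n > 0), key=render_term):
        for s in _match_term(t, g, h, subst):
            reduced = Counter(ground)
            reduced[g] -= 1
            results.extend(_match_multiset(pending[1:], reduced, h, s))
    return results


def match_soup(
    p: Soup,
    g: Soup,
    h: SortHierarchy,
    subst: Optional[Substitution] = None,
    allow_remainder: bool = False,
) -> list[tuple[Substitution, Counter]]:
    """Match a pattern soup against a ground soup.

    With ``allow_remainder`` the unconsumed ground occurrences are returned
    alongside each substitution (sub-multiset matching, used by rule
    application); otherwise the pattern's collection variable, if any, must
    absorb the remainder exactly.
    """
    if g.var is not None:
        raise ValueError("target soup must be ground")
    subst = subst or Substitution()
    out: list[tuple[Substitution, Counter]] = []
    for s, rem in _match_multiset(list(p.terms()), g.counter(), h, subst):
        if p.var is not None:
            rem_soup = Soup.from_counter(rem)
            if p.var in s.soup:
                if s.soup[p.var] != rem_soup:
                    continue
            else:
                s = s.bind_soup(p.var, rem_soup)
            out.append((s, Counter()))
        elif rem and not allow_remainder:
            continue
        else:
            out.append((s, rem))
    return _dedup_pairs(out)


def _dedup(subs: Iterable[Substitution]) -> list[Substitution]:
    seen: dict[str, Substitution] = {}
    for s in subs:
        seen.setdefault(s.key(), s)
    return [seen[k] for k in sorted(seen)]


def _dedup_pairs(
    pairs: Iterable[tuple[Substitution, Counter]]
) -> list[tuple[Substitution, Counter]]:
    seen: dict[str, tuple[Substitution, Counter]] = {}
    for s, rem in pairs:
        key = s.key() + " // " + Soup.from_counter(rem).render()
        seen.setdefault(key, (s, rem))
    return [seen[k] for k in sorted(seen)]


def _check_conditions(
    subst: Substitution, conditions: Iterable[tuple[str, str]], h: SortHierarchy
) -> bool:
    """Sort-membership conditions on bound variables; unbound tests fail closed."""
    for var, sort in conditions:
        bound = subst.element.get(var)
        if bound is None or not h.member(bound, sort):
            return False
    return True


def match(
    p: Dish,
    d: Dish,
    h: SortHierarchy,
    conditions: Iterable[tuple[str, str]] = (),
) -> list[Substitution]:
    """All substitutions making pattern dish ``p`` canonically equal to ground ``d``.

    The result is duplicate-free and deterministically ordered; an empty
    list means no match.  A location absent from a dish reads as the empty
    soup, and a dish-level variable on ``p`` absorbs the locations of ``d``
    that ``p`` does not mention.
    """
    if not is_ground(d):
        raise ValueError("match target must be a ground dish")
    d_map = {tag: soup for tag, soup in d.locations if not soup.is_empty()}
    p_tags = set(p.tags())
    extra = {tag: soup for tag, soup in d_map.items() if tag not in p_tags}
    if extra and p.var is None:
        return []

    partial: list[Substitution] = [Substitution()]
    for tag, psoup in p.locations:
        gsoup = d_map.get(tag, Soup())
        nxt: list[Substitution] = []
        for s in partial:
            psoup_applied = s.apply_soup(psoup)
            if psoup_applied.var is not None and psoup_applied.var != psoup.var:
                raise RestrictionViolation("substitution introduced a second soup variable")
            for s2, _rem in match_soup(psoup_applied, gsoup, h, s, allow_remainder=False):
                nxt.append(s2)
        partial = nxt
        if not partial:
            return []
    out = []
    for s in partial:
        if p.var is not None:
            rest = Dish.of(extra)
            if p.var in s.dish:
                if canonicalize(s.dish[p.var]) != canonicalize(rest):
                    continue
            else:
                s = s.bind_dish(p.var, rest)
        if _check_conditions(s, conditions, h):
            out.append(s)
    return _dedup(out)


def apply_rule(
    r: Rule, d: Dish, h: SortHierarchy
) -> list[tuple[Dish, Substitution]]:
    """All one-step successors of ground dish ``d`` under rule ``r``.

    One successor per distinct match of the LHS (as a sub-multiset at each
    mentioned location), built by replacing the matched part with the
    substituted RHS; deterministic order, empty list when the rule does not
    apply.
    """
    if not is_ground(d):
        raise ValueError("rule application needs a ground dish")
    d_map = d.mapping()
    # (substitution, per-tag remainder) pairs, threaded across locations
    partial: list[tuple[Substitution, dict[str, Counter]]] = [(Substitution(), {})]
    for tag, psoup in r.lhs.locations:
        gsoup = d_map.get(tag, Soup())
        nxt = []
        for s, rems in partial:
            for s2, rem in match_soup(s.apply_soup(psoup), gsoup, h, s, allow_remainder=True):
                nxt.append((s2, {**rems, tag: rem}))
        partial = nxt
        if not partial:
            return []

    lhs_tags = set(r.lhs.tags())
    out: list[tuple[str, Dish, Substitution]] = []
    for s, rems in partial:
        if not _check_conditions(s, r.conditions, h):
            continue
        new_locations = {tag: soup for tag, soup in d_map.items() if tag not in lhs_tags}
        ok = True
        for tag, _ in r.rhs.locations:
            produced = s.apply_soup(r.rhs.soup(tag))
            if produced.var is not None:
                ok = False  # un-instantiated collection variable: not a ground successor
                break
            new_locations[tag] = merge_soups(produced, Soup.from_counter(rems[tag]))
        if not ok:
            continue
        succ = Dish.of({t: sp for t, sp in new_locations.items() if not sp.is_empty()})
        if not is_ground(succ):
            continue
        out.append((s.key(), succ, s))
    seen: dict[str, tuple[Dish, Substitution]] = {}
    for key, succ, s in out:
        seen.setdefault(canonicalize(succ) + " // " + key, (succ, s))
    return [seen[k] for k in sorted(seen)]
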