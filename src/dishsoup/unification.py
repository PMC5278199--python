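"""Unification of dish patterns modulo the multiset axioms.

Both sides may contain variables; a unifier makes them canonically equal.
The supported fragment mirrors the shape of pathway rules: sorted
first-order element variables (syntactic unification with sort meets), at
most one collection variable per soup per side, and at most one dish
variable per side.  Collection variables are solved by cancelling shared
occurrences and enumerating the finitely many assignments of the surplus,
introducing one fresh shared-remainder variable when both sides carry a
collection variable — which keeps the unifier set finite and complete for
this fragment.  When two element variables meet on incomparable sorts, the
finitely many shared members of the KB vocabulary are enumerated instead
of inventing intersection sorts.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import RestrictionViolation
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
    is_ground,
    render_term,
    vars_of,
)

__all__ = ["UnificationProblem", "unify", "rename_apart", "rename_vars"]


@dataclass
class UnificationProblem:
    left: Dish
    right: Dish
    hierarchy: SortHierarchy


# ---------------------------------------------------------------------------
# variable renaming


def rename_vars(x, element: dict[str, str], soup: dict[str, str], dish: dict[str, str]):
    """Structurally rename variables (name -> name) in a term, soup or dish."""

    def on_term(t: Term) -> Term:
        if isinstance(t, Entity):
            return t
        if isinstance(t, ElementVar):
            return ElementVar(element.get(t.name, t.name), t.sort, t.mods)
        return Complex.of(*(on_term(p) for p in t.parts))

    def on_soup(s: Soup) -> Soup:
        c: Counter = Counter()
        for t, n in s.counts:
            c[on_term(t)] += n
        var = soup.get(s.var, s.var) if s.var is not None else None
        return Soup.from_counter(c, var=var)

    if isinstance(x, Dish):
        return Dish.of(
            {tag: on_soup(s) for tag, s in x.locations},
            var=dish.get(x.var, x.var) if x.var is not None else None,
        )
    if isinstance(x, Soup):
        return on_soup(x)
    return on_term(x)


def rename_apart(x, fresh: FreshNames):
    """Rename every variable in ``x`` to a fresh name; returns (renamed, maps)."""
    vs = vars_of(x)
    emap = {n: fresh.name() for n in sorted(vs.element)}
    smap = {n: fresh.name() for n in sorted(vs.soup)}
    dmap = {n: fresh.name() for n in sorted(vs.dish)}
    return rename_vars(x, emap, smap, dmap), (emap, smap, dmap)


# ---------------------------------------------------------------------------
# term unification


def _unify_terms(
    t1: Term, t2: Term, h: SortHierarchy, subst: Substitution, fresh: FreshNames
) -> list[Substitution]:
    t1 = subst.apply_term(t1)
    t2 = subst.apply_term(t2)
    if t1 == t2:
        return [subst]
    if isinstance(t1, ElementVar):
        return _bind_var(t1, t2, h, subst, fresh)
    if isinstance(t2, ElementVar):
        return _bind_var(t2, t1, h, subst, fresh)
    if isinstance(t1, Entity) or isinstance(t2, Entity):
        return []  # distinct entities, or entity vs complex
    # complex vs complex: AC unification of equal-size component multisets
    if len(t1.parts) != len(t2.parts):
        return []
    return _unify_part_multisets(list(t1.parts), list(t2.parts), h, subst, fresh)


def _unify_part_multisets(
    left: list[Term],
    right: list[Term],
    h: SortHierarchy,
    subst: Substitution,
    fresh: FreshNames,
) -> list[Substitution]:
    if not left:
        return [subst] if not right else []
    left = sorted((subst.apply_term(t) for t in left), key=render_term)
    right = sorted((subst.apply_term(t) for t in right), key=render_term)
    t = left[0]
    out: list[Substitution] = []
    tried: set[str] = set()
    for j, u in enumerate(right):
        key = render_term(u)
        if key in tried:
            continue
        tried.add(key)
        for s in _unify_terms(t, u, h, subst, fresh):
            out.extend(
                _unify_part_multisets(left[1:], right[:j] + right[j + 1 :], h, s, fresh)
            )
    return out


def _bind_var(
    v: ElementVar, t: Term, h: SortHierarchy, subst: Substitution, fresh: FreshNames
) -> list[Substitution]:
    """Unify variable occurrence ``[v.name:v.sort - v.mods]`` with term ``t``."""
    if isinstance(t, Entity):
        if not v.mods <= t.mods or not h.member(t, v.sort):
            return []
        return [subst.bind_element(v.name, Entity(t.name, t.mods - v.mods))]
    if isinstance(t, Complex):
        if v.mods or v.name in vars_of(t).element or not h.member(t, v.sort):
            return []
        return [subst.bind_element(v.name, t)]
    assert isinstance(t, ElementVar)
    if v.name == t.name:
        if v.mods == t.mods:
            return [subst]
        # [x - M1] == [x - M2] forces the symmetric difference onto x's base
        delta = (v.mods | t.mods) - (v.mods & t.mods)
        z = fresh.element_var(v.sort)
        return [subst.bind_element(v.name, ElementVar(z.name, v.sort, frozenset(delta)))]
    # two distinct variables: bases must coincide on the sort meet, each side
    # re-adding the modifications the other lists and it does not
    extra_v = t.mods - v.mods
    extra_t = v.mods - t.mods
    meet = h.meet(v.sort, t.sort)
    if meet is not None:
        z = fresh.element_var(meet)
        out = subst
        out = out.bind_element(v.name, ElementVar(z.name, meet, frozenset(extra_v)))
        out = out.bind_element(t.name, ElementVar(z.name, meet, frozenset(extra_t)))
        return [out]
    shared = sorted(h.denotation(v.sort) & h.denotation(t.sort))
    results = []
    for name in shared:
        out = subst
        out = out.bind_element(v.name, Entity(name, frozenset(extra_v)))
        out = out.bind_element(t.name, Entity(name, frozenset(extra_t)))
        results.append(out)
    return results


# ---------------------------------------------------------------------------
# soup unification


def _unify_soups(
    s1: Soup, s2: Soup, h: SortHierarchy, subst: Substitution, fresh: FreshNames
) -> list[Substitution]:
    s1 = subst.apply_soup(s1)
    s2 = subst.apply_soup(s2)
    if s1.var is not None and s1.var == s2.var:
        raise RestrictionViolation(
            "the two sides share a collection variable; rename apart first"
        )
    results: list[Substitution] = []

    def finalize(subst: Substitution, into_l: Counter, into_r: Counter) -> None:
        # into_l: occurrences from the right absorbed by s1's collection var, etc.
        if s1.var is not None and s2.var is not None:
            z = fresh.soup_var()
            results.append(
                subst.bind_soup(s1.var, Soup.from_counter(into_l, var=z)).bind_soup(
                    s2.var, Soup.from_counter(into_r, var=z)
                )
            )
        elif s1.var is not None:
            results.append(subst.bind_soup(s1.var, Soup.from_counter(into_l)))
        elif s2.var is not None:
            results.append(subst.bind_soup(s2.var, Soup.from_counter(into_r)))
        else:
            results.append(subst)

    def go(lc: Counter, rc: Counter, subst: Substitution, into_l: Counter, into_r: Counter):
        lc = Counter({subst.apply_term(t): n for t, n in lc.items()})
        rc = Counter({subst.apply_term(t): n for t, n in rc.items()})
        common = lc & rc  # syntactically equal occurrences cancel
        lc -= common
        rc -= common
        if lc:
            t = min(lc, key=render_term)
            lc2 = Counter(lc)
            lc2[t] -= 1
            for u in sorted((u for u, n in rc.items() if n > 0), key=render_term):
                for s in _unify_terms(t, u, h, subst, fresh):
                    rc2 = Counter(rc)
                    rc2[u] -= 1
                    go(lc2, rc2, s, into_l, into_r)
            if s2.var is not None:
                into_r2 = Counter(into_r)
                into_r2[t] += 1
                go(lc2, rc, subst, into_l, into_r2)
            return
        if rc:
            if s1.var is None:
                return
            t = min(rc, key=render_term)
            rc2 = Counter(rc)
            rc2[t] -= 1
            into_l2 = Counter(into_l)
            into_l2[t] += 1
            go(lc, rc2, subst, into_l2, into_r)
            return
        finalize(subst, +into_l, +into_r)

    go(s1.counter(), s2.counter(), subst, Counter(), Counter())
    return results


# ---------------------------------------------------------------------------
# dish unification


def _unify_empty(
    s: Soup, h: SortHierarchy, subst: Substitution
) -> list[Substitution]:
    """Unify a soup pattern with the empty soup (an absent location)."""
    s = subst.apply_soup(s)
    if s.counts:
        return []  # each fixed member denotes exactly one occurrence
    if s.var is not None:
        return [subst.bind_soup(s.var, Soup())]
    return [subst]


def unify(problem: UnificationProblem, fresh: Optional[FreshNames] = None) -> list[Substitution]:
    """A finite, duplicate-free, complete set of unifiers for the fragment.

    Every common ground instance of ``left`` and ``right`` is an instance of
    some returned unifier, and each returned substitution makes the two
    sides canonically equal.  The sides must not share variable names.
    """
    left, right, h = problem.left, problem.right, problem.hierarchy
    overlap = vars_of(left).names() & vars_of(right).names()
    if overlap:
        raise RestrictionViolation(
            f"left and right share variables {sorted(overlap)}; rename apart first"
        )
    fresh = fresh or FreshNames("u#")

    lmap = {tag: s for tag, s in left.locations if not s.is_empty()}
    rmap = {tag: s for tag, s in right.locations if not s.is_empty()}
    common = sorted(set(lmap) & set(rmap))
    lonly = sorted(set(lmap) - set(rmap))
    ronly = sorted(set(rmap) - set(lmap))

    partial: list[Substitution] = [Substitution()]
    for tag in common:
        partial = [
            s2 for s in partial for s2 in _unify_soups(lmap[tag], rmap[tag], h, s, fresh)
        ]
        if not partial:
            return []
    # locations present on one side only are absorbed by the other side's
    # dish variable, or must unify with the empty soup
    if right.var is None:
        for tag in lonly:
            partial = [s2 for s in partial for s2 in _unify_empty(lmap[tag], h, s)]
            if not partial:
                return []
    if left.var is None:
        for tag in ronly:
            partial = [s2 for s in partial for s2 in _unify_empty(rmap[tag], h, s)]
            if not partial:
                return []

    out: list[Substitution] = []
    for s in partial:
        if left.var is not None and right.var is not None:
            z = fresh.dish_var()
            s = s.bind_dish(
                left.var, Dish.of({tag: s.apply_soup(rmap[tag]) for tag in ronly}, var=z)
            )
            s = s.bind_dish(
                right.var, Dish.of({tag: s.apply_soup(lmap[tag]) for tag in lonly}, var=z)
            )
        elif left.var is not None:
            s = s.bind_dish(left.var, Dish.of({tag: s.apply_soup(rmap[tag]) for tag in ronly}))
        elif right.var is not None:
            s = s.bind_dish(right.var, Dish.of({tag: s.apply_soup(lmap[tag]) for tag in lonly}))
        out.append(s)

    protected = vars_of(left).names() | vars_of(right).names()
    seen: dict[str, Substitution] = {}
    for s in out:
        s = _normalize_fresh(s, protected)
        seen.setdefault(s.key(), s)
    return [seen[k] for k in sorted(seen)]


_VAR_TOKEN = re.compile(r"[A-Za-z_][A-Za-z0-9_.'#]*(?=:[A-Za-z_][A-Za-z0-9_.'#]*)")


def _normalize_fresh(s: Substitution, protected: set[str]) -> Substitution:
    """Rename the fresh variables a unifier introduced to a canonical sequence.

    Two unifiers that differ only in the fresh names drawn from the shared
    counter then serialize identically and deduplicate.
    """
    order: list[str] = []
    seen: set[str] = set(protected)
    for kind in ("element", "soup", "dish"):
        bindings = getattr(s, kind)
        for name in sorted(bindings):
            value = bindings[name]
            rendered = value.render() if hasattr(value, "render") else render_term(value)
            for v in _VAR_TOKEN.findall(rendered):
                if v not in seen:
                    seen.add(v)
                    order.append(v)
            if name not in protected and name not in seen:
                seen.add(name)
                order.append(name)
    if not order:
        return s
    mapping: dict[str, str] = {}
    i = 0
    for v in order:
        i += 1
        candidate = f"z#{i}"
        while candidate in protected:
            i += 1
            candidate = f"z#{i}"
        mapping[v] = candidate
    out = Substitution()
    out.element = {
        mapping.get(n, n): rename_vars(t, mapping, mapping, mapping)
        for n, t in s.element.items()
    }
    out.soup = {
        mapping.get(n, n): rename_vars(sp, mapping, mapping, mapping)
        for n, sp in s.soup.items()
    }
    out.dish = {
        mapping.get(n, n): rename_vars(d, mapping, mapping, mapping)
        for n, d in s.dish.items()
    }
    return out
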