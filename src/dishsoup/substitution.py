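"""Substitutions: finite maps from variables to terms, soups or location maps.

Bindings are split by kind, mirroring the disjoint variable namespaces:
element variables bind terms, soup (collection) variables bind soups, and
dish variables bind dishes (location maps with an optional further dish
variable).  Application is simultaneous; composition applies the later
substitution to the earlier one's bindings, which keeps results idempotent
as long as fresh variables never recur — the renaming discipline the
narrowing engine enforces.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .errors import RestrictionViolation, SortViolation
from .terms import (
    Complex,
    Dish,
    ElementVar,
    Entity,
    Soup,
    Term,
    dish_from_json,
    dish_to_json,
    render_term,
    soup_from_json,
    soup_to_json,
    term_from_json,
    term_to_json,
)

__all__ = ["Substitution", "substitute", "merge_soups"]


def merge_soups(a: Soup, b: Soup) -> Soup:
    """Multiset union of two soups; at most one may carry a collection variable."""
    if a.var is not None and b.var is not None and a.var != b.var:
        raise RestrictionViolation("soup union would carry two collection variables")
    return Soup.from_counter(a.counter() + b.counter(), var=a.var or b.var)


@dataclass
class Substitution:
    element: dict[str, Term] = field(default_factory=dict)
    soup: dict[str, Soup] = field(default_factory=dict)
    dish: dict[str, Dish] = field(default_factory=dict)

    # -- construction -------------------------------------------------------

    def copy(self) -> "Substitution":
        return Substitution(dict(self.element), dict(self.soup), dict(self.dish))

    def is_identity(self) -> bool:
        return not (self.element or self.soup or self.dish)

    def bind_element(self, name: str, t: Term) -> "Substitution":
        out = self.copy()
        out.element[name] = t
        return out

    def bind_soup(self, name: str, s: Soup) -> "Substitution":
        out = self.copy()
        out.soup[name] = s
        return out

    def bind_dish(self, name: str, d: Dish) -> "Substitution":
        out = self.copy()
        out.dish[name] = d
        return out

    # -- application --------------------------------------------------------

    def apply_term(self, t: Term) -> Term:
        if isinstance(t, Entity):
            return t
        if isinstance(t, ElementVar):
            b = self.element.get(t.name)
            if b is None:
                return t
            if not t.mods:
                return b
            if isinstance(b, Entity):
                return b.with_mods(t.mods)
            if isinstance(b, ElementVar):
                return ElementVar(b.name, b.sort, b.mods | t.mods)
            raise SortViolation(
                f"cannot attach modifications {sorted(map(str, t.mods))} to complex "
                f"binding of variable {t.name!r}"
            )
        if isinstance(t, Complex):
            return Complex.of(*(self.apply_term(p) for p in t.parts))
        raise TypeError(f"not a term: {t!r}")

    def apply_soup(self, s: Soup) -> Soup:
        c: Counter = Counter()
        for t, n in s.counts:
            c[self.apply_term(t)] += n
        var = s.var
        if var is not None and var in self.soup:
            bound = self.soup[var]
            c += bound.counter()
            var = bound.var
        return Soup.from_counter(c, var=var)

    def apply_dish(self, d: Dish) -> Dish:
        locations = {tag: self.apply_soup(s) for tag, s in d.locations}
        var = d.var
        if var is not None and var in self.dish:
            bound = self.dish[var]
            for tag, s in bound.locations:
                s = self.apply_soup(s)
                locations[tag] = merge_soups(locations[tag], s) if tag in locations else s
            var = bound.var
        return Dish.of(locations, var=var)

    def apply(self, x: Union[Dish, Soup, Term]):
        if isinstance(x, Dish):
            return self.apply_dish(x)
        if isinstance(x, Soup):
            return self.apply_soup(x)
        return self.apply_term(x)

    # -- algebra -------------------------------------------------------------

    def compose(self, later: "Substitution") -> "Substitution":
        """The substitution mapping x to later(self(x)).

        Bindings of ``later`` on variables untouched by ``self`` are kept, so
        applying the composite equals applying ``self`` then ``later``.
        """
        out = Substitution()
        out.element = {n: later.apply_term(t) for n, t in self.element.items()}
        out.soup = {n: later.apply_soup(s) for n, s in self.soup.items()}
        out.dish = {n: later.apply_dish(d) for n, d in self.dish.items()}
        for n, t in later.element.items():
            out.element.setdefault(n, t)
        for n, s in later.soup.items():
            out.soup.setdefault(n, s)
        for n, d in later.dish.items():
            out.dish.setdefault(n, d)
        return out

    def restrict(self, names: Iterable[str]) -> "Substitution":
        keep = set(names)
        return Substitution(
            {n: t for n, t in self.element.items() if n in keep},
            {n: s for n, s in self.soup.items() if n in keep},
            {n: d for n, d in self.dish.items() if n in keep},
        )

    # -- interchange ---------------------------------------------------------

    def to_json(self):
        return {
            "element": {n: term_to_json(t) for n, t in sorted(self.element.items())},
            "soup": {n: soup_to_json(s) for n, s in sorted(self.soup.items())},
            "dish": {n: dish_to_json(d) for n, d in sorted(self.dish.items())},
        }

    @staticmethod
    def from_json(obj) -> "Substitution":
        return Substitution(
            {n: term_from_json(t) for n, t in obj.get("element", {}).items()},
            {n: soup_from_json(s) for n, s in obj.get("soup", {}).items()},
            {n: dish_from_json(d) for n, d in obj.get("dish", {}).items()},
        )

    def key(self) -> str:
        """Deterministic serialization used for ordering and deduplication."""
        parts = []
        for n, t in sorted(self.element.items()):
            parts.append(f"e {n}={render_term(t)}")
        for n, s in sorted(self.soup.items()):
            parts.append(f"s {n}={s.render()}")
        for n, d in sorted(self.dish.items()):
            parts.append(f"d {n}={d.render()}")
        return "; ".join(parts)


def _check_sorts(x: Union[Dish, Soup, Term], sub: Substitution, hierarchy) -> None:
    from .terms import vars_of

    for name, sort in vars_of(x).element.items():
        if name in sub.element:
            bound = sub.element[name]
            if isinstance(bound, ElementVar):
                ok = hierarchy.sort_leq(bound.sort, sort)
            else:
                ok = hierarchy.member(bound, sort)
            if not ok:
                raise SortViolation(
                    f"variable {name}:{sort} cannot be bound to {render_term(bound)}"
                )


def substitute(x: Union[Dish, Soup, Term], sub: Substitution, hierarchy=None):
    """Apply ``sub`` to a dish, soup or term; all occurrences replaced at once.

    When a sort ``hierarchy`` is supplied, every binding of an element
    variable is checked against the variable's declared sort and a
    :class:`~dishsoup.errors.SortViolation` is raised on a mismatch.
    """
    if hierarchy is not None:
        _check_sorts(x, sub, hierarchy)
    return sub.apply(x)
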