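"""The term algebra: entities, modifications, complexes, soups, dishes, variables.

A *dish* is the global state of the modeled cell: a mapping from location
tags (XOut, CLm, NUc, ...) to *soups*, unordered multisets of molecular
terms.  A term is a basic entity (``Egf``), an entity carrying a set of
modifications (``[EgfR - Yphos]``), a complex of bound terms
(``[EgfR - Yphos] : Egf``), or a sorted element variable (``gab:GabS``).
Soups may additionally hold one collection variable (sort ``Things``)
standing for "the rest of the soup", and a dish may hold one dish-level
variable standing for further unnamed locations; a dish with any variable
is a *pattern* rather than a concrete state.

Binding (``:``) and soup union are associative-commutative with identity
``none``: equality of soups and complexes ignores order and grouping.  The
module therefore defines a canonical string form — the single source of
truth for equality, hashing and search-state deduplication.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Union

from .errors import ParseError, RestrictionViolation

__all__ = [
    "Modification",
    "Entity",
    "Complex",
    "ElementVar",
    "Term",
    "Soup",
    "Dish",
    "VarSet",
    "FreshNames",
    "THINGS_SORT",
    "DISH_SORT",
    "EMPTY_DISH_SENTINEL",
    "canonicalize",
    "render_term",
    "is_ground",
    "vars_of",
    "parse_dish",
    "term_to_json",
    "term_from_json",
    "soup_to_json",
    "soup_from_json",
    "dish_to_json",
    "dish_from_json",
]

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_.'#]*")

#: Reserved sort of soup (collection) variables: every term is a Thing.
THINGS_SORT = "Things"
#: Pseudo-sort used to annotate dish-level variables in the textual form.
DISH_SORT = "Dishes"
#: Canonical form of the dish with no locations and no variable.
EMPTY_DISH_SENTINEL = "{}"


def _check_ident(name: str, what: str) -> None:
    if not name or not _IDENT_RE.fullmatch(name):
        raise ValueError(f"{what} must be a nonempty identifier, got {name!r}")


@dataclass(frozen=True, order=True)
class Modification:
    """A state marker on a protein, e.g. ``Yphos`` or ``phos(TEY)``."""

    name: str
    arg: Optional[str] = None

    def __post_init__(self) -> None:
        _check_ident(self.name, "modification name")
        if self.arg is not None:
            _check_ident(self.arg, "modification argument")

    def __str__(self) -> str:
        return self.name if self.arg is None else f"{self.name}({self.arg})"


@dataclass(frozen=True)
class Entity:
    """A basic or modified molecular entity.

    ``mods`` has set semantics: adding a modification twice is the same as
    adding it once (``[EgfR - Yphos]`` denotes a state, not a count).
    """

    name: str
    mods: frozenset[Modification] = frozenset()

    def __post_init__(self) -> None:
        _check_ident(self.name, "entity name")
        object.__setattr__(self, "mods", frozenset(self.mods))

    def with_mods(self, extra: Iterable[Modification]) -> "Entity":
        return Entity(self.name, self.mods | frozenset(extra))


@dataclass(frozen=True)
class ElementVar:
    """A sorted first-order variable, optionally carrying modifications.

    ``[gab:GabS - Yphos]`` denotes *some* member of sort GabS in the
    tyrosine-phosphorylated state; the binding of ``gab`` is the member
    with the Yphos marker stripped, so substitution re-adds ``mods``.
    """

    name: str
    sort: str
    mods: frozenset[Modification] = frozenset()

    def __post_init__(self) -> None:
        _check_ident(self.name, "variable name")
        _check_ident(self.sort, "sort name")
        object.__setattr__(self, "mods", frozenset(self.mods))


@dataclass(frozen=True)
class Complex:
    """An association of bound terms, e.g. ``[EgfR - Yphos] : Egf``.

    Binding is associative-commutative, so components form a flat multiset
    (complexes of complexes are flattened) with at least two members.
    """

    parts: tuple["Term", ...]

    @staticmethod
    def of(*parts: "Term") -> "Complex":
        flat: list[Term] = []
        for p in parts:
            if isinstance(p, Complex):
                flat.extend(p.parts)
            else:
                flat.append(p)
        if len(flat) < 2:
            raise ValueError("a complex needs at least two components")
        flat.sort(key=render_term)
        return Complex(tuple(flat))

    def counter(self) -> Counter:
        return Counter(self.parts)

    def __post_init__(self) -> None:
        for p in self.parts:
            if isinstance(p, Complex):
                raise ValueError("complexes must be flattened; use Complex.of")


Term = Union[Entity, ElementVar, Complex]


def _render_mods(mods: frozenset[Modification]) -> str:
    return " ".join(str(m) for m in sorted(mods))


def render_term(t: Term) -> str:
    """Canonical textual form of a term."""
    if isinstance(t, Entity):
        if t.mods:
            return f"[{t.name} - {_render_mods(t.mods)}]"
        return t.name
    if isinstance(t, ElementVar):
        base = f"{t.name}:{t.sort}"
        if t.mods:
            return f"[{base} - {_render_mods(t.mods)}]"
        return base
    if isinstance(t, Complex):
        return " : ".join(render_term(p) for p in t.parts)
    raise TypeError(f"not a term: {t!r}")


@dataclass(frozen=True)
class Soup:
    """An unordered multiset of terms, plus at most one collection variable.

    Internally a sorted tuple of ``(term, count)`` pairs keyed by the
    canonical string of the member, so equality, hashing and iteration are
    order-free and deterministic.
    """

    counts: tuple[tuple[Term, int], ...] = ()
    var: Optional[str] = None

    @staticmethod
    def of(*terms: Term, var: Optional[str] = None) -> "Soup":
        return Soup.from_counter(Counter(terms), var=var)

    @staticmethod
    def from_counter(c: Mapping[Term, int], var: Optional[str] = None) -> "Soup":
        items = [(t, n) for t, n in c.items() if n > 0]
        items.sort(key=lambda tn: render_term(tn[0]))
        if var is not None:
            _check_ident(var, "soup variable name")
        return Soup(tuple(items), var)

    def counter(self) -> Counter:
        return Counter(dict(self.counts))

    def terms(self) -> Iterator[Term]:
        """Yield members with multiplicity, in canonical order."""
        for t, n in self.counts:
            for _ in range(n):
                yield t

    @property
    def size(self) -> int:
        return sum(n for _, n in self.counts)

    def is_empty(self) -> bool:
        return not self.counts and self.var is None

    def render(self) -> str:
        parts = [render_term(t) for t in self.terms()]
        if self.var is not None:
            parts.append(f"{self.var}:{THINGS_SORT}")
        return " ".join(parts) if parts else "none"


@dataclass(frozen=True)
class Dish:
    """A mapping from location tags to soups; the global system state.

    Declared-but-empty locations are retained structurally (rules refer to
    them), but the canonical form drops variable-free empty soups: ``none``
    is the identity of soup union, so ``{CLo | none}`` adds nothing to the
    state a dish denotes.
    """

    locations: tuple[tuple[str, Soup], ...] = ()
    var: Optional[str] = None

    @staticmethod
    def of(locations: Mapping[str, Soup], var: Optional[str] = None) -> "Dish":
        tags = list(locations)
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate location tags")
        for tag in tags:
            _check_ident(tag, "location tag")
        if var is not None:
            _check_ident(var, "dish variable name")
        return Dish(tuple(sorted(locations.items())), var)

    def mapping(self) -> dict[str, Soup]:
        return dict(self.locations)

    def soup(self, tag: str) -> Soup:
        """The soup at ``tag``; absent locations read as the empty soup."""
        for t, s in self.locations:
            if t == tag:
                return s
        return Soup()

    def tags(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.locations)

    def render(self) -> str:
        """Canonical form: sorted tags, empty variable-free soups dropped."""
        parts = [
            f"{{{tag} | {soup.render()}}}"
            for tag, soup in self.locations
            if not (soup.is_empty())
        ]
        if self.var is not None:
            parts.append(f"{self.var}:{DISH_SORT}")
        return " ".join(parts) if parts else EMPTY_DISH_SENTINEL


def canonicalize(d: Dish) -> str:
    """Canonical string of a dish: the authority for state equality.

    Two dishes equal up to soup/complex permutation (and up to declaring
    empty locations) map to the identical string, and the string parses
    back to a canonically equal dish.
    """
    return d.render()


# ---------------------------------------------------------------------------
# variables and groundness


@dataclass
class VarSet:
    """Variables occurring in a pattern, split by kind."""

    element: dict[str, str] = field(default_factory=dict)  # name -> sort
    soup: set[str] = field(default_factory=set)
    dish: set[str] = field(default_factory=set)

    def is_empty(self) -> bool:
        return not (self.element or self.soup or self.dish)

    def names(self) -> set[str]:
        return set(self.element) | self.soup | self.dish


def _collect_term_vars(t: Term, out: VarSet) -> None:
    if isinstance(t, ElementVar):
        out.element[t.name] = t.sort
    elif isinstance(t, Complex):
        for p in t.parts:
            _collect_term_vars(p, out)


def vars_of(x: Union[Dish, Soup, Term]) -> VarSet:
    out = VarSet()
    if isinstance(x, Dish):
        for _, soup in x.locations:
            for t, _n in soup.counts:
                _collect_term_vars(t, out)
            if soup.var is not None:
                out.soup.add(soup.var)
        if x.var is not None:
            out.dish.add(x.var)
    elif isinstance(x, Soup):
        for t, _n in x.counts:
            _collect_term_vars(t, out)
        if x.var is not None:
            out.soup.add(x.var)
    else:
        _collect_term_vars(x, out)
    return out


def is_ground(x: Union[Dish, Soup, Term]) -> bool:
    """True iff no variable of any kind occurs."""
    return vars_of(x).is_empty()


class FreshNames:
    """Deterministic fresh-variable supply; one shared counter for all kinds.

    Variable namespaces are disjoint by kind (element / soup / dish), but a
    single counter keeps renamings collision-free across kinds, which
    topification and narrowing rely on.
    """

    def __init__(self, prefix: str = "v#"):
        self.prefix = prefix
        self._n = 0

    def name(self) -> str:
        self._n += 1
        return f"{self.prefix}{self._n}"

    def element_var(self, sort: str, mods: Iterable[Modification] = ()) -> ElementVar:
        return ElementVar(self.name(), sort, frozenset(mods))

    def soup_var(self) -> str:
        return self.name()

    def dish_var(self) -> str:
        return self.name()


# ---------------------------------------------------------------------------
# textual parser

_TOKEN_RE = re.compile(
    r"""
    (?P<VAR>[A-Za-z_][A-Za-z0-9_.'#]*:[A-Za-z_][A-Za-z0-9_.'#]*)
  | (?P<IDENT>[A-Za-z_][A-Za-z0-9_.'#]*)
  | (?P<PUNCT>[{}|\[\]()\-:])
  | (?P<WS>\s+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    toks = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ParseError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind != "WS":
            toks.append((kind, m.group(), pos))
        pos = m.end()
    return toks


class _Parser:
    """Recursive-descent reader for the textual dish notation.

    ``{TAG | term term ...}`` concatenated; modified term ``[Name - mod ...]``;
    complex ``a : b`` (the ``:`` spaced apart — ``a:b`` without spaces lexes
    as a sorted variable); empty soup ``none``.  Variables: ``x:Sort`` is an
    element variable, ``x:Things`` a soup variable, ``x:Dishes`` a dish
    variable.  When a ``vocab`` of known entity names is supplied, a bare
    lowercase identifier outside the vocabulary is read as a soup variable
    (dish variable at dish level), permitting the looser style ``{XOut | xout}``.
    """

    def __init__(self, text: str, vocab: Optional[set[str]] = None):
        self.toks = _tokenize(text)
        self.i = 0
        self.vocab = vocab

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of input")
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val, pos = self.next()
        if val != value:
            raise ParseError(f"expected {value!r}, got {val!r}", pos)

    def _is_loose_var(self, name: str) -> bool:
        return (
            self.vocab is not None
            and name not in self.vocab
            and name != "none"
            and name[0].islower()
        )

    def parse_dish(self) -> Dish:
        locations: dict[str, Soup] = {}
        dish_var: Optional[str] = None
        if self.peek() and self.peek()[1] == "{" and self._empty_braces():
            self.next(), self.next()
            return Dish()
        while self.peek() is not None:
            kind, val, pos = self.peek()
            if val == "{":
                tag, soup = self.parse_location()
                if tag in locations:
                    raise ParseError(f"duplicate location tag {tag!r}", pos)
                locations[tag] = soup
            elif kind == "VAR" and val.endswith(f":{DISH_SORT}"):
                if dish_var is not None:
                    raise ParseError("more than one dish variable", pos)
                dish_var = val.rsplit(":", 1)[0]
                self.next()
            elif kind == "IDENT" and self._is_loose_var(val):
                if dish_var is not None:
                    raise ParseError("more than one dish variable", pos)
                dish_var = val
                self.next()
            else:
                raise ParseError(f"unexpected token {val!r} at dish level", pos)
        return Dish.of(locations, var=dish_var)

    def _empty_braces(self) -> bool:
        return (
            self.i + 1 < len(self.toks)
            and self.toks[self.i][1] == "{"
            and self.toks[self.i + 1][1] == "}"
        )

    def parse_location(self) -> tuple[str, Soup]:
        self.expect("{")
        kind, tag, pos = self.next()
        if kind not in ("IDENT",):
            raise ParseError(f"expected location tag, got {tag!r}", pos)
        self.expect("|")
        soup = self.parse_soup()
        self.expect("}")
        return tag, soup

    def parse_soup(self) -> Soup:
        first = self.peek()
        if first is not None and first[1] == "none":
            self.next()
            return Soup()
        terms: list[Term] = []
        soup_var: Optional[str] = None
        while self.peek() is not None and self.peek()[1] != "}":
            kind, val, pos = self.peek()
            if kind == "VAR" and val.endswith(f":{THINGS_SORT}"):
                if soup_var is not None:
                    raise RestrictionViolation("two soup variables in one soup")
                soup_var = val.rsplit(":", 1)[0]
                self.next()
                continue
            if kind == "IDENT" and self._is_loose_var(val):
                if soup_var is not None:
                    raise RestrictionViolation("two soup variables in one soup")
                soup_var = val
                self.next()
                continue
            terms.append(self.parse_term())
        return Soup.of(*terms, var=soup_var)

    def parse_term(self) -> Term:
        parts = [self.parse_simple_term()]
        while self.peek() is not None and self.peek()[1] == ":":
            self.next()
            parts.append(self.parse_simple_term())
        if len(parts) == 1:
            return parts[0]
        return Complex.of(*parts)

    def parse_simple_term(self) -> Term:
        kind, val, pos = self.next()
        if val == "[":
            base = self.parse_base()
            self.expect("-")
            mods = [self.parse_mod()]
            while self.peek() is not None and self.peek()[1] != "]":
                mods.append(self.parse_mod())
            self.expect("]")
            if isinstance(base, Entity):
                return Entity(base.name, frozenset(mods))
            return ElementVar(base.name, base.sort, frozenset(mods))
        self.i -= 1
        return self.parse_base()

    def parse_base(self) -> Union[Entity, ElementVar]:
        kind, val, pos = self.next()
        if kind == "VAR":
            name, sort = val.rsplit(":", 1)
            return ElementVar(name, sort)
        if kind == "IDENT":
            return Entity(val)
        raise ParseError(f"expected a term, got {val!r}", pos)

    def parse_mod(self) -> Modification:
        kind, val, pos = self.next()
        if kind != "IDENT":
            raise ParseError(f"expected modification name, got {val!r}", pos)
        if self.peek() is not None and self.peek()[1] == "(":
            self.next()
            akind, arg, apos = self.next()
            if akind != "IDENT":
                raise ParseError(f"expected modification argument, got {arg!r}", apos)
            self.expect(")")
            return Modification(val, arg)
        return Modification(val)


def parse_dish(text: str, vocab: Optional[set[str]] = None) -> Dish:
    """Parse the textual dish notation back into a :class:`Dish`."""
    return _Parser(text, vocab).parse_dish()


# ---------------------------------------------------------------------------
# JSON (the primary, diff-able interchange form)


def _mod_to_json(m: Modification):
    return m.name if m.arg is None else {"name": m.name, "arg": m.arg}


def _mod_from_json(obj) -> Modification:
    if isinstance(obj, str):
        return Modification(obj)
    return Modification(obj["name"], obj.get("arg"))


def term_to_json(t: Term):
    if isinstance(t, Entity):
        out = {"entity": t.name}
        if t.mods:
            out["mods"] = [_mod_to_json(m) for m in sorted(t.mods)]
        return out
    if isinstance(t, ElementVar):
        out = {"var": t.name, "sort": t.sort}
        if t.mods:
            out["mods"] = [_mod_to_json(m) for m in sorted(t.mods)]
        return out
    if isinstance(t, Complex):
        return {"complex": [term_to_json(p) for p in t.parts]}
    raise TypeError(f"not a term: {t!r}")


def term_from_json(obj) -> Term:
    if not isinstance(obj, dict):
        raise ParseError(f"term must be a JSON object, got {obj!r}")
    if "entity" in obj:
        return Entity(obj["entity"], frozenset(_mod_from_json(m) for m in obj.get("mods", [])))
    if "var" in obj:
        return ElementVar(
            obj["var"], obj["sort"], frozenset(_mod_from_json(m) for m in obj.get("mods", []))
        )
    if "complex" in obj:
        return Complex.of(*(term_from_json(p) for p in obj["complex"]))
    raise ParseError(f"unrecognized term object: {obj!r}")


def soup_to_json(s: Soup):
    return {"elements": [term_to_json(t) for t in s.terms()], "var": s.var}


def soup_from_json(obj) -> Soup:
    return Soup.of(*(term_from_json(t) for t in obj.get("elements", [])), var=obj.get("var"))


def dish_to_json(d: Dish):
    return {
        "locations": {tag: soup_to_json(s) for tag, s in d.locations},
        "var": d.var,
    }


def dish_from_json(obj) -> Dish:
    return Dish.of(
        {tag: soup_from_json(s) for tag, s in obj.get("locations", {}).items()},
        var=obj.get("var"),
    )
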