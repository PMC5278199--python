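"""Sort hierarchy: membership of entities (and terms) in named sorts.

A sort denotes a set of entity names, given directly (``GabS`` contains
``Gab1`` and ``Gab2``) or through subsorts (``ErkS`` below ``BProtein``).
Membership of a term follows its base entity name and ignores modification
state — a phosphorylated Erks is still an ErkS — while complexes belong
only to the universal collection sort ``Things``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import UnknownSortError, ValidationError
from .terms import THINGS_SORT, Complex, ElementVar, Entity, Term

__all__ = ["SortHierarchy"]


@dataclass
class SortHierarchy:
    """Acyclic subsort graph with entity members, queried by transitive closure."""

    members: dict[str, set[str]] = field(default_factory=dict)
    entities: set[str] = field(default_factory=set)
    _denotation_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    @staticmethod
    def build(
        sorts: Mapping[str, Iterable[str]],
        entity_sorts: Optional[Mapping[str, Iterable[str]]] = None,
    ) -> "SortHierarchy":
        """Assemble from a sort->members map plus per-entity declared sorts."""
        members = {s: set(ms) for s, ms in sorts.items()}
        entities = set(entity_sorts or ())
        for ent, declared in (entity_sorts or {}).items():
            for s in declared:
                members.setdefault(s, set()).add(ent)
        h = SortHierarchy(members=members, entities=entities)
        h.validate()
        return h

    @property
    def sorts(self) -> set[str]:
        return set(self.members) | {THINGS_SORT}

    def validate(self) -> None:
        """Reject cycles in the subsort graph and clear stale caches."""
        self._denotation_cache.clear()
        state: dict[str, int] = {}

        def visit(s: str, stack: tuple[str, ...]) -> None:
            if state.get(s) == 2:
                return
            if state.get(s) == 1:
                raise ValidationError(f"subsort cycle through {s!r}: {' -> '.join(stack)}")
            state[s] = 1
            for m in self.members.get(s, ()):
                if m in self.members:
                    visit(m, stack + (m,))
            state[s] = 2

        for s in self.members:
            visit(s, (s,))

    def denotation(self, sort: str) -> frozenset[str]:
        """All entity names in ``sort``, by transitive closure of subsorts."""
        if sort == THINGS_SORT:
            return frozenset(self.entities)
        if sort not in self.members:
            raise UnknownSortError(f"sort {sort!r} is not declared")
        cached = self._denotation_cache.get(sort)
        if cached is not None:
            return cached
        out: set[str] = set()
        for m in self.members[sort]:
            if m in self.members:
                out |= self.denotation(m)
            else:
                out.add(m)
        result = frozenset(out)
        self._denotation_cache[sort] = result
        return result

    def member(self, t: Term, sort: str) -> bool:
        """True iff term ``t`` belongs to ``sort``.

        ``Things`` contains every term; otherwise membership follows the base
        entity name, so modification state does not change sort membership.
        """
        if sort == THINGS_SORT:
            return True
        if isinstance(t, Entity):
            return t.name in self.denotation(sort)
        if isinstance(t, ElementVar):
            return self.sort_leq(t.sort, sort)
        if isinstance(t, Complex):
            return False
        raise TypeError(f"not a term: {t!r}")

    def sort_leq(self, s1: str, s2: str) -> bool:
        """Subsort test by denotation inclusion."""
        if s2 == THINGS_SORT:
            return True
        if s1 == THINGS_SORT:
            return self.denotation(s1) <= self.denotation(s2)
        return self.denotation(s1) <= self.denotation(s2)

    def meet(self, s1: str, s2: str) -> Optional[str]:
        """A named sort denoting the intersection, when one side contains the other."""
        if self.sort_leq(s1, s2):
            return s1
        if self.sort_leq(s2, s1):
            return s2
        return None

    def to_json(self):
        return {s: sorted(ms) for s, ms in sorted(self.members.items())}
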