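"""Knowledge base: labeled rewrite rules, sort hierarchy, vocabulary, dishes.

A rule is a labeled pair of dish patterns (LHS, RHS) plus optional
sort-membership conditions; it models one reaction.  Reactants appear on
the LHS and are consumed; products appear on the RHS; modifiers (enzymes,
scaffolds, controls) are listed identically on both sides and pass through
unchanged.  The KB bundles the rules with the sort hierarchy, the entity
vocabulary and named initial dishes, and is serialized as versioned JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

from .errors import ParseError, UnknownSortError, ValidationError
from .sorts import SortHierarchy
from .terms import (
    Dish,
    Soup,
    Term,
    canonicalize,
    dish_from_json,
    dish_to_json,
    vars_of,
)

__all__ = ["Rule", "KnowledgeBase", "load_kb", "save_kb", "sort_member"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Rule:
    """One reaction: ``lhs => rhs`` over dish patterns, with sort conditions."""

    label: str
    lhs: Dish
    rhs: Dish
    conditions: tuple[tuple[str, str], ...] = ()
    source: Optional[str] = None

    def validate(self, hierarchy: Optional[SortHierarchy] = None) -> None:
        lhs_vars = vars_of(self.lhs)
        rhs_vars = vars_of(self.rhs)
        extra = rhs_vars.names() - lhs_vars.names()
        if extra:
            raise ValidationError(
                f"rule {self.label!r}: RHS invents variables {sorted(extra)}"
            )
        lhs_tags = set(self.lhs.tags())
        rhs_tags = set(self.rhs.tags())
        if lhs_tags != rhs_tags:
            raise ValidationError(
                f"rule {self.label!r}: LHS and RHS mention different locations "
                f"({sorted(lhs_tags ^ rhs_tags)})"
            )
        if hierarchy is not None:
            for var, sort in self.conditions:
                if sort not in hierarchy.sorts:
                    raise UnknownSortError(
                        f"rule {self.label!r}: condition on unknown sort {sort!r}"
                    )
            for var, sort in {**lhs_vars.element, **rhs_vars.element}.items():
                if sort not in hierarchy.sorts:
                    raise UnknownSortError(
                        f"rule {self.label!r}: variable {var!r} has unknown sort {sort!r}"
                    )

    def entity_names(self) -> set[str]:
        names: set[str] = set()
        for dish in (self.lhs, self.rhs):
            for _, soup in dish.locations:
                for t, _n in soup.counts:
                    names |= _term_entities(t)
        return names

    def to_json(self):
        out = {
            "label": self.label,
            "lhs": dish_to_json(self.lhs),
            "rhs": dish_to_json(self.rhs),
            "conditions": [[v, s] for v, s in self.conditions],
        }
        if self.source:
            out["source"] = self.source
        return out

    @staticmethod
    def from_json(obj) -> "Rule":
        try:
            return Rule(
                label=obj["label"],
                lhs=dish_from_json(obj["lhs"]),
                rhs=dish_from_json(obj["rhs"]),
                conditions=tuple((v, s) for v, s in obj.get("conditions", [])),
                source=obj.get("source"),
            )
        except KeyError as e:
            raise ParseError(f"rule object missing field {e}") from e


def _term_entities(t: Term) -> set[str]:
    from .terms import Complex, ElementVar, Entity

    if isinstance(t, Entity):
        return {t.name}
    if isinstance(t, ElementVar):
        return set()
    if isinstance(t, Complex):
        out: set[str] = set()
        for p in t.parts:
            out |= _term_entities(p)
        return out
    raise TypeError(f"not a term: {t!r}")


@dataclass
class KnowledgeBase:
    rules: dict[str, Rule] = field(default_factory=dict)
    sorts: SortHierarchy = field(default_factory=SortHierarchy)
    entities: dict[str, list[str]] = field(default_factory=dict)  # name -> declared sorts
    dishes: dict[str, Dish] = field(default_factory=dict)

    def rule_list(self) -> list[Rule]:
        """Rules in lexicographic label order — the deterministic application order."""
        return [self.rules[label] for label in sorted(self.rules)]

    def validate(self) -> None:
        self.sorts.validate()
        for label, rule in self.rules.items():
            if rule.label != label:
                raise ValidationError(f"rule keyed {label!r} carries label {rule.label!r}")
            rule.validate(self.sorts)
            undeclared = rule.entity_names() - set(self.entities)
            if undeclared:
                raise ValidationError(
                    f"rule {label!r} references undeclared entities {sorted(undeclared)}"
                )
        for name, dish in self.dishes.items():
            for _, soup in dish.locations:
                for t, _n in soup.counts:
                    undeclared = _term_entities(t) - set(self.entities)
                    if undeclared:
                        raise ValidationError(
                            f"dish {name!r} references undeclared entities {sorted(undeclared)}"
                        )

    def fingerprint(self) -> str:
        """Stable digest of rule content; used to detect stale search solutions."""
        import hashlib

        h = hashlib.sha256()
        for rule in self.rule_list():
            h.update(rule.label.encode())
            h.update(canonicalize(rule.lhs).encode())
            h.update(canonicalize(rule.rhs).encode())
            h.update(repr(sorted(rule.conditions)).encode())
        return h.hexdigest()

    def to_json(self):
        return {
            "version": SCHEMA_VERSION,
            "sorts": self.sorts.to_json(),
            "entities": {n: sorted(ss) for n, ss in sorted(self.entities.items())},
            "rules": [r.to_json() for r in self.rule_list()],
            "dishes": {n: dish_to_json(d) for n, d in sorted(self.dishes.items())},
        }

    @staticmethod
    def from_json(obj) -> "KnowledgeBase":
        if not isinstance(obj, dict):
            raise ParseError("knowledge base must be a JSON object")
        version = obj.get("version")
        if version != SCHEMA_VERSION:
            raise ParseError(f"unsupported KB schema version {version!r}")
        entities = {n: list(ss) for n, ss in obj.get("entities", {}).items()}
        sorts = SortHierarchy.build(
            {s: set(ms) for s, ms in obj.get("sorts", {}).items()}, entities
        )
        rules: dict[str, Rule] = {}
        for robj in obj.get("rules", []):
            rule = Rule.from_json(robj)
            if rule.label in rules:
                raise ValidationError(f"duplicate rule label {rule.label!r}")
            rules[rule.label] = rule
        dishes = {n: dish_from_json(d) for n, d in obj.get("dishes", {}).items()}
        kb = KnowledgeBase(rules=rules, sorts=sorts, entities=entities, dishes=dishes)
        kb.validate()
        return kb


def load_kb(source: Union[str, Path]) -> KnowledgeBase:
    """Load and validate a KB from a JSON file path or a JSON text string."""
    text: str
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        path = Path(source)
        text = path.read_text()
    else:
        text = source
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid KB JSON: {e.msg} (line {e.lineno})") from e
    return KnowledgeBase.from_json(obj)


def save_kb(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(kb.to_json(), indent=1, sort_keys=True) + "\n")


def sort_member(t: Term, sort: str, hierarchy: SortHierarchy) -> bool:
    """Membership of a term in a sort, e.g. a modified Erks in ErkS."""
    return hierarchy.member(t, sort)
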