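"""Seed-reproducible random knowledge bases for property testing.

The generated systems mimic the structure of curated pathway rules at toy
scale: a handful of entities with a small sort vocabulary, a few
locations, and rules that mostly conserve entities — relocating or
complexing them, listing modifiers unchanged on both sides — with an
occasional "transform" rule that swaps one entity for another (the shape
of a GDP-to-GTP load switch).  Each rule is applicable to the generated
witness dish by construction, so engine tests always exercise
transitions.  Identical configuration and seed give a byte-identical KB.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .kb import KnowledgeBase, Rule
from .sorts import SortHierarchy
from .substitution import Substitution, merge_soups
from .terms import Dish, ElementVar, Entity, Modification, Soup, Term

__all__ = ["GenConfig", "generate"]


@dataclass
class GenConfig:
    """Knobs for the random KB generator; defaults keep the reachable state
    space small enough for exhaustive oracles (a few hundred states)."""

    n_entities: int = 4
    n_locations: int = 2
    n_rules: int = 3
    max_soup_size: int = 3
    max_rule_width: int = 2
    p_modifier: float = 0.25
    p_sort_condition: float = 0.25
    p_transform: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_entities", "n_locations", "max_soup_size", "max_rule_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_rules < 0:
            raise ValueError("n_rules must be >= 0")
        for name in ("p_modifier", "p_sort_condition", "p_transform"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")


MOD = Modification("mod")


def generate(cfg: GenConfig) -> tuple[KnowledgeBase, Dish]:
    """A validated random KB plus a ground witness dish named ``Start``.

    The witness dish is the union of one ground instantiation of every
    rule's LHS (so every rule fires on it) plus a little random padding.
    """
    cfg.validate()
    rng = random.Random(cfg.seed)

    entities = [f"E{i + 1}" for i in range(cfg.n_entities)]
    locations = [f"L{i + 1}" for i in range(cfg.n_locations)]
    # two overlapping sorts over the vocabulary; every sort nonempty
    half = max(1, cfg.n_entities // 2)
    sort_a = entities[:half]
    sort_b = entities[half:] or entities[:1]
    entity_sorts = {e: ["SortA"] for e in sort_a}
    for e in sort_b:
        entity_sorts.setdefault(e, []).append("SortB")
    hierarchy = SortHierarchy.build({"SortA": set(), "SortB": set()}, entity_sorts)

    def random_entity() -> Entity:
        name = rng.choice(entities)
        if rng.random() < cfg.p_modifier:
            return Entity(name, frozenset({MOD}))
        return Entity(name)

    rules: dict[str, Rule] = {}
    witness: dict[str, Soup] = {}
    for i in range(cfg.n_rules):
        label = f"r{i + 1:03d}"
        width = rng.randint(1, cfg.max_rule_width)
        lhs_terms: list[tuple[str, Term]] = []
        grounding = Substitution()
        for j in range(width):
            loc = rng.choice(locations)
            if rng.random() < cfg.p_sort_condition:
                sort = rng.choice(["SortA", "SortB"])
                var = ElementVar(f"x{i + 1}_{j}", sort)
                lhs_terms.append((loc, var))
                grounding.element[var.name] = Entity(
                    rng.choice(sorted(hierarchy.denotation(sort)))
                )
            else:
                lhs_terms.append((loc, random_entity()))
        # products: the same matter, possibly relocated / re-modified, with at
        # most one transform swap
        rhs_terms: list[tuple[str, Term]] = []
        transformed = False
        for loc, t in lhs_terms:
            new_loc = rng.choice(locations)
            if (
                not transformed
                and isinstance(t, Entity)
                and rng.random() < cfg.p_transform
            ):
                t = Entity(rng.choice(entities), t.mods)
                transformed = True
            elif isinstance(t, Entity) and rng.random() < cfg.p_modifier:
                t = Entity(t.name, frozenset() if t.mods else frozenset({MOD}))
            rhs_terms.append((new_loc, t))
        if rng.random() < cfg.p_modifier:
            loc = rng.choice(locations)
            m = random_entity()
            lhs_terms.append((loc, m))
            rhs_terms.append((loc, m))

        tags = sorted({loc for loc, _ in lhs_terms} | {loc for loc, _ in rhs_terms})
        lhs = Dish.of(
            {tag: Soup.of(*(t for loc, t in lhs_terms if loc == tag)) for tag in tags}
        )
        rhs = Dish.of(
            {tag: Soup.of(*(t for loc, t in rhs_terms if loc == tag)) for tag in tags}
        )
        rules[label] = Rule(label=label, lhs=lhs, rhs=rhs)
        ground_lhs = grounding.apply_dish(lhs)
        for tag, soup in ground_lhs.locations:
            witness[tag] = merge_soups(witness.get(tag, Soup()), soup)

    # pad with a little random matter, bounded per location
    for loc in locations:
        soup = witness.get(loc, Soup())
        while soup.size < cfg.max_soup_size and rng.random() < 0.5:
            soup = merge_soups(soup, Soup.of(random_entity()))
        witness[loc] = soup

    dish = Dish.of({tag: s for tag, s in witness.items() if not s.is_empty()})
    kb = KnowledgeBase(
        rules=rules,
        sorts=hierarchy,
        entities={e: sorted(entity_sorts[e]) for e in entities},
        dishes={"Start": dish},
    )
    kb.validate()
    return kb, dish
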