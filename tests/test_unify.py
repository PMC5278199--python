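"""AC-multiset unification: worked examples, soundness, completeness, symmetry."""

import itertools
import random

import pytest

from dishsoup import (
    Dish,
    ElementVar,
    Entity,
    FreshNames,
    Modification,
    RestrictionViolation,
    Soup,
    UnificationProblem,
    canonicalize,
    match,
    parse_dish,
    unify,
)
from dishsoup.narrowing import pattern_key
from dishsoup.sorts import SortHierarchy

from .oracles import ground_soups

H = SortHierarchy.build(
    {"SortA": set(), "SortB": set()},
    {"Aa": ["SortA"], "Bb": ["SortA", "SortB"], "Cc": ["SortB"]},
)
UNIVERSE = ["Aa", "Bb", "Cc"]


def _ground_instances(pattern, universe, max_size):
    """Every ground dish obtainable from the pattern over a small universe."""
    from dishsoup import Substitution, vars_of

    vs = vars_of(pattern)
    element_choices = {
        n: [Entity(e) for e in sorted(H.denotation(s) & set(universe))]
        for n, s in vs.element.items()
    }
    soup_choices = {n: ground_soups(universe, max_size) for n in vs.soup}
    dish_choices = {
        n: [Dish(), Dish.of({"L9": Soup.of(Entity(universe[0]))})] for n in vs.dish
    }
    names = sorted(element_choices) + sorted(soup_choices) + sorted(dish_choices)
    pools = (
        [element_choices[n] for n in sorted(element_choices)]
        + [soup_choices[n] for n in sorted(soup_choices)]
        + [dish_choices[n] for n in sorted(dish_choices)]
    )
    for combo in itertools.product(*pools):
        sub = Substitution()
        for n, v in zip(names, combo):
            if isinstance(v, Dish):
                sub.dish[n] = v
            elif isinstance(v, Soup):
                sub.soup[n] = v
            else:
                sub.element[n] = v
        yield sub.apply_dish(pattern)


def assert_complete_and_sound(left, right, max_size=3):
    unifiers = unify(UnificationProblem(left, right, H))
    # soundness: each unifier really equalizes the two sides
    for sigma in unifiers:
        assert canonicalize(sigma.apply_dish(left)) == canonicalize(
            sigma.apply_dish(right)
        )
    # completeness vs ground enumeration over a 3-entity universe
    left_instances = {canonicalize(g): g for g in _ground_instances(left, UNIVERSE, max_size)}
    right_instances = {canonicalize(g) for g in _ground_instances(right, UNIVERSE, max_size)}
    common = sorted(set(left_instances) & right_instances)
    for key in common:
        ground = left_instances[key]
        assert any(
            match(sigma.apply_dish(left), ground, H) for sigma in unifiers
        ), f"common instance {key} covered by no unifier"
    return unifiers, common


def test_soup_variable_must_contain_the_fixed_occurrence():
    left = parse_dish("{XOut | xout:Things}")
    right = parse_dish("{XOut | Aa rest:Things}")
    unifiers = unify(UnificationProblem(left, right, H))
    assert len(unifiers) == 1
    bound = unifiers[0].soup["xout"]
    assert Entity("Aa") in dict(bound.counts)
    assert bound.var is not None  # "xout must be of the form xout' Aa"


def test_identical_ground_dishes_unify_with_empty_substitution(vending_kb):
    d = vending_kb.dishes["TwoQuarterDish"]
    e = parse_dish(canonicalize(d))
    unifiers = unify(UnificationProblem(d, e, vending_kb.sorts))
    assert len(unifiers) == 1
    assert unifiers[0].is_identity()


def test_shared_variables_are_rejected():
    left = parse_dish("{A | v:Things}")
    right = parse_dish("{A | Aa v:Things}")
    with pytest.raises(RestrictionViolation):
        unify(UnificationProblem(left, right, H))


def test_surplus_assignment_enumeration_is_complete():
    # {A | q q v} vs {A | q w}: the surplus q can pair or be absorbed
    left = parse_dish("{A | Aa Aa v:Things}")
    right = parse_dish("{A | Aa w:Things}")
    unifiers, common = assert_complete_and_sound(left, right, max_size=4)
    assert common  # the enumeration actually produced shared instances


@pytest.mark.parametrize(
    "left_text,right_text",
    [
        ("{A | x:SortA rest:Things}", "{A | [Bb - m] w:Things}"),
        ("{A | x:SortA}", "{A | y:SortB}"),
        ("{A | Aa v:Things} {B | Bb}", "{A | w:Things} {B | y:SortA}"),
        ("{A | v:Things} d1:Dishes", "{A | Aa} {B | Bb w:Things}"),
        ("{A | [x:SortA - m]}", "{A | [y:SortB - n]}"),
    ],
)
def test_unification_fragment_examples(left_text, right_text):
    assert_complete_and_sound(parse_dish(left_text), parse_dish(right_text))


def test_random_soup_problems_complete_against_enumeration():
    rng = random.Random(3)
    pool = [
        Entity("Aa"),
        Entity("Bb"),
        Entity("Cc"),
        Entity("Aa", frozenset([Modification("m")])),
        ElementVar("x", "SortA"),
        ElementVar("y", "SortB"),
    ]

    def random_side(var_name):
        terms = [rng.choice(pool) for _ in range(rng.randint(0, 2))]
        # variables on the right side are renamed apart
        terms = [
            ElementVar(var_name + t.name, t.sort, t.mods)
            if isinstance(t, ElementVar)
            else t
            for t in terms
        ]
        return Dish.of(
            {"A": Soup.of(*terms, var=var_name if rng.random() < 0.7 else None)}
        )

    nonempty = 0
    for _ in range(25):
        left = random_side("l")
        right = random_side("r")
        _, common = assert_complete_and_sound(left, right, max_size=2)
        nonempty += bool(common)
    assert nonempty >= 10


def test_unify_is_symmetric_up_to_renaming():
    cases = [
        ("{A | Aa Aa v:Things}", "{A | Aa w:Things}"),
        ("{A | x:SortA rest:Things}", "{A | [Bb - m] w:Things}"),
        ("{A | v:Things} d1:Dishes", "{A | Aa} {B | Bb w:Things}"),
    ]
    for lt, rt in cases:
        left, right = parse_dish(lt), parse_dish(rt)
        fwd = unify(UnificationProblem(left, right, H))
        rev = unify(UnificationProblem(right, left, H))
        fwd_keys = {pattern_key(s.apply_dish(left)) for s in fwd}
        rev_keys = {pattern_key(s.apply_dish(right)) for s in rev}
        assert fwd_keys == rev_keys


def test_unifier_list_is_deterministic_and_duplicate_free():
    left = parse_dish("{A | Aa Aa v:Things}")
    right = parse_dish("{A | Aa Bb w:Things}")
    first = unify(UnificationProblem(left, right, H))
    second = unify(UnificationProblem(left, right, H))
    keys = [s.key() for s in first]
    assert keys == [s.key() for s in second]
    assert len(keys) == len(set(keys))
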