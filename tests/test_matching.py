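"""Pattern matching and single-rule application, checked against brute force."""

import random
from collections import Counter

import pytest

from dishsoup import (
    Complex,
    Dish,
    ElementVar,
    Entity,
    Modification,
    Soup,
    apply_rule,
    canonicalize,
    match,
    parse_dish,
)

from .oracles import enumerate_matches

YPHOS = Modification("Yphos")


def test_match_binds_extension_variables_to_none(egf_kb):
    p = parse_dish("{XOut | Egf xout:Things} {EgfRC | EgfR e:Things}")
    d = parse_dish("{XOut | Egf} {EgfRC | EgfR}")
    subs = match(p, d, egf_kb.sorts)
    assert len(subs) == 1
    assert subs[0].soup["xout"] == Soup()
    assert subs[0].soup["e"] == Soup()


def test_match_element_variable_against_modified_entity(egf_kb):
    erks = Entity(
        "Erks", frozenset([Modification("phos", "TEY"), Modification("phos", "SPS")])
    )
    d = Dish.of({"NUc": Soup.of(erks, Entity("Atf1"))})
    p = Dish.of({"NUc": Soup.of(ElementVar("prot", "BProtein"), var="rest")})
    subs = match(p, d, egf_kb.sorts, conditions=[("prot", "ErkS")])
    assert len(subs) == 1
    assert subs[0].element["prot"] == erks
    # the condition prunes bindings outside ErkS: Atf1 is a Protein, not an ErkS
    assert all(s.element["prot"].name == "Erks" for s in subs)


def test_most_general_pattern_has_exactly_one_match(egf_kb):
    d = egf_kb.dishes["EgfDish"]
    p = Dish.of(
        {tag: Soup(var=f"v{i}") for i, tag in enumerate(d.tags())},
    )
    subs = match(p, d, egf_kb.sorts)
    assert len(subs) == 1
    for i, tag in enumerate(d.tags()):
        assert subs[0].soup[f"v{i}"] == d.soup(tag)


def test_match_requires_exact_coverage(vending_kb):
    p = parse_dish("{VM | quarter}")
    d = parse_dish("{VM | quarter quarter}")
    assert match(p, d, vending_kb.sorts) == []


def _random_ground_dish(rng):
    entities = ["Aa", "Bb", "Cc"]
    terms = []
    for _ in range(rng.randint(1, 6)):
        name = rng.choice(entities)
        if rng.random() < 0.3:
            terms.append(Entity(name, frozenset([YPHOS])))
        elif rng.random() < 0.2:
            terms.append(Complex.of(Entity(name), Entity(rng.choice(entities))))
        else:
            terms.append(Entity(name))
    tags = ["L1", "L2"]
    split = rng.randint(0, len(terms))
    return Dish.of(
        {
            "L1": Soup.of(*terms[:split]),
            "L2": Soup.of(*terms[split:]),
        }
    )


def _random_pattern_from(d, rng, hierarchy):
    """Perturb a ground dish into a pattern that should still match it."""
    locations = {}
    var_i = 0
    for tag, soup in d.locations:
        terms = list(soup.terms())
        keep = []
        dropped = False
        for t in terms:
            r = rng.random()
            if r < 0.25 and isinstance(t, Entity) and not t.mods:
                var_i += 1
                keep.append(ElementVar(f"x{var_i}", rng.choice(["SortA", "SortB"])))
            elif r < 0.45:
                dropped = True
            else:
                keep.append(t)
        locations[tag] = Soup.of(*keep, var=f"s_{tag}" if dropped or rng.random() < 0.5 else None)
    return Dish.of(locations)


def test_match_agrees_with_brute_force_enumeration():
    from dishsoup.sorts import SortHierarchy

    hierarchy = SortHierarchy.build(
        {"SortA": set(), "SortB": set()},
        {"Aa": ["SortA"], "Bb": ["SortA", "SortB"], "Cc": ["SortB"]},
    )
    rng = random.Random(42)
    checked_nonempty = 0
    for _ in range(60):
        d = _random_ground_dish(rng)
        p = _random_pattern_from(d, rng, hierarchy)
        got = {s.key() for s in match(p, d, hierarchy)}
        expected = enumerate_matches(p, d, hierarchy)
        assert got == expected
        checked_nonempty += bool(expected)
    assert checked_nonempty >= 20  # the comparison exercises real matches


def test_apply_rule_001_worked_example(egf_kb):
    rule = egf_kb.rules["001.EgfR.irt.Egf"]
    d = parse_dish("{XOut | Egf} {EgfRC | EgfR}")
    successors = apply_rule(rule, d, egf_kb.sorts)
    assert len(successors) == 1
    succ, _ = successors[0]
    expected = Dish.of(
        {
            "XOut": Soup(),
            "EgfRC": Soup.of(Complex.of(Entity("EgfR", frozenset([YPHOS])), Entity("Egf"))),
        }
    )
    assert canonicalize(succ) == canonicalize(expected)


def test_rule_188_recruits_shp2_to_receptor_complex(egf_kb):
    d0 = egf_kb.dishes["EgfDish"]
    (d1, _), = apply_rule(egf_kb.rules["001.EgfR.irt.Egf"], d0, egf_kb.sorts)
    (d2, _), = apply_rule(egf_kb.rules["188.Shp2.irt.Egf"], d1, egf_kb.sorts)
    shp2_p = Entity("Shp2", frozenset([YPHOS]))
    assert shp2_p in dict(d2.soup("EgfRC").counts)
    assert Entity("Shp2") not in dict(d2.soup("CLc").counts)
    # the receptor complex acts as a modifier: still there afterwards
    egfr_complex = Complex.of(Entity("EgfR", frozenset([YPHOS])), Entity("Egf"))
    assert egfr_complex in dict(d2.soup("EgfRC").counts)


def test_rule_529_needs_gdp_loaded_hras(egf_kb):
    d0 = egf_kb.dishes["EgfDish"]
    (d1, _), = apply_rule(egf_kb.rules["001.EgfR.irt.Egf"], d0, egf_kb.sorts)
    (d2, _), = apply_rule(egf_kb.rules["188.Shp2.irt.Egf"], d1, egf_kb.sorts)
    # strip Hras:GDP from CLi: rule 529 must no longer apply
    cli = d2.soup("CLi").counter()
    del cli[Complex.of(Entity("Hras"), Entity("GDP"))]
    stripped = Dish.of({**d2.mapping(), "CLi": Soup.from_counter(cli)})
    assert apply_rule(egf_kb.rules["529.Hras.irt.Egf"], stripped, egf_kb.sorts) == []
    assert apply_rule(egf_kb.rules["529.Hras.irt.Egf"], d2, egf_kb.sorts) != []


def _entity_census(d):
    names = Counter()

    def walk(t):
        if isinstance(t, Entity):
            names[t.name] += 1
        elif isinstance(t, Complex):
            for p in t.parts:
                walk(p)

    for _, soup in d.locations:
        for t in soup.terms():
            walk(t)
    return names


@pytest.mark.parametrize(
    "label, swap",
    [
        ("001.EgfR.irt.Egf", {}),
        ("188.Shp2.irt.Egf", {}),
        ("529.Hras.irt.Egf", {"GDP": -1, "GTP": +1}),
    ],
)
def test_egf_rules_conserve_entities(egf_kb, label, swap):
    """Base entity counts are preserved, except 529's GDP-to-GTP load swap."""
    d = egf_kb.dishes["EgfDish"]
    for step in ("001.EgfR.irt.Egf", "188.Shp2.irt.Egf"):
        if step == label:
            break
        (d, _), = apply_rule(egf_kb.rules[step], d, egf_kb.sorts)
    (succ, _), = apply_rule(egf_kb.rules[label], d, egf_kb.sorts)
    before, after = _entity_census(d), _entity_census(succ)
    delta = {n: after[n] - before[n] for n in set(before) | set(after) if after[n] != before[n]}
    assert delta == swap
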