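"""Topification, backward narrowing search, and its soundness/completeness."""

import itertools

import pytest

from dishsoup import (
    Complex,
    Dish,
    Entity,
    GenConfig,
    SearchGoal,
    Soup,
    backward_search,
    canonicalize,
    forward_search,
    generate,
    ground_check,
    match,
    parse_dish,
    topify,
    vars_of,
)
from dishsoup.matching import apply_rule
from dishsoup.narrowing import pattern_key
from dishsoup.substitution import Substitution

from .oracles import bfs_shortest_depths, ground_soups

APPLE_GOAL = parse_dish("{VM | apple v:Things}")


# ---------------------------------------------------------------------------
# topification


def test_topified_rule_001_shape(egf_kb):
    rule = topify(egf_kb.rules["001.EgfR.irt.Egf"], egf_kb)
    assert rule.lhs.var is not None and rule.lhs.var == rule.rhs.var
    for tag in ("XOut", "EgfRC"):
        lvar = rule.lhs.soup(tag).var
        assert lvar is not None
        assert rule.rhs.soup(tag).var == lvar  # remainder passes through
    assert Entity("Egf") in dict(rule.lhs.soup("XOut").counts)
    assert Entity("EgfR") in dict(rule.lhs.soup("EgfRC").counts)


def test_topify_is_idempotent_up_to_renaming(egf_kb):
    for rule in egf_kb.rule_list():
        once = topify(rule, egf_kb)
        twice = topify(once, egf_kb)
        assert pattern_key(twice.lhs) == pattern_key(once.lhs)
        assert pattern_key(twice.rhs) == pattern_key(once.rhs)


def _successors_via_topified_match(kb, rule, dish):
    """Second route: exact match of the topified LHS at the top of the dish."""
    top = topify(rule, kb)
    out = set()
    for sub in match(top.lhs, dish, kb.sorts, conditions=rule.conditions):
        out.add(canonicalize(sub.apply_dish(top.rhs)))
    return out


@pytest.mark.parametrize("seed", range(20))
def test_topification_preserves_transition_relation(seed):
    """Ground rewriting below the top and topified rewriting at the top agree."""
    kb, start = generate(GenConfig(seed=seed))
    states = [start]
    seen = {canonicalize(start)}
    for _ in range(3):
        nxt = []
        for d in states:
            for rule in kb.rule_list():
                direct = {
                    canonicalize(s) for s, _ in apply_rule(rule, d, kb.sorts)
                }
                via_top = _successors_via_topified_match(kb, rule, d)
                assert direct == via_top, (seed, rule.label, canonicalize(d))
                for s, _ in apply_rule(rule, d, kb.sorts):
                    if canonicalize(s) not in seen:
                        seen.add(canonicalize(s))
                        nxt.append(s)
        states = nxt


def test_topification_on_egf_fixture_chain(egf_kb):
    d = egf_kb.dishes["EgfDish"]
    for label in ("001.EgfR.irt.Egf", "188.Shp2.irt.Egf", "529.Hras.irt.Egf"):
        rule = egf_kb.rules[label]
        direct = {canonicalize(s) for s, _ in apply_rule(rule, d, egf_kb.sorts)}
        assert direct == _successors_via_topified_match(egf_kb, rule, d)
        (d, _), = apply_rule(rule, d, egf_kb.sorts)


# ---------------------------------------------------------------------------
# backward search: the vending machine trace


def test_vending_backward_trace(vending_kb):
    sols = backward_search(vending_kb, APPLE_GOAL, max_depth=2)
    assert sols[0].depth == 0
    assert sols[0].accumulated_substitution.is_identity()
    assert sols[0].rule_path == ()

    def fixed_counts(sol):
        return sol.initial_pattern.soup("VM").counter()

    by_depth = {d: [s for s in sols if s.depth == d] for d in (0, 1, 2)}
    # one step back: a pattern whose fixed part holds the two quarters the
    # apple rule consumes
    assert any(
        fixed_counts(s)[Entity("quarter")] >= 2 for s in by_depth[1]
    )
    # two steps back: a dollar suffices
    assert any(
        fixed_counts(s)[Entity("dollar")] >= 1
        and fixed_counts(s)[Entity("apple")] == 0
        and fixed_counts(s)[Entity("quarter")] == 0
        for s in by_depth[2]
    )
    depths = [s.depth for s in sols]
    assert depths == sorted(depths)


def test_vending_backward_solutions_all_ground_check(vending_kb):
    for sol in backward_search(vending_kb, APPLE_GOAL, max_depth=2):
        assert ground_check(sol, vending_kb)


def test_corrupted_solution_fails_ground_check(vending_kb):
    sols = backward_search(vending_kb, APPLE_GOAL, max_depth=2)
    sol = next(s for s in sols if s.depth == 2)
    sol.accumulated_substitution = Substitution(
        soup={"v": Soup.of(Entity("chocolate", frozenset()))}
    )
    sol.initial_pattern = parse_dish("{VM | chocolate}")
    assert not ground_check(sol, vending_kb)


def test_unreachable_goal_has_only_the_identity(vending_kb):
    # nothing produces a dollar
    sols = backward_search(
        vending_kb, parse_dish("{VM | dollar dollar}"), max_depth=2
    )
    assert [s.depth for s in sols] == [0]


# ---------------------------------------------------------------------------
# backward search on the EGF model


def test_egf_backward_second_solution_is_one_step_back(egf_kb):
    start = egf_kb.dishes["EgfDish"]
    goal = Dish.of(
        {"CLi": Soup.of(Complex.of(Entity("Hras"), Entity("GTP")), var="rest")},
        var="drest",
    )
    final = forward_search(egf_kb, start, SearchGoal(pattern=goal))[0].final_dish
    sols = backward_search(egf_kb, final, max_depth=1)
    assert sols[0].depth == 0 and sols[0].accumulated_substitution.is_identity()
    assert sols[1].depth == 1 and len(sols[1].rule_path) == 1
    assert ground_check(sols[1], egf_kb)
    # undoing the load-switch reaction proposes a GDP-loaded Hras again
    undo_529 = next(s for s in sols if s.rule_path == ("529.Hras.irt.Egf",))
    assert Complex.of(Entity("Hras"), Entity("GDP")) in dict(
        undo_529.initial_pattern.soup("CLi").counts
    )


# ---------------------------------------------------------------------------
# property suites on random knowledge bases


@pytest.mark.parametrize("seed", range(50))
def test_narrowing_soundness_on_random_kbs(seed):
    """Every backward solution forward-replays from a ground instance."""
    kb, start = generate(GenConfig(seed=seed))
    # a goal built from a reachable state keeps the search meaningful
    mid = start
    for rule in kb.rule_list():
        succ = apply_rule(rule, mid, kb.sorts)
        if succ:
            mid = succ[0][0]
            break
    tag, soup = mid.locations[0]
    fixed = list(soup.terms())[:1]
    goal = Dish.of({tag: Soup.of(*fixed, var="v")}, var="d")
    for sol in backward_search(kb, goal, max_depth=2, max_solutions=12):
        assert ground_check(sol, kb), (seed, sol.depth, sol.rule_path)


@pytest.mark.parametrize("seed", range(10))
def test_narrowing_completeness_at_desk_scale(seed):
    """Every small ground state that forward-reaches the goal in <= 3 steps is
    an instance of some backward solution of equal depth."""
    kb, _start = generate(
        GenConfig(seed=seed, n_entities=2, n_locations=2, n_rules=2, max_rule_width=1)
    )
    entities = sorted(kb.entities)
    goal_entity = Entity(entities[0])
    goal = Dish.of({"L1": Soup.of(goal_entity, var="v")}, var="d")
    sols = backward_search(kb, goal, max_depth=3)
    soups = ground_soups(entities, 2)
    for s1, s2 in itertools.product(soups, soups):
        state = Dish.of({"L1": s1, "L2": s2})
        reached = forward_search(
            kb, state, SearchGoal(pattern=goal, min_steps=0, max_depth=3)
        )
        if not reached:
            continue
        depth = reached[0].depth
        assert any(
            sol.depth == depth and match(sol.initial_pattern, state, kb.sorts)
            for sol in sols
        ), (seed, canonicalize(state), depth)


def test_subsumption_filter_only_drops_instances(vending_kb):
    full = backward_search(vending_kb, APPLE_GOAL, max_depth=2)
    filtered = backward_search(vending_kb, APPLE_GOAL, max_depth=2, subsume=True)
    kept = [s.initial_pattern for s in filtered]
    kept_keys = {pattern_key(p) for p in kept}
    from dishsoup.narrowing import _pattern_instance_of

    for sol in full:
        if pattern_key(sol.initial_pattern) in kept_keys:
            continue
        assert any(
            _pattern_instance_of(sol.initial_pattern, p, vending_kb.sorts) for p in kept
        )
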