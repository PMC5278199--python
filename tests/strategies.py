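"""Hypothesis strategies for random terms, soups, dishes and substitutions."""

from __future__ import annotations

from hypothesis import strategies as st

from dishsoup import Complex, Dish, ElementVar, Entity, Modification, Soup, Substitution

ENTITY_NAMES = ["Aa", "Bb", "Cc", "Dd"]
SORT_TABLE = {"SortA": ["Aa", "Bb"], "SortB": ["Cc", "Dd"]}
MODS = [Modification("m1"), Modification("m2", "arg")]
TAGS = ["L1", "L2", "L3"]

entities = st.builds(
    Entity,
    st.sampled_from(ENTITY_NAMES),
    st.frozensets(st.sampled_from(MODS), max_size=2),
)

element_vars = st.builds(
    ElementVar,
    st.sampled_from(["x", "y", "w"]),
    st.sampled_from(sorted(SORT_TABLE)),
    st.frozensets(st.sampled_from(MODS), max_size=1),
)

complexes = st.builds(
    lambda parts: Complex.of(*parts),
    st.lists(entities, min_size=2, max_size=3),
)

ground_terms = st.one_of(entities, complexes)
terms = st.one_of(entities, complexes, element_vars)


def soups(term_strategy=ground_terms, with_var=False):
    var = st.sampled_from(["s1", "s2"]) if with_var else st.none()
    return st.builds(
        lambda ts, v: Soup.of(*ts, var=v),
        st.lists(term_strategy, max_size=3),
        st.one_of(st.none(), var) if with_var else st.none(),
    )


def dishes(term_strategy=ground_terms, with_vars=False):
    return st.builds(
        lambda pairs, v: Dish.of(dict(pairs), var=v),
        st.lists(
            st.tuples(st.sampled_from(TAGS), soups(term_strategy, with_var=with_vars)),
            max_size=3,
            unique_by=lambda p: p[0],
        ),
        st.sampled_from(["d1", None]) if with_vars else st.none(),
    )


ground_dishes = dishes()
pattern_dishes = dishes(terms, with_vars=True)

# element bindings are entities: a variable occurrence may carry modifications,
# and modifications cannot be attached to a complex
substitutions = st.builds(
    lambda e, s: Substitution(element=e, soup=s),
    st.dictionaries(st.sampled_from(["x", "y", "w"]), entities, max_size=2),
    st.dictionaries(st.sampled_from(["s1", "s2"]), soups(), max_size=2),
)
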