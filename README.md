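# dishsoup

Symbolic analysis of rule-based signaling models by multiset rewriting:
**forward** breadth-first reachability ("can this cell state evolve into one
where Hras is GTP-loaded, and through which reactions?") and a **backward
search based on narrowing** ("what are the most general initial states that
*cause* a given outcome?").

It is aimed at people who work with qualitative, rule-based pathway models
(in the style of Pathway Logic, Kappa or BioNetGen) and want executable
causality queries rather than simulation: curators checking that an encoded
reaction set supports a known phenotype, and modelers tracing which initial
conditions are actually required for it.

## The model

A cell state is a **dish**: a map from location tags (`XOut` extracellular,
`CLm`/`CLi` the plasma-membrane faces, `CLc` cytoplasm, `NUc` nucleus, ...)
to **soups** — multisets of molecular terms. A term is an entity (`Egf`), an
entity with a modification set (`[EgfR - Yphos]`, tyrosine-phosphorylated),
or a complex of bound terms (`[EgfR - Yphos] : Egf`; `Hras : GTP` for
nucleotide loading). Soup union and complex binding are
associative-commutative with identity `none`, so states are compared by a
canonical form, never by order of writing.

A reaction is a labeled rewrite rule `LHS ⇒ RHS` over dish patterns;
modifiers (enzymes, scaffolds) appear unchanged on both sides. Patterns may
contain sorted element variables (`gab:GabS` — "Gab1 or Gab2") and one
collection variable per soup standing for "the rest".

* **Forward search** starts from a ground dish and explores successors
  breadth-first (rule label order, deterministic match order, canonical-form
  deduplication), returning goal instances with their variable bindings and
  the rule-label path that replays to them.
* **Backward search** runs rules in reverse on *patterns*: each step unifies
  the current goal with a *topified* rule's RHS (the rule extended with
  fresh collection/dish variables so it applies at the top of the whole
  state term) and emits the instantiated LHS as a new, more-initial
  pattern. Unification modulo the multiset axioms assigns values to
  variables on the fly, so the result is the most general initial dish per
  narrowing branch, not a single concrete precursor.

Three curated EGF-response reactions ship as a fixture (receptor activation
`001.EgfR.irt.Egf`, Shp2 recruitment `188.Shp2.irt.Egf`, Hras GDP→GTP
exchange `529.Hras.irt.Egf`, with the initial state `EgfDish`), alongside
the classic vending-machine rewriting system (dollar → four quarters,
dollar → chocolate + quarter, two quarters → apple) and a seeded random-KB
generator for property testing.

## Worked example

```python
from dishsoup import (SearchGoal, backward_search, canonicalize,
                      egf_fixture, forward_search, parse_dish,
                      vending_fixture)

egf = egf_fixture()
goal = SearchGoal(pattern=parse_dish("{CLi | Hras : GTP rest:Things} d:Dishes"))
sol = forward_search(egf, egf.dishes["EgfDish"], goal)[0]
print(sol.depth, list(sol.path))

vm = vending_fixture()
for s in backward_search(vm, parse_dish("{VM | apple v:Things}"), max_depth=2):
    print(s.depth, canonicalize(s.initial_pattern))
```

prints

```
3 ['001.EgfR.irt.Egf', '188.Shp2.irt.Egf', '529.Hras.irt.Egf']
0 {VM | apple v:Things}
1 {VM | apple dollar z#1:Things}
1 {VM | quarter quarter z#1:Things}
2 {VM | apple dollar dollar z#2:Things}
2 {VM | dollar quarter quarter z#2:Things}
2 {VM | dollar z#2:Things}
2 {VM | dollar quarter z#2:Things}
2 {VM | quarter quarter quarter quarter z#2:Things}
```

The first line: from `EgfDish`, GTP-loaded Hras appears at the inner
membrane after exactly the three-reaction chain — ligand binding
phosphorylates the receptor, the active receptor complex recruits Shp2,
and only then can the nucleotide exchange fire. The backward trace reads:
an apple is "caused by" an apple already being there (0 steps), by two
quarters (1 step, the apple rule), or by just a dollar (2 steps) — each
pattern's trailing `z#k:Things` is the arbitrary rest of the soup, so each
line stands for the whole family of concrete states containing those items.
Every solution is validated by `ground_check`, which grounds the pattern
and replays the proposed rule path forward.

The same queries from the shell:

```sh
dishsoup forward-search --kb egf.json --dish EgfDish --goal hras_gtp.json
dishsoup backward-search --kb vm.json --goal apple.json --max-depth 2 --check
dishsoup gen-kb --seed 7 --out random_kb.json
```

(KBs and goals are plain JSON; `save_kb(egf_fixture(), "egf.json")` writes
the fixture. `--graph out.dot` exports the explored transition graph.)

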