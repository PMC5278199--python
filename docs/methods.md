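# Methods

## State model and canonical forms

A dish maps location tags to soups (multisets of terms); terms are entities
with a modification *set* (set semantics: `[EgfR - Yphos]` denotes a state,
not a count), complexes (flat multisets of ≥ 2 components — binding is
associative-commutative, so complexes of complexes are flattened one
level), and sorted element variables, which may themselves carry
modifications (`[gab:GabS - Yphos]`: some member of GabS in the
Yphos-marked state; its binding is the member with that marker stripped, so
substitution re-adds it). Soups hold at most one collection variable of the
universal sort `Things`; a dish holds at most one dish-level variable for
further unnamed locations.

Multisets are stored as counters keyed by the canonical string of the
member, iterated in lexicographic key order, which makes equality, hashing
and search-state deduplication `O(n log n)` and reproducible. The canonical
string is the single equality authority; it drops variable-free empty
locations (`none` is the identity of soup union, so `{CLo | none}`
contributes nothing), while rules structurally retain declared-empty
locations because the LHS/RHS location sets must coincide. `Hras : GDP`
nucleotide loading is an ordinary complex; no separate "load" operator is
introduced.

Variable namespaces are disjoint by kind (element / soup / dish); a single
shared counter generates fresh names, so renamings never collide across
kinds — topification and narrowing depend on that.

## Sorts

A sort denotes a set of entity names, by direct members and acyclic
subsorts, queried by transitive closure. Membership of a term follows its
base entity name and ignores modification state (a doubly-phosphorylated
Erks is still an ErkS); complexes belong only to `Things`. In the EGF
fixture: `ErkS`, `GabS = {Gab1, Gab2}` and `RasActS = {RasGrp3, Sos1}` sit
below `BProtein`, and `Things` contains every term.

## Forward semantics

Rule application is rewriting *below the top*: the LHS soup must match a
sub-multiset of the state's soup at each mentioned location; the remainder
and unmentioned locations pass through. Matching is multiset matching —
ground pattern members consume equal occurrences, element variables try
each candidate occurrence in canonical order (checking sort membership),
the collection variable absorbs the rest — yielding a duplicate-free,
deterministically ordered substitution list.

The search is plain BFS with a FIFO frontier; at one state rules apply in
lexicographic label order and matches in match order, so "the first
solution" is well defined. Visited states are pruned by canonical form,
which is what makes the vending machine terminate; a consequence is that
each distinct state is reported at most once, at its shallowest depth.
`min_steps` defaults to 1 (the at-least-one-step search mode); 0 also
accepts the start state. Goal conditions are conjunctions of
sort-membership tests on goal variables, nothing more general.

## Backward semantics (narrowing)

Narrowing needs rules that apply at the top of the whole state term, so
rules are first **topified**: every mentioned location gains one fresh
collection variable shared by LHS and RHS, and a fresh shared dish variable
covers unmentioned locations. Ground rewriting with the topified rule at
the top generates exactly the original transition relation — the package
keeps both routes (direct sub-multiset application, and exact match of the
topified LHS) and the test suite checks their equivalence on random
systems, so the transform is a genuinely cross-checked component rather
than an internal detail.

One backward step unifies the current goal pattern with a (freshly
renamed) topified rule's RHS and emits the instantiated LHS; substitutions
compose along the branch, and the rule path is kept in forward order.
Solutions are enumerated by nondecreasing depth, within a depth by (rule
label, unifier index); the depth-0 identity solution always comes first.
Subgoal patterns are deduplicated by a canonical key with variables renamed
in first-appearance order: branches that reproduce an already-seen pattern
(up to renaming) are neither re-emitted nor re-expanded. This is slightly
stronger than reporting every branch verbatim — equivalent proposals from
different rules collapse onto the first — and was chosen because duplicate
patterns carry no extra causal information and bloat the solution list.
The optional subsumption filter additionally drops patterns that are
instances of already-retained ones; its instance test freezes the specific
pattern's variables into rigid markers and is deliberately conservative (a
failed test retains the solution, never the other way around).

### The unification fragment

Full AC unification with repeated collection variables is exponential and
unnecessary for pathway-style rules, so the solver is restricted to the
shape the rules actually have: at most one collection variable per soup
per side, and sides renamed apart. The algorithm cancels syntactically
equal occurrences (sound and complete: multisets form a cancellative
monoid), then backtracks over pairing a remaining occurrence with one from
the other side versus absorbing it into the other side's collection
variable; when both sides carry a collection variable the two bindings
share one fresh remainder variable. Element variables unify syntactically
with sort meets; when two variables meet on incomparable sorts, no
intersection sort is invented — the finitely many shared members of the KB
vocabulary are enumerated instead, which is complete because a knowledge
base is a closed vocabulary. Modified variable occurrences unify by
pushing the symmetric difference of the modification sets onto a fresh
shared base variable. Occurs-checks guard element variables inside
complexes; collection variables cannot occur inside terms. Complexes unify
component-wise at equal sizes (a variable inside a complex never binds
another complex — flattening would change the component count).

Unifier sets are finished by renaming the fresh variables of each unifier
to a canonical sequence, so the returned list is deterministic and
duplicate-free.

### Validation of backward solutions

`ground_check` grounds a solution with one substitution applied to both
the initial pattern and the narrowed goal (collection/dish variables to
empty, element variables to the first member of their sort — the invariant
quantifies over *every* ground instance, so the smallest suffices) and
replays the solution's own rule path forward, requiring the goal instance
among the states after exactly `depth` steps. Replaying the path, rather
than re-running BFS, matters: BFS deduplication reports each state only at
its first depth and would reject sound cyclic solutions that return to an
already-visited state.

## Fixtures

The vending machine is encoded exactly as stated: one compartment, rules
dollar → four quarters, dollar → chocolate + quarter, two quarters →
apple.

The EGF fragment encodes the three published reactions and the initial
dish. The published dish truncates two locations ("and so forth"), so
`EgfDish` is the minimal closure supporting the chain: the named entities
per location, plus Shp2, Gab1 and Sos1 in the cytoplasm — Gab1 and Sos1 in
the tyrosine-phosphorylated state, because the nucleotide-exchange rule
requires `[gab:GabS - Yphos]` and a Yphos-marked RasGrp3/Sos1 and no rule
of the fragment produces those states. The "RasGrp3 or Sos1" prerequisite
reuses the sort idiom (`RasActS = {RasGrp3, Sos1}`) rather than
duplicating the rule; `[Shp2 - Yphos]` is required inside the receptor
complex, where the recruitment rule puts it, which forces the unique
three-step order 001 → 188 → 529. Pi3k is required in the cytoplasm, as
listed in the initial dish. Consequences: receptor activation and Shp2
recruitment conserve the entity census exactly; nucleotide exchange swaps
one GDP for one GTP (checked as a test).

## Synthetic knowledge bases

The generator emulates the *shape* of curated rule sets at toy scale:
entities with a small two-sort vocabulary, a few locations, rules that
conserve matter (relocation, modification toggles, modifiers listed on
both sides) except an occasional one-entity "transform" swap mirroring the
load-switch idiom. Defaults (4 entities, 2 locations, 3 rules, soup size
≤ 3, modifier/condition/transform probabilities 0.25) keep reachable state
spaces within a few hundred states so exhaustive oracles stay tractable; a
witness dish is built by instantiating every rule's LHS, so each rule is
applicable by construction, and identical config + seed reproduce the KB
byte for byte.

What the generator does **not** emulate: biologically realistic topology,
rule sparsity, or the scale of a curated knowledge base (hundreds of rules,
dozens of locations). Passing property suites therefore demonstrates
engine correctness — matching against brute-force enumeration, unifier-set
completeness against ground enumeration, topification equivalence,
narrowing soundness and desk-scale completeness — on small systems of the
right structural kind, not performance or biological adequacy at database
scale.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `SearchGoal.min_steps` | 1 | least rewrite depth for a solution (0 = accept start) |
| `SearchGoal.max_depth` / `max_solutions` | unbounded | search cut-offs; BFS guarantees minimal-depth first |
| `backward_search.max_depth` | 3 | narrowing horizon (each step is one rule undone) |
| `backward_search.subsume` | off | drop initial patterns that are instances of retained ones |
| `GenConfig.*` | see above | synthetic system size and rule-shape probabilities |

## Known limitations

* No modification-set variables: a pattern cannot say "any further
  modifications" on a single occurrence; goal patterns generalize via
  plain sorted variables (which match any superset of the listed marks).
* Conditions are sort-membership tests only; no general predicates, no
  conditional rules in the narrowing sense.
* Complex-complex unification requires equal component counts; collection
  variables cannot occur inside complexes.
* Variable-variable unification on incomparable sorts enumerates the KB
  vocabulary, so unifier sets are only meaningful relative to a closed
  entity vocabulary.
* No nested locations, stoichiometric rates, or continuous concentrations;
  no temporal-logic model checking.
* The EGF fixture is the three-rule published fragment; queries that need
  the full curated rule set (e.g. full Erk activation) are out of reach by
  construction.
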