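# Methods

## Model

A stoichiometric metabolic network is a directed bipartite graph
`(R ∪ M, E, s)` over reactions and metabolites with positive rational edge
labels (stoichiometric coefficients). The canonical in-memory form is
irreversible: an SBML-reversible reaction (attribute `reversible="true"`,
or an fbc lower bound < 0) is split into a forward/backward pair linked by
`reverse_of`, with the backward upper bound set to |lower bound| when
explicit bounds exist and to the forward bound otherwise. This matches the
flux formalism, which admits only non-negative fluxes (`0 ≤ v_r ≤ ub_r`)
and models reversibility through mirrored reaction pairs. Reactions with
no upper bound default to 1000 flux units (the conventional genome-scale
cap, configurable); fixtures default to 10.

Metabolite identity is the full compartment-qualified species id:
compartmental copies of a compound are distinct, which matters for real
models (e.g. periplasmic vs cytosolic water).

### Seeds and boundaries

Boundary seeds are structural: `S_b(G) = {m ∈ prds(r) | rcts(r) = ∅}`,
plus species flagged `boundaryCondition` in SBML (the second dialect for
the same idea). The seed set `S` defaults to `S_b(G)` extended by any
user-supplied medium list (replacement is available as an option). The
standing assumption throughout is `S_b(G) ⊆ S`.

### Scope semantics and boundary reactions

The scope `Σ(G, S)` is the least fixpoint of
`M0 = S; M_{i+1} = M_i ∪ prds({r | rcts(r) ⊆ M_i})`, computed with a
worklist over unmet-reactant counters (O(|E|) per closure; the breadth
wave count is reported as `iterations`). Self-loops follow the strict
recursive semantics: a reaction consuming and producing `m` fires only
once `m` is reachable by another route, so cycles are not self-initiating.

One deliberate choice: reactant-free boundary reactions take no part in
the closure. A literal reading (`∅ ⊆ M_i` always) would inject every
boundary compound into every scope, making seed-subset analyses vacuous;
since boundary availability is exactly what the seed set expresses, and
`S_b ⊆ S` makes the two readings coincide for any full seed set, the
closure excludes reactant-free reactions. The per-reaction test
`topologically_activated` keeps the literal `rcts ⊆ Σ` condition, so a
reactant-free reaction is always activated. This mirrors logic-program
encodings of network expansion, where seeds are facts and boundary
reactions are not expansion rules.

### Pruning

`prune(G, m)` removes `{r | m ∈ rcts(r)}` together with members of
reversible pairs producing `m` (whose partner consumes it), leaving the
metabolite set intact; a surviving direction whose partner was removed
loses its `reverse_of` link. Pruning is idempotent and can only shrink
scopes; both are property-tested.

## Flux problems

All flux analyses share one LP: variables are the irreversible reactions
in lexicographic order, box bounds `[0, ub_r]`, and one mass-balance
equality row per internal metabolite (products positive, reactants
negative). Boundary-condition species get no balance row; all other
metabolites, including products of reactant-free reactions, are balanced —
the reactant-free reaction itself supplies the influx that initiates flux.
LPs are solved with HiGHS via `scipy.optimize.linprog`; the fixed variable
ordering makes runs deterministic, and every classification decision
depends only on optimal values, never on which degenerate optimizer the
solver returns.

Tolerances: activation `ε_act = 1e-6` (a reaction is active when its
maximal flux exceeds this); essentiality uses a drop of more than
`δ_ess = 1e-6` absolute *and* a `ρ_ess = 1e-6` fraction of the base
optimum. These sit three orders of magnitude above typical solver noise
(~1e-9) and three below the smallest meaningful flux in the fixtures.

Knockouts fix `v_r = 0`; both directions of a reversible pair are knocked
out jointly (a gene deletion removes the enzyme, not one direction), and
an essential pair contributes the substrates of both directions to the
optimal-efficiency set. FVA minimizes/maximizes one flux over the
polytope, optionally pinned to the target optimum (lower bound
`μ*·(1 − 1e-9)` to absorb solver noise); knockout essentiality and
min-flux-positive-at-optimum are equivalent characterizations and are
tested as such on every fixture.

Thermodynamically infeasible loops are *not* excluded (no loop law): a
mass-creating or futile cycle that the stoichiometry admits is honored
exactly as written, which is essential to the semantics — the divergence
between graph-based and flux-based producibility on self-activated cycles
is a finding, not an artifact.

## PEM classes

- **sustainability**: `m ∉ S ∪ rcts(r_T)`, target topologically activated
  in `G` but not in `prune(G, m)`. Candidates are restricted to compounds
  in `Σ(G, S)` that are reactants of at least one reaction (compounds
  outside that set can never qualify: pruning w.r.t. an out-of-scope or
  never-consumed compound leaves the scope unchanged). Enumeration is
  per-candidate scope recomputation — correctness-first; the single-pass
  declarative formulation is an optimization with identical semantics and
  is covered instead by a brute-force equivalence test over an exhaustive
  family of tiny networks and seeded random networks.
- **producibility**: same exclusion, with stoichiometric activation
  (`max v_rT > ε_act`) replacing topological activation; one LP per
  candidate. This covers both substrates of single lethal reactions and
  jointly-lethal multi-reaction consumption.
- **optimal efficiency**: substrates of reactions whose knockout lowers
  `max v_rT`. Implemented literally, with no seed/target exclusion; the
  classification exposes `filter_roles` as an optional consistency filter,
  and reporting uses role precedence seed > target > PEM > other so a
  seed qualifying under the literal criterion is reported as a seed.

If the target is not activated in the unpruned network, the pruning-based
enumerations raise (naming the missing reactants / the zero optimum)
rather than silently returning the empty set; `classify` converts that
into a partial classification with recorded warnings.

## Reporting

The three sets are merged into a 7-region Venn partition per metabolite
(`S-only … SPO`, `none`); region counts always sum to the union size.
Summaries report counts and percentages over the metabolite total, with
reactions counted as biological reactions (reversible pairs collapsed) —
the same collapsed convention used for connectivity degrees. The
degree/role table bins compounds by connectivity (`[e_i, e_{i+1})`, last
bin closed) against roles {PEM, seed, target, other}; cross-model skeleton
comparison requires an explicit id mapping per model (no automatic name
reconciliation — compartment suffixes and namespace drift make silent
matching unsafe) and returns the compounds that are SPO in every model.

## Fixtures: what they emulate, and what they do not

The built-in networks are minimal mechanisms, built so that each published
Venn region has a deterministic witness:

- `fig1` — two branches (a linear seed branch and a nutrient-driven cycle
  with a 2:1 stoichiometric gain feeding the target); exercises scope
  restriction to seed subsets and the mass-balance collapse of the cycle
  (`v7 = v8 = 0`, zero target flux) when one nutrient supply is shut.
- `fig2` / `fig2_bounds` — the classification showcase. A single entry
  metabolite (SPO witness), a co-product coupled to every route into the
  target (PO witness), and a two-route bottleneck whose direct route is
  capped at ub 1 (versus the default 10) in the `_bounds` variant, turning
  the high-capacity route's substrates into optimal-efficiency-PEMs. The
  uncapped variant keeps all bounds at the default 10 and uses a 2:1
  stoichiometric loss on the bypass instead of a bound asymmetry.
- `fig4` — two parallel single reactions from one compound, jointly but
  not singly required (SP-only witness).
- `fig5` — an import route and an internal route where only the internal
  route co-satisfies a second target requirement whose direct supply is
  scarce (ub 1): its intermediates are O-only witnesses.
- `fig6_motif` — a self-activated cycle producing the target compound with
  a nine-intermediate linear initiation pathway that carries zero flux at
  steady state: S-only witnesses (pathway length configurable).
- `fig7_motif` — a main route (capacity 10) plus a seed-disconnected
  internal cycle (capacity 5): an SO witness whose knockout halves the
  optimum.
- `fig8_motif` — a target precursor whose synthesis co-produces a
  compound with two redundant exports: P-only witness.
- `chain_n`, `random_small` — parametric chain and seeded random networks
  for property tests and oracle-agreement rates.

These fixtures reproduce mechanisms, not organisms: they lack
compartments, cofactor coupling, and realistic degree distributions, so
passing tests demonstrate the correctness of the semantics and their
divergences, not genome-scale biology. Genome-scale models (SBML + an
explicit medium) run through the same code paths via `pemnet run`, at a
cost of one scope recomputation and one LP per candidate metabolite plus
one LP per reaction knockout; expect minutes to an hour per thousand
reactions on one CPU.

## Verification strategy

Every computational claim in the docs is recomputed by the test suite or
`scripts/acceptance.py`, never asserted from memory. Independent oracles:
a repeat-until-stable naive closure (against the worklist fixpoint), a
per-candidate brute-force sustainability enumeration (against the
candidate-restricted enumeration, over an exhaustive family of ≤6-reaction
networks and seeded random networks), a vertex-enumeration LP maximum on
tiny integer-bounded networks and a cobra-built FBA model (against the
HiGHS LP), and hand-solved bottleneck chains. Problem sizes in the default
suite are 3–14 reactions per network and ≤ 256 generated networks per
property, chosen so the whole suite runs in seconds while still covering
every branch of the pruning/scope/essentiality logic.

## Known limitations

- Optimal-efficiency enumeration solves one LP per reaction; no
  warm-starting or deletion-set reduction is attempted.
- The declarative single-pass sustainability computation is not bundled;
  the fixpoint engine carries the equivalent contract (oracle-tested).
- No parsimonious or loopless FBA, no shadow prices/reduced costs, no
  gene–protein–reaction logic: compounds, not genes, are classified.
- Exact reproduction of published genome-scale counts depends on the
  exact SBML dialect and growth-medium configuration of those models;
  diverging boundary/bound interpretations should be compared via the
  boundary-seed list and the per-reaction bound table before comparing
  PEM counts.
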