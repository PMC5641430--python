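# pemnet

Classification of **phenotypic essential metabolites (PEMs)** in
stoichiometric metabolic networks.

Genome-scale metabolic models are usually interrogated reaction-by-reaction
(essential genes, essential reactions, minimal cut sets). `pemnet` instead
asks which *internal compounds* a growth phenotype hinges on: a metabolite is
phenotypically essential when removing the network's ability to **consume**
it changes the activation of a targeted reaction `r_T` (typically biomass).
Because "activation" means different things under different modeling
formalisms, the package classifies each compound under three semantics and
compares them:

| class | formalism | criterion |
|---|---|---|
| sustainability-PEM | graph (network expansion) | `r_T` is topologically activated from the seeds `S` in `G` but not in `prune(G, m)` |
| producibility-PEM | steady-state flux (FBA) | `r_T` carries flux in `G` but not in `prune(G, m)` |
| optimal-efficiency-PEM | optimal flux (FBA/FVA) | `m ∈ rcts(r0)` for some reaction `r0` whose knockout lowers `max v_rT` |

Here `prune(G, m)` removes every reaction with `m` among its reactants
(including the reverse direction of reversible reactions producing `m`), the
*scope* `Σ(G, S)` is the least fixpoint `M0 = S`,
`M_{i+1} = M_i ∪ prds({r | rcts(r) ⊆ M_i})`, and flux vectors satisfy
`0 ≤ v_r ≤ ub_r` with steady-state mass balance
`Σ s(r,m)·v_r − Σ s(m,r)·v_r = 0` for every internal metabolite.
The two pruning-based classes exclude seeds and target reactants
(`m ∉ S ∪ rcts(r_T)`); the optimal-efficiency class is a single-reaction
criterion with no such exclusion, which keeps the three classes logically
independent. The overlaps of the three sets define a 7-region Venn partition
whose regions are diagnostic of network structure: redundant parallel
pathways (SP-only), self-activated cycles needing graph-side initiation
(S-only), co-product export coupling (P-only), optimal pathway choice
(O-only), seed-disconnected internal cycles (SO).

## Worked example

The built-in `fig2` fixture is a seven-metabolite showcase network: a single
entry `S → E`, two routes from `E` to the precursor of the target compound
`C`, and a co-product `G` emitted by both `C`-producing reactions and
removed by a single export.

```sh
pemnet fixtures export --name fig2 --out fig2.xml
pemnet run --sbml fig2.xml --target r_T --out fig2_out --venn
```

stderr log:

```
INFO pemnet: parsed fig2.xml: 7 metabolites, 10 reactions (10 after splitting), 1 seeds
INFO pemnet: seed scope: 7 metabolites, 9 activated reactions (4 closure rounds)
INFO pemnet: max target flux: 10
INFO pemnet: classified 4/7 metabolites as PEMs (S=1, P=2, O=4) -> fig2_out
```

`fig2_out/summary.tsv`:

```
quantity	count	percent_of_metabolites
reactions	10
metabolites	7
pems	4	57.1
sustainability_pems	1	14.3
producibility_pems	2	28.6
optimal_efficiency_pems	4	57.1
```

Reading `fig2_out/classification.tsv`: `E` is SPO (its single consumer is
the only way into the network, under every semantics); `G` is PO (pruning
its export makes it accumulate, which graph semantics ignores but mass
balance forbids); the seed `S` and target reactant `C` appear in the
optimal-efficiency column only (the literal single-reaction criterion
applies no role exclusion — pass `--filter-roles` to remove them). Running
the `fig2_bounds` variant, which caps the direct route (`ub_r7 = 1` versus
10 for `r1`/`r8`), additionally makes `B` an optimal-efficiency-PEM: the
optimum must then run through `B`, although producibility and graph
reachability never depend on it.

The same pipeline runs on any SBML Level 2/3 model
(`pemnet run --sbml MODEL.xml --target BIOMASS_...`), with boundary seeds
detected structurally (products of reactant-free reactions plus
boundary-condition species) and optionally extended or replaced by a medium
file (`--seeds medium.txt`, one metabolite id per line).

## Library use

```python
from pemnet import make_fixture, classify

fx = make_fixture("fig2")
cl = classify(fx.network, fx.seeds, fx.target)
print(sorted(cl.sustainability))   # ['E']
print(cl.venn_region("G"))         # 'PO'
```

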