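# routenet

Template-based enumeration of hybrid chemical synthesis routes: expand a
reaction network from SMARTS-encoded rules, search it for every multi-step
pathway from feedstocks to a target, and rank the pathways by weighted,
normalized criteria.

`routenet` is for synthetic chemists, biotechnologists and process modelers
who want to explore what can be made from a given feedstock slate — or how a
target might be reached — using both chemical/chemocatalytic and enzymatic
transformations in one network, with cofactors handled automatically.

## What it computes

**Network expansion.** Reaction rules are reaction SMARTS templates with
metadata (type, stoichiometry, salt flag, thermo correction, cofactor slots
for enzymatic rules). Expansion applies every rule to every compatible
molecule tuple, level by level (*generations*), forward from starters,
backward from targets via reversed rules, or both combined. Helper molecules
(H2O, O2, H2, CO, HCl, Cl2) react with everything but each other. Composable
filters (AND/OR/NOT over predicates such as `enthalpy_below(40)` or
`max_heavy_atoms(20)`) prune molecules and reactions during expansion.

**Thermochemistry.** Reaction enthalpies come from Benson group additivity:
ΔHf°(gas, 298 K) = Σ group contributions + ring corrections, with one group
per polyvalent heavy atom (e.g. ethanol = C-(C)(H)₃ + C-(C)(O)(H)₂ +
O-(C)(H)). The estimator is pluggable, so an external free-energy calculator
can stand in.

**Pathway search.** Reactions take several reactants, so a route is a
cycle-free *set* of reactions — with forks and parallel branches — in which
every reactant is a feedstock, a helper, or the product of an earlier
member. The backward search enumerates all such sets exhaustively up to step,
depth and atom-economy limits, resolving hardest-to-make molecules first.
Each pathway gets a net reaction (minimal integer combination cancelling
intermediates, cofactors excluded) and an atom economy
AE = MW_target / Σ νᵢ·MWᵢ over net products.

**Ranking.** Eight criteria — worst step enthalpy, step count, by-product
number (one-generation expansion of the pathway "soup"), atom economy, salt
score, database-hit percentage, reaction-type preference, profitability
index — are min-max normalized (1 = best), weighted and summed:
Score_i = Σⱼ Score_ij · Weight_j. Only weight ratios matter. A grid sweep
over the weight simplex quantifies rank sensitivity.

## Worked example

Find and rank routes from ethene to acetic acid with water and hydrogen as
helpers, a 40 kcal/mol step-enthalpy filter, two forward and one retro
generation:

```python
import routenet as rn
from routenet.expand import ExpansionConfig, expand
from routenet.thermo import BensonModel
from routenet.ranking import (RankingContext, criterion_values,
                              normalize_and_rank, DEFAULT_WEIGHTS)

rules = rn.fixtures.demo_rules()
benson = BensonModel()
net = expand(ExpansionConfig(
    strategy="combined", generations=2, retro_generations=1,
    rules=rules, starters=["C=C"], helpers=["O", "[H][H]"],
    targets=["CC(=O)O"], thermo=benson, filters="enthalpy_below(40)",
))
pathways = rn.find_pathways(net, "CC(=O)O", ["C=C"], ["O", "[H][H]"],
                            rn.SearchLimits(max_steps=4, max_generations=4))
ctx = RankingContext(network=net, rules=rules, thermo=benson)
values = {p.key: criterion_values(p, ctx) for p in pathways}
table = normalize_and_rank(values, DEFAULT_WEIGHTS)
```

Output:

```
network: 17 molecules, 16 reactions
pathways to acetic acid: 1
rank 1  total 0.900  steps 3  max_dH +16.9  AE 0.937  byproducts 12
steps of the top pathway:
  C=C + O -> CCO   (hydration of alkenes, dH -10.9 kcal/mol)
  CCO -> CC=O + [H][H]   (dehydrogenation of alcohols, dH +16.9 kcal/mol)
  CC=O + O -> CC(=O)O + [H][H]   (oxidation of aldehydes to acids, dH -6.3 kcal/mol)
```

Reading it: the only route surviving the limits is hydration → alcohol
dehydrogenation → aldehyde oxidation. Its hardest step costs +16.9 kcal/mol,
its net reaction keeps 93.7% of the product mass in acetic acid (the rest
leaves as H2), and a one-generation expansion of all species in the route
finds 12 possible side products under the demo rules. With the default
weights (steps 0.4, thermodynamics 0.2, by-products 0.2, atom economy 0.1)
that totals 0.900 of a possible 0.9 — trivially rank 1 here, informative
once several routes compete.

The same run from the shell:

```bash
routenet run --config config.yaml --seed 1 --out-dir out/
```

writes `net.json`, `paths.json`, `ranking.json`, per-pathway Graphviz dot
graphs (database-reported steps highlighted in blue) and a manifest. Each
stage also exists as its own subcommand (`expand`, `paths`, `rank`,
`report`, `fixtures`) operating on the JSON artifacts, so `expand` can serve
as a one-step reaction generator inside custom search strategies.

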