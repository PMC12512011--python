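# Methods

This note documents the models and algorithms implemented in `routenet`, the
assumptions behind them, the numerical choices, and what the packaged
fixtures do and do not demonstrate.

## Molecular identity

Every molecule is keyed by a canonical SMILES with stereochemistry stripped.
Reaction templates are constitutional (they match and rewrite molecular
graphs, not configurations), so two stereoisomers produced by the same
template would otherwise appear as duplicate network nodes. Ions are
represented in molecular form (Cl⁻ as HCl, etc.), and molecules are stored
neutral. Reaction identity is the rule id plus the sorted reactant and
product multisets; symmetric template matches therefore collapse to a single
reaction, and the same transformation discovered by forward and by retro
expansion has the same key.

Synthetic benchmark networks (the planted-pathway generator) use opaque
molecule keys with explicitly assigned masses instead of structures. This is
deliberate: pathway search and ranking are pure hypergraph/stoichiometry
algorithms, and testing them against ground truth should not depend on any
chemistry-toolkit behavior.

## Reaction rules

Rules are reaction SMARTS with atom maps, applied with RDKit. A rule carries
metadata: kind (chemo vs enzymatic), direction, per-slot stoichiometry, an
additive enthalpy correction in kcal/mol (default 0), a salt-formation flag
(set only on nitrogen/sulfur chemistry in the demo set), a reaction-type
label used by the "coolness" criterion, cofactor lists, provenance text, and
a mass-balance flag.

Application semantics: every template match is enumerated and the outcomes
are collapsed by canonical product multiset, so one reaction per distinct
outcome. Product sets that fail sanitization are dropped and logged. A
per-rule cap (256 distinct outcomes) guards pathological symmetric
substrates; truncation is deterministic in canonical product order.
Bimolecular templates bind distinct tuple positions; the same species may
occupy both positions (e.g. ether condensation of two ethanol molecules).

Chemo rules are written mass-balanced: co-substrates such as water or H2
appear explicitly in the template, so elemental balance and atom economy are
exact. Reversal swaps the template sides, toggles the direction, negates the
enthalpy correction and swaps the cofactor lists; it is an involution.

Enzymatic rules transform only the primary substrate in the template; the
currency couple is attached at application time (`resolve_cofactors`):
`cofactors_in` joins the reactant multiset and `cofactors_out` joins every
generated product multiset, and the attached species carry the `cofactor`
role. The demo set uses simple, real currency couples chosen so the overall
reaction is exactly balanced: a benzoquinone/hydroquinone couple for the
dehydrogenase rule, dimethyl sulfide/methanethiol as a methyl-donor analogue
of the SAM/SAH couple, and alanine/pyruvate for the transaminase. They are
analogues — small enough to reason about, with the same bookkeeping as the
biological cofactors they stand in for.

The demo rule set (30 rules) covers hydrogenation/dehydrogenation,
hydration/dehydration, ether/ester/amide hydrolysis and condensation,
alcohol/aldehyde oxidation, substitutions at carbon (amination,
chlorination, arene alkylation), decarboxylation, hydroformylation, alkene
isomerization, sulfur chemistry, and the three enzymatic rules. It is a
demonstration set: broad enough to exercise every engine feature, far too
small to be a production rule library, and user rule files in the same JSON
(or TSV) dialect replace it freely.

## Benson group-additivity thermochemistry

Gas-phase ΔHf at 298 K is the sum of one group contribution per polyvalent
heavy atom plus ring-strain corrections. Group signatures encode the
center's class — `C` (sp3), `Cd` (double-bonded, partner implicit), `Ct`
(triple), `CB` (aromatic, ring neighbors implicit), `CO` (carbonyl, oxygen
implicit), or the heteroatom symbol — and the sorted classes of its
remaining neighbors with hydrogens folded in. Ethanol decomposes to
`C-(C)(H)3 + C-(C)(O)(H)2 + O-(C)(H)` = −10.2 − 8.1 − 37.9 = −56.2 kcal/mol
(experimental −56.2).

The shipped table (CSV, user-replaceable) carries published values for
alkane/alkene/aromatic/carbonyl carbon, alcohol/ether/acid/ester oxygen,
amine/amide nitrogen, thiol/sulfide sulfur and C–Cl groups, ring strain for
3-, 4- and 5-membered carbocycles only, and a fixed molecular table for
species with no polyvalent-center decomposition (H2O −57.8, HCl −22.06,
CO −26.42, CO2 −94.05, NH3, H2S, ...). Elements in their reference state are
zero by definition. Known approximations: no gauche/ortho/cis corrections,
no entropy or heat capacity, gas phase only. The worked check: ethylbenzene
(6.95) → styrene (35.22) + H2 (0) gives ΔH = +28.3 kcal/mol, matching the
textbook value of ~28.5 for the styrene process within the table's accuracy.

A reaction enthalpy is Σproducts − Σreactants (stoichiometry-weighted) plus
the rule's additive correction, which we interpret as a per-rule offset in
kcal/mol (e.g. to absorb a known systematic error of a rule family). A
molecule containing a group without table coverage yields "unavailable"
(`None`), never a silent zero. The estimator sits behind a one-method
`ThermoModel` contract so an external calculator (e.g. an aqueous ΔG′°
service) can replace it in filters and ranking; enthalpy-based filtering
*passes* reactions with unavailable endpoints and logs them, so
thermochemistry remains optional.

## Network expansion

Expansion is level-wise. Generation g applies every rule to every
arity-compatible ordered tuple of network molecules containing at least one
molecule first seen in generation g−1 (starters and helpers seed generation
1) and at least one non-helper — helpers (water, O2, H2, CO, HCl, Cl2 in the
packaged roster) react with everything except each other. Both orderings of
asymmetric bimolecular tuples are tried; reaction identity collapses the
symmetric duplicates. A molecule's generation is the level of first
appearance and never updates.

Filters form a predicate tree (AND/OR/NOT, short-circuit) over two scopes:
molecule predicates (`max_heavy_atoms`, `max_mw`, `allowed_elements`,
`generation_cap`) gate admission of new molecules — and, via a separately
configurable second hook, membership in the next reactive set — while
reaction predicates (`enthalpy_below`, `no_new_rings`) gate reactions. A
rejected product molecule rejects its reaction, preserving referential
closure. The textual spec `and(enthalpy_below(15), max_heavy_atoms(20))`
parses to the same tree as the programmatic constructors, and the registry
is user-extensible.

Retro expansion applies the reversed rules starting from the targets but
stores each generated reaction in its forward (synthesis) orientation under
the forward rule id. Consequences: reaction filters judge the synthesis
direction (the direction the enthalpy threshold is meant for), a reaction
found by both directions deduplicates to one entry, and the combined
strategy is a plain keyed union (`merge_networks`) of one forward and one
retro run. Retro generations are stored as negative offsets from the target
so the two directional depths remain distinguishable after merging.

Everything iterates in sorted order, so a fixed config yields a
byte-identical serialized network. Caps on molecule/reaction counts truncate
deterministically with a logged warning and a provenance marker.

## Pathway search

Because reactions take multiple reactants, a route is not a walk but a
proof: a cycle-free reaction set in which every reactant of every member is
a starter, a helper, or a product of an earlier member, and the target is
produced. Routes to each reactant are integral to the route to the target,
so forks and parallel branches are normal, and two pathways are the same iff
they use the same reaction set.

The search runs backward from the target. A state is a partial producer
assignment plus the list of demanded-but-unresolved molecules. The
unresolved molecule with the fewest producers is resolved first (ties
lexicographic) — synthetically hard molecules prune earliest — branching
over all of its producer reactions; children of the latest expansion are
explored first (LIFO), siblings remain queued. A producer is inadmissible
when one of its reactants is an ancestor of the molecule being resolved,
which keeps accepted assignments acyclic. Helpers and starters never need
producers. Completed assignments are deduplicated by reaction set.

Limits: `max_steps` bounds the number of distinct reactions; the generation
limit bounds the *structural depth*, defined as the longest chain in the
reaction-precedence DAG (r precedes r′ when a product of r is a reactant of
r′); `min_atom_economy` is enforced on the completed pathway's net reaction.
We deliberately do not prune partial pathways on atom economy: the seemingly
safe bound ("later steps only add by-products") is unsound, because a later
producer can consume an already-committed by-product and raise the net AE.
Enforcing AE at completion keeps the search exactly equivalent to exhaustive
enumeration under identical limits, which the test suite verifies on 100+
seeded random networks against an independent brute-force oracle.

The net reaction multiplies member reactions by minimal positive integers
such that every molecule that is both produced and consumed within the
pathway has nonnegative net production (a small integer program; surplus
becomes a net by-product, and infeasibility raises a stoichiometric
inconsistency error). Cofactor-role species are removed from both sides —
they are recycled. Atom economy is the mass of one desired copy of the
target divided by the stoichiometry-weighted mass of all net products.

## Ranking

Eight criteria per pathway: maximum step enthalpy (worst step), number of
steps, pathway by-product number, atom economy, salt score (count of
salt-forming steps), database-hit percentage, coolness (sum of user weights
over the member reactions' type labels), and profitability index
(price·mass of net products over price·mass of net feedstocks). The pathway
by-product number merges all feedstocks, intermediates and products into a
soup, runs one expansion generation with the rules of interest, and counts
distinct new molecules; the intermediate by-product number repeats this once
per intermediate with only that intermediate reactive and sums the counts —
it is reported as a reactivity indicator but carries zero weight by default.

Each weighted criterion is min-max normalized across the pathway set,
oriented so 1 is always best (benefit criteria score (v−min)/(max−min), cost
criteria (max−v)/(max−min)); a degenerate criterion (max = min) scores 1.0
for everyone, which is rank-neutral. Totals are Σ score·weight; weights need
not sum to anything — only ratios matter, and positive rescaling provably
preserves the ranking. A pathway with an unavailable value (e.g. no price
for a net species) is excluded from that criterion's normalization and gets
no contribution from it. Ties break by fewer steps, then higher atom
economy, then pathway key. Default weights: steps 0.4, thermodynamics 0.2,
by-products 0.2, atom economy 0.1, all others 0.

The sensitivity sweep evaluates every composition of the weight simplex over
2–5 selected criteria at a fixed step (3 criteria at step 0.1 gives
C(12,2) = 66 grid points), recomputing ranks at each point; the output is
ternary-plot-ready.

## Reporting

Graphviz dot text is the canonical rendering (bit-stable, golden-file
testable): molecules as boxes, each reaction as a labeled node joining its
reactants to its products, database-reported reactions and their edges in
blue (configurable). SVG/PDF rendering is delegated to a `dot` executable
when one is on PATH; otherwise the dot text stands, with a warning.
`export_run` writes net.json, paths.json, ranking.json, the report files and
a manifest carrying a config hash, the seed and per-generation counts.

## Synthetic planted networks

The generator grows each planted pathway backward from the target — every
demanded molecule gets a dedicated fresh producer whose reactants are
starters, a helper, or new intermediates, with occasional undemanded
co-products — then pads the network with randomly wired distractor
reactions. Guarantees: reproducible per seed; every planted pathway is a
valid DAG pathway within the network with a consistent net reaction; masses
are assigned so atom economy is well defined. Not guaranteed (and not
intended): statistical realism, mass balance of pseudo-reactions, or that
the planted list is exhaustive — distractors create additional legitimate
pathways, which is exactly what the oracle-equivalence tests measure.

What passing on these fixtures shows: the search, stoichiometry and ranking
machinery are exact on networks whose ground truth is enumerable. What it
does not show: behavior at the scale of production rule sets (hundreds of
rules, 10⁵–10⁶ molecules), where memory and combinatorics dominate; the
packaged problem sizes (tens of molecules, ≤15 reactions per benchmark
instance, 100+ instances) were chosen so ground truth stays computable by
brute force.

## Numerical and degenerate-input choices

- Unestimable ΔHf → reaction enthalpy unavailable → thermo filter passes,
  ranking marks the criterion unavailable.
- max = min in normalization → constant score 1.0.
- All-zero weights → error, raised before any expensive stage runs.
- Net-reaction integer program: minimize Σν with ν ≥ 1; solutions are
  reduced by their gcd; infeasible → error, the pathway is dropped from
  search results.
- Deterministic tie-breaks everywhere: sorted molecule keys, sorted reaction
  keys, lexicographic pathway keys; truncations (match cap, network caps,
  pathway cap) always operate on sorted order and are logged/flagged.
- The pipeline seed is recorded in provenance and the manifest; at shipped
  scale no stage actually samples, so identical configs are byte-identical
  regardless of seed, and the seed matters only to the synthetic-network
  generator.

## Known limitations

- The demo rule set is illustrative; real studies need curated rule
  libraries and the thermo table extended to their chemistry.
- Benson v1 omits gauche/ortho corrections and non-3–5 ring strain; aromatic
  heterocycles are unparameterized (they fall back to "unavailable").
- Exhaustive pathway enumeration is exponential in the worst case; the
  limits (steps, depth, AE, pathway cap) are the only defense, as in any
  complete enumerator.
- The profitability index ignores catalyst and operating costs by design.
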