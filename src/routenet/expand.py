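"""Iterated rule application: forward, retro, and combined network expansion.

Expansion is level-wise: generation g applies every rule to every
arity-compatible tuple of molecules that includes at least one molecule first
seen in generation g-1 (starters and helpers seed generation 1). Helper
molecules — common co-reagents like water, O2 or H2 — react with starters,
targets and intermediates but never with each other, so all-helper tuples
are excluded.

Retro expansion applies the reversed rules starting from the targets, but
stores every generated reaction in its forward (synthesis) orientation, so a
retro-discovered reaction has the same identity as the forward-discovered
one and merged combined networks are coherent inputs for pathway search.
Retro-side generations are recorded as negative offsets from the target to
keep the two directional depths distinguishable after a merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product as iproduct

from routenet import chem
from routenet.filters import AcceptAll, EvalContext, FilterExpr, build_filter
from routenet.model import Molecule, Network, Reaction
from routenet.rules import ReactionRule, apply_rule, reverse_rule
from routenet.thermo import ThermoModel

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class ExpansionConfig:
    strategy: str  # {"forward", "retro", "combined"}
    generations: int
    rules: list[ReactionRule]
    starters: list[str] = field(default_factory=list)
    helpers: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    retro_generations: int | None = None  # combined mode: retro-side depth
    filters: FilterExpr | str | None = None  # admission hook (molecules + reactions)
    reactive_filter: FilterExpr | str | None = None  # next-reactive-set hook
    thermo: ThermoModel | None = None
    seed: int = 0
    max_molecules: int = 100_000
    max_reactions: int = 200_000

    def validate(self) -> None:
        if self.generations < 1:
            raise ConfigError("generations must be >= 1")
        if self.strategy not in ("forward", "retro", "combined"):
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.strategy in ("forward", "combined") and not self.starters:
            raise ConfigError(f"{self.strategy} expansion requires starter molecules")
        if self.strategy in ("retro", "combined") and not self.targets:
            raise ConfigError(f"{self.strategy} expansion requires target molecules")
        if self.strategy == "combined" and (self.retro_generations or 0) < 1:
            raise ConfigError("combined strategy requires retro_generations >= 1")
        if not self.rules:
            raise ConfigError("no reaction rules given")


def _flip(rxn: Reaction) -> Reaction:
    return Reaction(
        rule_id=rxn.rule_id,
        reactants=list(rxn.products),
        products=list(rxn.reactants),
        generation=rxn.generation,
    )


class _MatchCache:
    """Per-run cache of which molecules match each rule's reactant templates."""

    def __init__(self) -> None:
        self._match: dict[tuple[str, int, str], bool] = {}

    def matches(self, rule: ReactionRule, slot: int, key: str) -> bool:
        ck = (rule.rule_id + rule.template, slot, key)
        hit = self._match.get(ck)
        if hit is None:
            tmpl = rule.rxn.GetReactantTemplate(slot)
            try:
                mol = chem.mol_from_smiles(key)
                hit = mol.HasSubstructMatch(tmpl)
            except chem.ParseError:
                hit = False
            self._match[ck] = hit
        return hit


def one_generation(
    network: Network,
    rules: list[ReactionRule],
    filters: FilterExpr | None,
    reactive_set: set[str],
    *,
    generation: int = 1,
    flip: bool = False,
    cache: _MatchCache | None = None,
    max_molecules: int = 100_000,
    max_reactions: int = 200_000,
) -> tuple[set[str], set[str]]:
    """Apply every rule to every admissible tuple and fold results into
    ``network``. Returns (new reaction keys, new molecule keys).

    Tuples are drawn from the whole molecule store but must contain at least
    one member of ``reactive_set`` and at least one non-helper. With
    ``flip=True`` (retro mode) generated reactions are stored in reverse
    orientation and molecule generations as ``-generation``.
    """
    filters = filters or AcceptAll()
    cache = cache or _MatchCache()
    missing = reactive_set - set(network.molecules)
    if missing:
        raise ValueError(f"reactive set not in network: {sorted(missing)}")
    helpers = {k for k, m in network.molecules.items() if "helper" in m.roles}
    all_keys = sorted(network.molecules)

    new_rxn_keys: set[str] = set()
    new_mol_keys: set[str] = set()
    truncated = False
    for rule in rules:
        slot_candidates = []
        for slot in range(rule.arity):
            slot_candidates.append(
                [k for k in all_keys if cache.matches(rule, slot, k)]
            )
        for combo in iproduct(*slot_candidates):
            if not any(k in reactive_set for k in combo):
                continue
            if all(k in helpers for k in combo):
                continue
            for rxn in sorted(apply_rule(rule, combo, generation=generation), key=lambda r: r.key):
                if flip:
                    rxn = _flip(rxn)
                    rxn.generation = -generation
                if rxn.key in network.reactions:
                    continue
                candidates = sorted(
                    set(rxn.reactants + rxn.products) - set(network.molecules)
                )
                if any(not filters.admits_molecule(k) for k in candidates):
                    continue
                if not filters.admits_reaction(rxn):
                    continue
                if (
                    len(network.molecules) + len(candidates) > max_molecules
                    or len(network.reactions) >= max_reactions
                ):
                    truncated = True
                    break
                gen_label = -generation if flip else generation
                for k in candidates:
                    is_cof = rule.kind == "enzymatic" and (
                        k in rule.cofactors_in or k in rule.cofactors_out
                    )
                    network.add_molecule(
                        Molecule(
                            key=k,
                            roles={"cofactor"} if is_cof else {"intermediate"},
                            generation=gen_label,
                        )
                    )
                    new_mol_keys.add(k)
                # cofactors consumed from the rule side also need store entries
                network.add_reaction(rxn)
                new_rxn_keys.add(rxn.key)
            if truncated:
                break
        if truncated:
            break
    if truncated:
        log.warning(
            "expansion caps reached at generation %d (%d molecules, %d reactions); truncated",
            generation, len(network.molecules), len(network.reactions),
        )
        network.provenance.append({"truncated_at_generation": generation})
    return new_rxn_keys, new_mol_keys


def _directional_run(
    rules: list[ReactionRule],
    seeds: list[str],
    seed_role: str,
    helpers: list[str],
    generations: int,
    filters: FilterExpr | None,
    config: ExpansionConfig,
    flip: bool,
    context: EvalContext,
) -> Network:
    net = Network()
    for k in seeds:
        net.add_molecule(Molecule(key=chem.canonicalize(k), roles={seed_role}, generation=0))
    for k in helpers:
        net.add_molecule(Molecule(key=chem.canonicalize(k), roles={"helper"}, generation=0))
    reactive = set(net.molecules)
    context.generations.update({k: 0 for k in net.molecules})
    reactive_filter = build_filter(config.reactive_filter, context) if config.reactive_filter else AcceptAll()
    cache = _MatchCache()
    counts = []
    for g in range(1, generations + 1):
        _, new_mols = one_generation(
            net, rules, filters, reactive,
            generation=g, flip=flip, cache=cache,
            max_molecules=config.max_molecules, max_reactions=config.max_reactions,
        )
        for k in new_mols:
            context.generations[k] = -g if flip else g
        counts.append({"generation": -g if flip else g,
                       "molecules": len(net.molecules), "reactions": len(net.reactions)})
        log.info(
            "%s generation %d: %d molecules, %d reactions",
            "retro" if flip else "forward", g, len(net.molecules), len(net.reactions),
        )
        reactive = {k for k in new_mols if reactive_filter.admits_molecule(k)}
        if not reactive:
            break
    net.provenance.append({
        "strategy": "retro" if flip else "forward",
        "generations": generations,
        "seed": config.seed,
        "per_generation": counts,
    })
    return net


def expand(config: ExpansionConfig) -> Network:
    """Run a full expansion per ``config`` and return the network.

    Forward mode grows from starters (+helpers); retro mode applies reversed
    rules from the targets; combined mode merges one run of each. Molecule
    ``generation`` is the first level of appearance. Deterministic for a
    fixed config and seed.
    """
    config.validate()
    context = EvalContext(
        thermo=config.thermo,
        rules_by_id={r.rule_id: r for r in config.rules},
    )
    filters = build_filter(config.filters, context)

    fwd_net = retro_net = None
    if config.strategy in ("forward", "combined"):
        fwd_net = _directional_run(
            config.rules, config.starters, "starter", config.helpers,
            config.generations, filters, config, flip=False, context=context,
        )
        for t in config.targets:
            key = chem.canonicalize(t)
            if key in fwd_net.molecules:
                fwd_net.molecules[key].roles.add("target")
    if config.strategy in ("retro", "combined"):
        retro_rules = [reverse_rule(r) for r in config.rules]
        retro_gens = config.retro_generations if config.strategy == "combined" else config.generations
        retro_net = _directional_run(
            retro_rules, config.targets, "target", config.helpers,
            retro_gens, filters, config, flip=True, context=context,
        )
        for s in config.starters:
            key = chem.canonicalize(s)
            if key in retro_net.molecules:
                retro_net.molecules[key].roles.add("starter")

    if config.strategy == "forward":
        return fwd_net
    if config.strategy == "retro":
        return retro_net
    from routenet.model import merge_networks

    return merge_networks(fwd_net, retro_net)
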