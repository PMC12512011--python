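"""Packaged demo rule set, toy molecule lists, and planted-pathway networks.

The demo rule set is a ~30-rule cross-section of textbook C/H/O/N/S
transformations (hydrogenation/dehydrogenation, hydration/dehydration,
ether/ester/amide hydrolysis and condensation, oxidations, substitutions,
plus three cofactor-bearing enzymatic-style rules), each annotated with
stoichiometry, salt flag and balance flag. It is small enough to reason
about by hand yet exercises every engine feature.

:func:`planted_network` builds seeded synthetic reaction networks with known
embedded pathways. Synthetic molecules use opaque keys with assigned masses
rather than real structures, which isolates pathway-search and ranking
behavior from any chemistry-toolkit detail and provides exact ground truth
for search testing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

from routenet.model import Molecule, Network, Reaction
from routenet.pathways import Pathway, net_reaction, structural_depth
from routenet.rules import ReactionRule, load_rules


def _data_path(name: str):
    return resources.files("routenet.data").joinpath(name)


def demo_rules() -> list[ReactionRule]:
    """The packaged demo rule set, validated at load."""
    with resources.as_file(_data_path("demo_rules.json")) as p:
        return load_rules(p)


def demo_helpers() -> list[str]:
    """Water, O2, H2, CO, HCl, Cl2 — the classic helper roster."""
    return ["O", "O=O", "[H][H]", "[C-]#[O+]", "Cl", "ClCl"]


@dataclass
class PlantedNetwork:
    network: Network
    planted: list[Pathway]
    starters: list[str]
    helpers: list[str]
    target: str
    seed: int
    params: dict = field(default_factory=dict)


def planted_network(
    seed: int,
    n_molecules: int = 18,
    n_reactions: int = 12,
    max_arity: int = 2,
    planted_count: int = 2,
) -> PlantedNetwork:
    """Seeded random reaction network containing ``planted_count`` known
    pathways from the starters to a designated target.

    Reproducible per seed; every planted pathway satisfies the pathway
    invariants within the returned network. Distractor reactions are wired
    randomly, so the network generally contains additional valid pathways
    beyond the planted ones — the planted list is a guaranteed subset, not
    the full answer.
    """
    if planted_count < 1:
        raise ValueError("planted_count must be >= 1")
    if n_molecules < 6:
        raise ValueError("need at least 6 molecules")
    rng = random.Random(seed)

    net = Network()
    starters = [f"S{i}" for i in range(3)]
    helpers = ["HLP"]
    target = "TGT"

    def add_mol(key: str, roles: set[str]) -> None:
        net.add_molecule(
            Molecule(key=key, roles=roles, mw=round(rng.uniform(20.0, 200.0), 2))
        )

    for s in starters:
        add_mol(s, {"starter"})
    for h in helpers:
        add_mol(h, {"helper"})
    add_mol(target, {"target"})

    counter = 0

    def fresh_key() -> str:
        nonlocal counter
        key = f"I{counter:02d}"
        counter += 1
        add_mol(key, {"intermediate"})
        return key

    rxn_idx = 0

    def add_rxn(reactants: list[str], products: list[str]) -> str:
        nonlocal rxn_idx
        rxn = Reaction(rule_id=f"r{rxn_idx:02d}", reactants=reactants, products=products)
        rxn_idx += 1
        return net.add_reaction(rxn).key

    planted: list[Pathway] = []
    for _ in range(planted_count):
        # grow backward from the target: resolve each open molecule with a
        # fresh reaction whose reactants are starters/helpers or new
        # intermediates (forced terminal at the depth cap)
        keys: list[str] = []
        open_mols = [(target, 0)]
        max_depth = rng.randint(1, 3)
        while open_mols:
            mol, depth = open_mols.pop()
            n_react = rng.randint(1, max_arity)
            reactants = []
            for j in range(n_react):
                if depth + 1 >= max_depth or rng.random() < 0.5:
                    pool = starters + (helpers if j > 0 else [])
                    reactants.append(rng.choice(pool))
                else:
                    q = fresh_key()
                    reactants.append(q)
                    open_mols.append((q, depth + 1))
            products = [mol]
            if rng.random() < 0.3:
                products.append(fresh_key())  # co-product, never demanded
            keys.append(add_rxn(sorted(set(reactants)), sorted(set(products))))
        consumed = {m for k in keys for m in net.reactions[k].reactants}
        produced = {m for k in keys for m in net.reactions[k].products}
        pw = Pathway(
            reactions=_topo(keys, target, net),
            target=target,
            feedstocks=sorted(consumed - produced),
            depth=structural_depth(set(keys), net),
            net=net_reaction(keys, target, net),
        )
        planted.append(pw)

    # pad the molecule pool, then add distractor reactions
    pool = sorted(net.molecules)
    while len(net.molecules) < n_molecules:
        pool.append(fresh_key())
    pool = sorted(net.molecules)
    while len(net.reactions) < n_reactions:
        reactants = sorted(rng.sample(pool, rng.randint(1, max_arity)))
        products = sorted(
            rng.sample([m for m in pool if m not in reactants and m not in starters], 1)
        )
        add_rxn(reactants, products)

    # dedup can collapse planted pathways built identically by chance
    uniq: dict[str, Pathway] = {p.key: p for p in planted}
    return PlantedNetwork(
        network=net,
        planted=sorted(uniq.values(), key=lambda p: p.key),
        starters=starters,
        helpers=helpers,
        target=target,
        seed=seed,
        params={
            "n_molecules": n_molecules,
            "n_reactions": n_reactions,
            "max_arity": max_arity,
            "planted_count": planted_count,
        },
    )


def _topo(keys: list[str], target: str, net: Network) -> list[str]:
    produced_by = {m for k in keys for m in net.reactions[k].products}
    available = {m for k in keys for m in net.reactions[k].reactants} - produced_by
    remaining = dict.fromkeys(sorted(keys))
    order = []
    while remaining:
        for k in remaining:
            if all(m in available for m in net.reactions[k].reactants):
                order.append(k)
                available.update(net.reactions[k].products)
                del remaining[k]
                break
        else:
            raise AssertionError("planted pathway is cyclic")
    for k in order:
        if target in net.reactions[k].products:
            order.remove(k)
            order.append(k)
            break
    return order

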