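"""Backward multi-reactant pathway search over a reaction network.

A pathway is not a walk but a proof: because reactions take several
reactants, the routes to every reactant are integral to the route to the
target, so a pathway is a cycle-free set of reactions in which every reactant
of every member is a starter, a helper, or a product of an earlier member,
and the target is produced. Forks and parallel sub-branches are therefore
normal. Two pathways are the same iff they use the same reaction set.

The search starts at the target and recursively replaces each demanded
molecule with the reactants of one of its producer reactions, branching over
producers. Demanded molecules are resolved fewest-producers-first
(synthetically challenging molecules prune earliest); children of the most
recent expansion are explored first. A producer is inadmissible whenever one
of its reactants is an ancestor of the molecule being resolved, which keeps
every accepted pathway a DAG. Step, generation-depth, and atom-economy
limits prune the enumeration; helpers never need producers.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from pathlib import Path

import numpy as np
from scipy.optimize import LinearConstraint, milp

from routenet.model import Network, Reaction

log = logging.getLogger(__name__)


class PathwayError(ValueError):
    pass


class StoichiometryError(PathwayError):
    """No positive integer multiplier combination cancels the intermediates."""


@dataclass
class SearchLimits:
    max_steps: int = 10
    max_generations: int = 10
    min_atom_economy: float = 0.0
    max_pathways: int = 100_000

    def __post_init__(self) -> None:
        if self.max_steps < 1 or self.max_generations < 1 or self.max_pathways < 1:
            raise ValueError("search limits must be positive")
        if not (0.0 <= self.min_atom_economy <= 1.0):
            raise ValueError("min_atom_economy must be within [0, 1]")


@dataclass
class NetReaction:
    """Integer combination of a pathway's reactions with intermediates cancelled."""

    target: str
    net_reactants: dict[str, int]
    net_products: dict[str, int]
    multipliers: dict[str, int]  # reaction key -> positive integer

    def to_dict(self) -> dict:
        return {
            "reactants": dict(sorted(self.net_reactants.items())),
            "products": dict(sorted(self.net_products.items())),
            "multipliers": dict(sorted(self.multipliers.items())),
        }


@dataclass
class Pathway:
    """A DAG of reactions from feedstocks/helpers to one target."""

    reactions: list[str]  # reaction keys, topological order, target-producing last
    target: str
    feedstocks: list[str]  # consumed but never produced within the pathway
    depth: int
    net: NetReaction | None = None
    atom_economy: float | None = None

    @property
    def key(self) -> str:
        return "+".join(sorted(self.reactions))

    @property
    def n_steps(self) -> int:
        return len(self.reactions)

    def to_dict(self) -> dict:
        d = {
            "target": self.target,
            "reactions": list(self.reactions),
            "feedstocks": list(self.feedstocks),
            "depth": self.depth,
        }
        if self.net is not None:
            d["net"] = self.net.to_dict()
        if self.atom_economy is not None:
            d["atom_economy"] = self.atom_economy
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Pathway":
        net = None
        if "net" in d:
            net = NetReaction(
                target=d["target"],
                net_reactants={k: int(v) for k, v in d["net"]["reactants"].items()},
                net_products={k: int(v) for k, v in d["net"]["products"].items()},
                multipliers={k: int(v) for k, v in d["net"].get("multipliers", {}).items()},
            )
        return cls(
            reactions=list(d["reactions"]),
            target=d["target"],
            feedstocks=list(d["feedstocks"]),
            depth=int(d.get("depth", len(d["reactions"]))),
            net=net,
            atom_economy=d.get("atom_economy"),
        )


class PathwaySet(list):
    """Result list; ``incomplete`` flags truncation at the pathway cap."""

    incomplete: bool = False


# -- net reaction ----------------------------------------------------------

def _cofactor_keys(network: Network) -> set[str]:
    return {k for k, m in network.molecules.items() if "cofactor" in m.roles}


def net_reaction(reaction_keys: list[str], target: str, network: Network) -> NetReaction:
    """Minimal positive integer multipliers cancelling every molecule that is
    both produced and consumed within the pathway; cofactor-role species are
    removed from both sides of the result (they are recycled).

    Raises :class:`StoichiometryError` when no such combination exists.
    """
    rxns = [network.reactions[k] for k in sorted(reaction_keys)]
    produced = Counter()
    consumed = Counter()
    for r in rxns:
        produced.update(r.product_counts())
        consumed.update(r.reactant_counts())
    internal = sorted((set(produced) & set(consumed)) - {target})

    n = len(rxns)
    if internal:
        # net(m) >= 0 for internal molecules, nu >= 1 integer, minimize sum(nu)
        A = np.zeros((len(internal), n))
        for j, r in enumerate(rxns):
            pc, rc = r.product_counts(), r.reactant_counts()
            for i, m in enumerate(internal):
                A[i, j] = pc.get(m, 0) - rc.get(m, 0)
        res = milp(
            c=np.ones(n),
            constraints=LinearConstraint(A, lb=0, ub=np.inf),
            integrality=np.ones(n),
            bounds=(1, np.inf),
        )
        if not res.success:
            raise StoichiometryError(
                f"stoichiometrically inconsistent pathway for target {target!r}"
            )
        nu = [int(round(x)) for x in res.x]
    else:
        nu = [1] * n

    g = 0
    for v in nu:
        g = gcd(g, v)
    nu = [v // g for v in nu]

    net: Counter[str] = Counter()
    for v, r in zip(nu, rxns):
        for m, c in r.product_counts().items():
            net[m] += v * c
        for m, c in r.reactant_counts().items():
            net[m] -= v * c
    cofactors = _cofactor_keys(network)
    net_products = {m: v for m, v in net.items() if v > 0 and m not in cofactors}
    net_reactants = {m: -v for m, v in net.items() if v < 0 and m not in cofactors}
    if target not in net_products:
        raise StoichiometryError(f"target {target!r} cancelled out of the net reaction")
    return NetReaction(
        target=target,
        net_reactants=net_reactants,
        net_products=net_products,
        multipliers={r.key: v for r, v in zip(rxns, nu)},
    )


def _net_atom_economy(net: NetReaction, network: Network) -> float:
    """Eq-style atom economy of a net reaction: desired-product mass over
    total net product mass (one desired copy; cofactors already excluded)."""
    mw = lambda k: network.molecules[k].weight
    denom = sum(v * mw(m) for m, v in net.net_products.items())
    return mw(net.target) / denom


# -- search ----------------------------------------------------------------

def _topological_order(reaction_keys: set[str], target: str, terminal: set[str],
                       network: Network) -> list[str] | None:
    """Firing order with the target-producing reaction last, or None if the
    set cannot be stratified (cyclic)."""
    remaining = dict.fromkeys(sorted(reaction_keys))
    available = set(terminal)
    for k in reaction_keys:
        for m in network.reactions[k].reactants:
            if m not in {p for rk in reaction_keys for p in network.reactions[rk].products}:
                available.add(m)
    order: list[str] = []
    while remaining:
        fired = None
        for k in remaining:
            if all(m in available for m in network.reactions[k].reactants):
                fired = k
                break
        if fired is None:
            return None
        order.append(fired)
        available.update(network.reactions[fired].products)
        del remaining[fired]
    # convention: target-producing reaction last, unless one of its
    # co-products feeds a later member (then the firing order stands)
    for k in order:
        if target in network.reactions[k].products:
            feeds_member = any(
                k2 != k and any(
                    p in network.reactions[k2].reactants
                    for p in network.reactions[k].products
                )
                for k2 in reaction_keys
            )
            if not feeds_member:
                order.remove(k)
                order.append(k)
            break
    return order


def structural_depth(reaction_keys: set[str], network: Network) -> int:
    """Longest chain in the reaction-precedence DAG of a pathway's reaction
    set: r precedes r' when a product of r is a reactant of r'."""
    keys = sorted(reaction_keys)
    memo: dict[str, int] = {}

    def level(k: str, seen: frozenset) -> int:
        if k in memo:
            return memo[k]
        preds = [
            k2 for k2 in keys
            if k2 != k and k2 not in seen
            and any(p in network.reactions[k].reactants for p in network.reactions[k2].products)
        ]
        d = 1 + max((level(p, seen | {k}) for p in preds), default=0)
        memo[k] = d
        return d

    return max(level(k, frozenset()) for k in keys) if keys else 0


def find_pathways(
    network: Network,
    target: str,
    starters: list[str],
    helpers: list[str] | None = None,
    limits: SearchLimits | None = None,
) -> PathwaySet:
    """Enumerate all distinct pathways from starters/helpers to ``target``.

    Exhaustive up to the limits and the ``max_pathways`` cap (the result is
    flagged ``incomplete`` when the cap truncates it); deterministic
    ordering; no duplicate reaction sets.
    """
    limits = limits or SearchLimits()
    helpers = helpers or []
    if target not in network.molecules:
        raise PathwayError(f"target {target!r} not in network")
    terminal = set(starters) | set(helpers)

    producers: dict[str, list[str]] = {}

    def producers_of(m: str) -> list[str]:
        if m not in producers:
            producers[m] = network.producers(m)
        return producers[m]

    results: dict[frozenset, Pathway] = {}
    out = PathwaySet()

    # State: (assignment mol->rxn key, pending list, ancestors mol->frozenset,
    # depth mol->int). LIFO stack gives depth-first descent into the most
    # recent branch while siblings stay queued.
    initial = ({}, [target], {target: frozenset()}, {target: 0})
    stack = [initial]
    while stack:
        assignment, pending, anc, depth = stack.pop()
        if not pending:
            rset = frozenset(assignment.values())
            if rset in results:
                continue
            order = _topological_order(rset, target, terminal, network)
            if order is None:
                continue
            pw_depth = structural_depth(rset, network)
            if pw_depth > limits.max_generations:
                continue
            try:
                net = net_reaction(sorted(rset), target, network)
            except StoichiometryError:
                continue
            ae = _net_atom_economy(net, network)
            if ae < limits.min_atom_economy:
                continue
            consumed = {m for k in rset for m in network.reactions[k].reactants}
            produced = {m for k in rset for m in network.reactions[k].products}
            pw = Pathway(
                reactions=order,
                target=target,
                feedstocks=sorted(consumed - produced),
                depth=pw_depth,
                net=net,
                atom_economy=ae,
            )
            results[rset] = pw
            out.append(pw)
            if len(out) >= limits.max_pathways:
                out.incomplete = True
                break
            continue

        # fewest-producers-first; ties broken lexicographically
        m = min(pending, key=lambda x: (len(producers_of(x)), x))
        rest = [x for x in pending if x != m]
        if depth[m] + 1 > limits.max_generations:
            continue
        # push siblings in reverse-sorted order so the first producer is
        # explored first from the LIFO stack
        for rk in sorted(producers_of(m), reverse=True):
            rxn = network.reactions[rk]
            if any(q == m or q in anc[m] for q in rxn.reactants):
                continue  # would create a cycle
            new_assignment = dict(assignment)
            new_assignment[m] = rk
            if len(set(new_assignment.values())) > limits.max_steps:
                continue
            new_pending = list(rest)
            new_anc = dict(anc)
            new_depth = dict(depth)
            m_anc = anc[m] | {m}
            ok = True
            for q in rxn.reactants:
                if q in terminal:
                    continue
                new_anc[q] = new_anc.get(q, frozenset()) | m_anc
                new_depth[q] = max(new_depth.get(q, 0), depth[m] + 1)
                if q in new_assignment:
                    # already resolved along another branch; the ancestor
                    # union above keeps later cycle checks sound
                    if q in new_anc and new_anc[q] & {q}:
                        ok = False
                        break
                    continue
                if q not in new_pending:
                    new_pending.append(q)
            if ok:
                stack.append((new_assignment, new_pending, new_anc, new_depth))

    out.sort(key=lambda p: (p.n_steps, p.key))
    return out


# -- Reaxys batch plumbing -------------------------------------------------

def write_reaxys_batch(
    pathways: list[Pathway], network: Network, path: str | Path
) -> tuple[Path, Path]:
    """Write a query batch (one line per unique reaction, stable index) and a
    zero-filled result template CSV alongside it.

    Returns (batch path, template path). The filled-in template is what the
    ranking stage reads back to score database-reported reactions.
    """
    if not pathways:
        raise PathwayError("no pathways to write")
    path = Path(path)
    keys = sorted({k for p in pathways for k in p.reactions})
    lines = []
    for idx, k in enumerate(keys, start=1):
        r = network.reactions[k]
        lines.append(f"{idx}\t{'.'.join(r.reactants)}>>{'.'.join(r.products)}")
    path.write_text("\n".join(lines) + "\n")
    template = path.with_suffix(".results.csv")
    template.write_text(
        "reaction_index,hits\n" + "".join(f"{i},0\n" for i in range(1, len(keys) + 1))
    )
    return path, template


def reaxys_index(pathways: list[Pathway]) -> dict[str, int]:
    """Stable reaction-key -> batch index mapping matching the batch file."""
    keys = sorted({k for p in pathways for k in p.reactions})
    return {k: i for i, k in enumerate(keys, start=1)}
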