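"""Shared fixtures: demo rules, thermo model, hand-built toy networks, and an
independent brute-force pathway oracle used to validate the backward search."""

from __future__ import annotations

import itertools

import pytest

from routenet.fixtures import demo_rules as _demo_rules
from routenet.model import Molecule, Network, Reaction
from routenet.pathways import (
    SearchLimits, StoichiometryError, net_reaction, structural_depth,
)
from routenet.ranking import atom_economy
from routenet.thermo import BensonModel


@pytest.fixture(scope="session")
def rules():
    return _demo_rules()


@pytest.fixture(scope="session")
def rules_by_id(rules):
    return {r.rule_id: r for r in rules}


@pytest.fixture(scope="session")
def benson():
    return BensonModel()


def build_network(reactions: list[tuple[str, list[str], list[str]]],
                  masses: dict[str, float] | None = None) -> Network:
    """Synthetic network from (rule_id, reactants, products) triples; every
    molecule gets mass 10 unless overridden."""
    net = Network()
    masses = masses or {}
    for rid, reactants, products in reactions:
        for m in reactants + products:
            net.add_molecule(Molecule(key=m, mw=masses.get(m, 10.0)))
        net.add_reaction(Reaction(rule_id=rid, reactants=list(reactants), products=list(products)))
    return net


@pytest.fixture
def linear_net():
    """A -> B -> C chain."""
    return build_network([("r1", ["A"], ["B"]), ("r2", ["B"], ["C"])])


@pytest.fixture
def diamond_net():
    """Two parallel one-step branches A->B, A->B2 converging on C."""
    return build_network([
        ("r1", ["A"], ["B"]),
        ("r2", ["A"], ["B2"]),
        ("r3", ["B"], ["C"]),
        ("r4", ["B2"], ["C"]),
    ])


@pytest.fixture
def convergent_net():
    """Fork that must be fully included: A->B, D->E, B+E->C."""
    return build_network([
        ("r1", ["A"], ["B"]),
        ("r2", ["D"], ["E"]),
        ("r3", ["B", "E"], ["C"]),
    ])


# -- independent oracle ----------------------------------------------------

def _fires(subset: set[str], net: Network, terminal: set[str]) -> bool:
    """All reactions in the subset can fire in some order starting from the
    terminal molecules plus the subset's external feedstocks."""
    produced = {m for k in subset for m in net.reactions[k].products}
    available = set(terminal) | {
        m for k in subset for m in net.reactions[k].reactants if m not in produced
    }
    remaining = set(subset)
    while remaining:
        fired = {k for k in remaining
                 if all(m in available for m in net.reactions[k].reactants)}
        if not fired:
            return False
        for k in fired:
            available.update(net.reactions[k].products)
        remaining -= fired
    return True


def _realizable(subset: set[str], net: Network, terminal: set[str], target: str) -> bool:
    """Exists a producer assignment whose demand closure from the target is
    exactly this subset and whose dependency graph is acyclic."""
    produced = sorted({m for k in subset for m in net.reactions[k].products})
    producers = {
        m: [k for k in sorted(subset) if m in net.reactions[k].products] for m in produced
    }
    for choice in itertools.product(*(producers[m] for m in produced)):
        f = dict(zip(produced, choice))
        closure: set[str] = set()
        demanded: set[str] = set()
        stack = [target]
        ok = True
        while stack:
            m = stack.pop()
            if m in demanded or m in terminal:
                continue
            if m not in f:
                ok = False
                break
            demanded.add(m)
            closure.add(f[m])
            stack.extend(net.reactions[f[m]].reactants)
        if not ok or closure != subset:
            continue
        # cycle check on the molecule dependency graph m -> reactants(f(m))
        color: dict[str, int] = {}

        def cyclic(m: str) -> bool:
            if m in terminal or m not in demanded:
                return False
            if color.get(m) == 1:
                return True
            if color.get(m) == 2:
                return False
            color[m] = 1
            for q in net.reactions[f[m]].reactants:
                if cyclic(q):
                    return True
            color[m] = 2
            return False

        if not cyclic(target):
            return True
    return False


def brute_force_pathways(
    net: Network, target: str, starters: list[str], helpers: list[str],
    limits: SearchLimits,
) -> set[frozenset]:
    """Exhaustive enumeration of all reaction subsets satisfying the pathway
    invariants and limits. Exponential; only for networks of <= ~15 reactions."""
    terminal = set(starters) | set(helpers)
    rkeys = sorted(net.reactions)
    found: set[frozenset] = set()
    for r in range(1, min(len(rkeys), limits.max_steps) + 1):
        for combo in itertools.combinations(rkeys, r):
            subset = set(combo)
            produced = {m for k in subset for m in net.reactions[k].products}
            if target not in produced:
                continue
            if not all(
                m in terminal or m in produced
                for k in subset for m in net.reactions[k].reactants
            ):
                continue
            if not _fires(subset, net, terminal):
                continue
            if not _realizable(subset, net, terminal, target):
                continue
            if structural_depth(subset, net) > limits.max_generations:
                continue
            try:
                nr = net_reaction(sorted(subset), target, net)
            except StoichiometryError:
                continue
            if atom_economy(nr, net) < limits.min_atom_economy:
                continue
            found.add(frozenset(subset))
    return found


@pytest.fixture(scope="session")
def oracle():
    return brute_force_pathways
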